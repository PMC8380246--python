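"""Response-trajectory classification and longitudinal k-means clustering.

Response status is rule-based: a responder shows at least a 50% reduction
of the MADRS score at week 8 relative to week 0 (ratio <= 0.5, boundary
inclusive); early responders additionally meet the criterion at week 2.
Nonresponders are descriptively subtyped as *flat* or *relapse* (initial
drop followed by a rise of more than 20% of baseline after the nadir);
the subtypes are merged for all downstream analyses.

Longitudinal k-means treats each subject's 5-week MADRS panel as a point
in R^5 and runs Lloyd's algorithm with multiple restarts; the number of
clusters is selected by the Calinski-Harabasz criterion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

WEEKS = (0, 2, 4, 6, 8)


@dataclass(frozen=True)
class ResponseLabel:
    subject_id: str
    delta_madrs_t2: float
    delta_madrs_t8: float
    label: str        # early_responder | later_responder | nonresponder
    nr_subtype: str   # flat | relapse | not_applicable


@dataclass
class KmlResult:
    k: int
    assignments: np.ndarray
    centroids: np.ndarray
    calinski_harabasz: float
    n_restarts: int
    best_inertia: float


def delta_madrs(score_t0: float, score_t_later: float) -> float:
    """Ratio of a later MADRS score to baseline (response = ratio <= 0.5)."""
    if score_t0 <= 0:
        raise ValueError("baseline MADRS must be positive (inclusion requires >= 21)")
    return score_t_later / score_t0


def classify_response(madrs_row, subject_id: str = "") -> ResponseLabel:
    """Classify one subject's 5-week MADRS row into a response-trajectory class."""
    row = np.asarray(madrs_row, dtype=float)
    if row.shape != (5,) or np.any(np.isnan(row)):
        raise ValueError("incomplete case: MADRS required at weeks 0, 2, 4, 6, 8")
    r2 = delta_madrs(row[0], row[1])
    r8 = delta_madrs(row[0], row[4])
    if r8 <= 0.5:
        label = "early_responder" if r2 <= 0.5 else "later_responder"
        subtype = "not_applicable"
    else:
        label = "nonresponder"
        nadir = int(np.argmin(row))
        rise = row[4] - row[nadir]
        subtype = "relapse" if nadir < 4 and rise > 0.2 * row[0] else "flat"
    return ResponseLabel(subject_id, r2, r8, label, subtype)


def classify_cohort(madrs: pd.DataFrame) -> pd.DataFrame:
    """Classify every row of a subjects x weeks MADRS table.

    Returns a table indexed by subject with ratio columns, the response
    label, the nonresponder subtype, and a responder indicator.
    """
    records = [classify_response(madrs.loc[sid].values, str(sid)) for sid in madrs.index]
    out = pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in records],
            "delta_madrs_t2": [r.delta_madrs_t2 for r in records],
            "delta_madrs_t8": [r.delta_madrs_t8 for r in records],
            "label": [r.label for r in records],
            "nr_subtype": [r.nr_subtype for r in records],
        }
    ).set_index("subject_id")
    out["responder"] = (out["label"] != "nonresponder").astype(int)
    return out


def calinski_harabasz(X: np.ndarray, labels: np.ndarray) -> float:
    """Calinski-Harabasz criterion [B/(k-1)] / [W/(n-k)].

    B is the size-weighted between-cluster sum of squared centroid
    distances to the grand mean, W the within-cluster sum of squares.
    Returns +inf for the degenerate W = 0 case.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    k, n = len(uniq), len(X)
    if k < 2:
        raise ValueError("Calinski-Harabasz requires at least 2 nonempty clusters")
    grand = X.mean(axis=0)
    B = 0.0
    W = 0.0
    for u in uniq:
        pts = X[labels == u]
        c = pts.mean(axis=0)
        B += len(pts) * float(np.sum((c - grand) ** 2))
        W += float(np.sum((pts - c) ** 2))
    if W == 0.0:
        return float("inf")
    return (B / (k - 1)) / (W / (n - k))


def _lloyd(X: np.ndarray, k: int, rng: np.random.Generator, max_iter: int = 300) -> tuple[np.ndarray, np.ndarray, float]:
    n = len(X)
    centroids = X[rng.choice(n, size=k, replace=False)].copy()
    assign = np.full(n, -1)
    for _ in range(max_iter):
        d2 = ((X[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        new_assign = np.argmin(d2, axis=1)  # ties -> lowest-index centroid
        reseeded: list[int] = []
        for c in range(k):
            if not np.any(new_assign == c):
                # re-seed an empty cluster at the point farthest from its
                # current centroid (excluding points just used to re-seed)
                dist = d2[np.arange(n), new_assign].copy()
                dist[reseeded] = -1.0
                far = int(np.argmax(dist))
                centroids[c] = X[far]
                new_assign[far] = c
                reseeded.append(far)
        if np.array_equal(new_assign, assign):
            break
        assign = new_assign
        for c in range(k):
            if np.any(assign == c):
                centroids[c] = X[assign == c].mean(axis=0)
    d2 = ((X[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    inertia = float(d2[np.arange(n), assign].sum())
    return assign, centroids, inertia


def kml_cluster(
    madrs_matrix: np.ndarray,
    k_candidates=(2, 3, 4, 5, 6),
    n_restarts: int = 50,
    seed: int | None = None,
) -> tuple[dict[int, KmlResult], int]:
    """Longitudinal k-means over candidate k with Calinski-Harabasz selection.

    Each restart runs Lloyd's algorithm from k distinct random subjects;
    the best restart per k minimizes inertia, and the selected k maximizes
    the Calinski-Harabasz criterion.

    Returns (per-k results, selected k).
    """
    X = np.asarray(madrs_matrix, dtype=float)
    if np.any(np.isnan(X)):
        raise ValueError("MADRS matrix must be complete")
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    rng = np.random.default_rng(seed)
    results: dict[int, KmlResult] = {}
    for k in k_candidates:
        if k >= len(X):
            raise ValueError(f"k={k} must be smaller than the number of subjects ({len(X)})")
        best = None
        for _ in range(n_restarts):
            assign, cents, inertia = _lloyd(X, k, rng)
            if best is None or inertia < best[2]:
                best = (assign, cents, inertia)
        assign, cents, inertia = best
        results[k] = KmlResult(
            k=k,
            assignments=assign,
            centroids=cents,
            calinski_harabasz=calinski_harabasz(X, assign),
            n_restarts=n_restarts,
            best_inertia=inertia,
        )
    selected = max(results, key=lambda k: results[k].calinski_harabasz)
    return results, selected
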