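"""Normalization, covariate adjustment, differential expression and the RNA screening funnel.

The funnel selects RNAs for longitudinal modelling by three stepwise
criteria:

1. differential expression between patients and healthy controls at
   baseline (NB-GLM Wald test, BH FDR <= 20%);
2. (after dropping RNAs with missing data at week 0 or 8) Pearson
   correlation between expression and the week-8 MADRS ratio, p < 0.05;
3. exclusion of RNAs whose *baseline* expression correlates with the same
   MADRS ratio at p < 0.2, so that selected RNAs track response without
   being baseline predictors.

Counts are normalized by median-of-ratios size factors, log2 transformed
with a pseudocount, and adjusted for age, sex and RIN by per-gene OLS
residualization.  The differential-expression engine is a negative
binomial GLM (variance mu + alpha*mu^2) with per-gene maximum-likelihood
dispersion and a Wald test on the group coefficient, fitted by IRLS
vectorized across genes; it deliberately omits empirical-Bayes dispersion
shrinkage and LFC shrinkage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

LN2 = np.log(2.0)


def size_factors(counts) -> pd.Series:
    """Median-of-ratios size factors.

    s_j = median over genes g (with positive counts in every sample) of
    counts_gj / geometric_mean_g.
    """
    mat = counts.values if isinstance(counts, pd.DataFrame) else np.asarray(counts, dtype=float)
    if np.any(mat < 0):
        raise ValueError("counts must be nonnegative")
    positive = np.all(mat > 0, axis=1)
    if not np.any(positive):
        raise ValueError(
            "no gene has positive counts in every sample; median-of-ratios "
            "normalization needs at least one such gene (filter the matrix or "
            "supply size factors explicitly)"
        )
    logc = np.log(mat[positive])
    log_ratios = logc - logc.mean(axis=1, keepdims=True)
    s = np.exp(np.median(log_ratios, axis=0))
    if isinstance(counts, pd.DataFrame):
        return pd.Series(s, index=counts.columns, name="size_factor")
    return pd.Series(s, name="size_factor")


def normalize_log2(counts, size_factors, pseudocount: float = 1.0):
    """log2(count / size_factor + pseudocount), elementwise."""
    mat = counts.values if isinstance(counts, pd.DataFrame) else np.asarray(counts, dtype=float)
    s = np.asarray(size_factors, dtype=float)
    if pseudocount <= 0 and np.any(mat == 0):
        raise ValueError("pseudocount must be positive when the matrix contains zero counts")
    out = np.log2(mat / s[None, :] + pseudocount)
    if isinstance(counts, pd.DataFrame):
        return pd.DataFrame(out, index=counts.index, columns=counts.columns)
    return out


def _check_full_rank(design: np.ndarray, names: list[str]) -> None:
    if np.linalg.matrix_rank(design) < design.shape[1]:
        bad = []
        for j in range(design.shape[1]):
            others = np.delete(design, j, axis=1)
            resid = design[:, j] - others @ np.linalg.lstsq(others, design[:, j], rcond=None)[0]
            if np.max(np.abs(resid)) < 1e-10 * max(1.0, np.max(np.abs(design[:, j]))):
                bad.append(names[j])
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad or names}")


def residualize(expr, covariates: pd.DataFrame):
    """Per-gene OLS residuals on intercept + covariates, grand mean added back.

    `expr` is genes x samples; `covariates` is samples x variables aligned
    with the columns of `expr`.
    """
    mat = expr.values if isinstance(expr, pd.DataFrame) else np.asarray(expr, dtype=float)
    cov = covariates.values.astype(float)
    if cov.shape[0] != mat.shape[1]:
        raise ValueError("covariate rows must match expression columns")
    if np.any(~np.isfinite(cov)):
        raise ValueError("covariates must be complete")
    X = np.column_stack([np.ones(cov.shape[0]), cov])
    _check_full_rank(X, ["intercept"] + list(covariates.columns))
    beta = np.linalg.lstsq(X, mat.T, rcond=None)[0]  # p x genes
    resid = mat - (X @ beta).T
    out = resid + mat.mean(axis=1, keepdims=True)
    if isinstance(expr, pd.DataFrame):
        return pd.DataFrame(out, index=expr.index, columns=expr.columns)
    return out


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Negative binomial GLM Wald differential expression
# ---------------------------------------------------------------------------

_ALPHA_LO, _ALPHA_HI = 1e-8, 10.0
_ETA_CAP = 30.0


def _nb_loglik(Y: np.ndarray, mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """NB2 log-likelihood summed over samples; alpha is per-gene (genes,)."""
    a = alpha[:, None]
    inv_a = 1.0 / a
    return np.sum(
        special.gammaln(Y + inv_a)
        - special.gammaln(inv_a)
        - special.gammaln(Y + 1.0)
        + Y * np.log(a * mu / (1.0 + a * mu))
        - inv_a * np.log1p(a * mu),
        axis=1,
    )


def _irls_beta(Y, X, offset, alpha, beta0, n_iter=25, tol=1e-8):
    """IRLS for the NB GLM with log link, vectorized across genes."""
    beta = beta0.copy()
    for _ in range(n_iter):
        eta = np.clip(offset[None, :] + beta @ X.T, -_ETA_CAP, _ETA_CAP)
        mu = np.exp(eta)
        W = mu / (1.0 + alpha[:, None] * mu)
        z = (eta - offset[None, :]) + (Y - mu) / mu
        XtWX = np.einsum("sj,gs,sk->gjk", X, W, X)
        XtWz = np.einsum("sj,gs,gs->gj", X, W, z)
        # ridge jitter keeps degenerate genes (e.g. a group of all zeros) solvable
        XtWX += 1e-10 * np.eye(X.shape[1])[None, :, :]
        new_beta = np.linalg.solve(XtWX, XtWz[..., None])[..., 0]
        step = np.max(np.abs(new_beta - beta))
        beta = new_beta
        if step < tol:
            break
    return beta


def _cr_penalty(X, mu, alpha):
    """Cox-Reid adjustment 0.5 * log det(X' W X), vectorized across genes."""
    W = mu / (1.0 + alpha[:, None] * mu)
    XtWX = np.einsum("sj,gs,sk->gjk", X, W, X) + 1e-12 * np.eye(X.shape[1])[None, :, :]
    _, logdet = np.linalg.slogdet(XtWX)
    return 0.5 * logdet


def _profile_alpha(Y, X, offset, beta, lo=_ALPHA_LO, hi=_ALPHA_HI, n_iter=40):
    """Golden-section maximization of the per-gene NB adjusted profile likelihood in log-alpha.

    The Cox-Reid term 0.5*log det(X'WX) is subtracted to debias the
    dispersion estimate for the fitted mean parameters.
    """
    eta = np.clip(offset[None, :] + beta @ X.T, -_ETA_CAP, _ETA_CAP)
    mu = np.exp(eta)
    g = Y.shape[0]

    def apl(log_alpha):
        a = np.exp(log_alpha)
        return _nb_loglik(Y, mu, a) - _cr_penalty(X, mu, a)

    a = np.full(g, np.log(lo))
    b = np.full(g, np.log(hi))
    gr = (np.sqrt(5.0) - 1.0) / 2.0
    c = b - gr * (b - a)
    d = a + gr * (b - a)
    fc = apl(c)
    fd = apl(d)
    for _ in range(n_iter):
        take_c = fc > fd
        b = np.where(take_c, d, b)
        a = np.where(take_c, a, c)
        c = b - gr * (b - a)
        d = a + gr * (b - a)
        fc = apl(c)
        fd = apl(d)
    return np.exp((a + b) / 2.0)


def nb_wald_de(
    counts,
    group_labels,
    size_factors_=None,
    covariates: pd.DataFrame | None = None,
    n_outer: int = 3,
) -> pd.DataFrame:
    """Negative binomial GLM Wald test for case-vs-control differential expression.

    Fits, per gene, log mu = beta0 + beta1 * group (+ covariates) + log s_j
    with per-gene ML dispersion (method-of-moments start, alternating IRLS
    for beta and golden-section profile maximization for alpha).  Returns a
    table with log2 fold change, SE, Wald z, two-sided normal p, BH
    adjusted p, mean normalized count and the dispersion estimate.

    `group_labels` is a boolean/0-1 vector (1 = case).  All-zero genes get
    p = 1 and the `all_zero` flag rather than being dropped.
    """
    Y = (counts.values if isinstance(counts, pd.DataFrame) else np.asarray(counts)).astype(float)
    genes = counts.index if isinstance(counts, pd.DataFrame) else pd.RangeIndex(Y.shape[0])
    group = np.asarray(group_labels, dtype=float)
    if set(np.unique(group)) - {0.0, 1.0}:
        raise ValueError("group_labels must be binary (1 = case)")
    if group.sum() < 2 or (1 - group).sum() < 2:
        raise ValueError("each group needs at least 2 samples")
    s = np.asarray(size_factors_ if size_factors_ is not None else size_factors(counts), dtype=float)
    offset = np.log(s)

    cols = [np.ones_like(group), group]
    names = ["intercept", "group"]
    if covariates is not None:
        cov = covariates.values.astype(float)
        cov = cov - cov.mean(axis=0, keepdims=True)
        cols.extend(cov.T)
        names.extend(covariates.columns)
    X = np.column_stack(cols)
    _check_full_rank(X, names)

    all_zero = Y.sum(axis=1) == 0
    norm = Y / s[None, :]

    # method-of-moments dispersion start, pooled within groups
    alpha0 = np.zeros(Y.shape[0])
    denom = 0.0
    for gval in (0.0, 1.0):
        sel = group == gval
        m = norm[:, sel].mean(axis=1)
        v = norm[:, sel].var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            alpha0 += np.where(m > 0, (v - m) / m**2, 0.0)
        denom += 1.0
    alpha = np.clip(alpha0 / denom, _ALPHA_LO, _ALPHA_HI)

    # beta start from group means of normalized counts
    beta = np.zeros((Y.shape[0], X.shape[1]))
    m0 = norm[:, group == 0].mean(axis=1)
    m1 = norm[:, group == 1].mean(axis=1)
    beta[:, 0] = np.log(np.maximum(m0, 0.5))
    beta[:, 1] = np.log(np.maximum(m1, 0.5)) - beta[:, 0]

    for _ in range(n_outer):
        beta = _irls_beta(Y, X, offset, alpha, beta)
        alpha = _profile_alpha(Y, X, offset, beta)
    beta = _irls_beta(Y, X, offset, alpha, beta)

    eta = np.clip(offset[None, :] + beta @ X.T, -_ETA_CAP, _ETA_CAP)
    mu = np.exp(eta)
    W = mu / (1.0 + alpha[:, None] * mu)
    XtWX = np.einsum("sj,gs,sk->gjk", X, W, X) + 1e-10 * np.eye(X.shape[1])[None, :, :]
    cov_beta = np.linalg.inv(XtWX)
    se = np.sqrt(np.maximum(cov_beta[:, 1, 1], 0.0))

    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, beta[:, 1] / se, 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    p[all_zero] = 1.0
    z[all_zero] = 0.0

    return pd.DataFrame(
        {
            "base_mean": norm.mean(axis=1),
            "lfc": np.where(all_zero, 0.0, beta[:, 1] / LN2),
            "se": se / LN2,
            "z": z,
            "p": p,
            "padj": bh_adjust(p),
            "dispersion": alpha,
            "all_zero": all_zero,
        },
        index=genes,
    )


def pearson_screen(expr, delta_madrs_vector) -> pd.DataFrame:
    """Per-gene Pearson correlation of expression with the MADRS ratio.

    Vectorized across the rows of `expr` (genes x subjects); p from the
    exact t transform on n-2 df.  Genes with zero expression variance are
    flagged (r = NaN, p = 1).
    """
    mat = expr.values if isinstance(expr, pd.DataFrame) else np.asarray(expr, dtype=float)
    y = np.asarray(delta_madrs_vector, dtype=float)
    n = len(y)
    if n < 3:
        raise ValueError("need at least 3 paired observations")
    if mat.shape[1] != n:
        raise ValueError("expression columns must match the MADRS vector")
    if np.var(y) == 0:
        raise ValueError("MADRS ratio vector has zero variance")
    xc = mat - mat.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    sx = np.sqrt(np.sum(xc**2, axis=1))
    sy = np.sqrt(np.sum(yc**2))
    degenerate = sx == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.clip((xc @ yc) / (sx * sy), -1.0, 1.0)
    r[degenerate] = np.nan
    df = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / np.maximum(1.0 - r**2, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(np.isnan(r), 1.0, np.where(np.abs(r) >= 1.0, 0.0, p))
    idx = expr.index if isinstance(expr, pd.DataFrame) else pd.RangeIndex(mat.shape[0])
    return pd.DataFrame({"r": r, "p": p, "zero_variance": degenerate}, index=idx)


@dataclass
class ScreenResult:
    """Funnel outcome: per-gene criteria table, stage counts and selected genes."""

    funnel: pd.DataFrame
    stage_counts: dict[str, int]
    selected: list[str]
    de: pd.DataFrame | None = None
    adjusted_expression: dict[int, pd.DataFrame] = field(default_factory=dict)
    delta_madrs: pd.Series | None = None


def select_candidates(
    de: pd.DataFrame,
    corr_t8: pd.DataFrame,
    corr_t0: pd.DataFrame,
    de_fdr: float = 0.20,
    corr_p: float = 0.05,
    baseline_p: float = 0.20,
    missing: pd.Series | None = None,
) -> ScreenResult:
    """Apply the three-criterion funnel in order and report per-stage counts.

    Stages: DE adjusted p <= `de_fdr`; drop genes missing at week 0 or 8;
    week-8 correlation p < `corr_p`; retain only genes whose baseline
    correlation p >= `baseline_p`.
    """
    for name, t in (("de_fdr", de_fdr), ("corr_p", corr_p), ("baseline_p", baseline_p)):
        if not 0 < t < 1:
            raise ValueError(f"threshold {name} must lie in (0, 1)")
    genes = de.index
    if not (genes.equals(corr_t8.index) and genes.equals(corr_t0.index)):
        raise ValueError("DE and correlation tables must share the same gene universe")
    if missing is None:
        missing = pd.Series(False, index=genes)

    c1 = de["padj"].values <= de_fdr
    not_missing = c1 & ~missing.loc[genes].values
    c2 = not_missing & (corr_t8["p"].values < corr_p)
    c3 = c2 & (corr_t0["p"].values >= baseline_p)

    funnel = pd.DataFrame(
        {
            "criterion1_de": c1,
            "not_missing": not_missing,
            "criterion2_corr_t8": c2,
            "criterion3_no_baseline_corr": c3,
            "final_selected": c3,
            "de_padj": de["padj"].values,
            "corr_t8_r": corr_t8["r"].values,
            "corr_t8_p": corr_t8["p"].values,
            "corr_t0_r": corr_t0["r"].values,
            "corr_t0_p": corr_t0["p"].values,
        },
        index=genes,
    )
    counts = {
        "universe": len(genes),
        "criterion1_de": int(c1.sum()),
        "not_missing": int(not_missing.sum()),
        "criterion2_corr_t8": int(c2.sum()),
        "criterion3_no_baseline_corr": int(c3.sum()),
    }
    return ScreenResult(funnel=funnel, stage_counts=counts, selected=list(genes[c3]))


def _patient_cols(counts: pd.DataFrame, week: int) -> list[str]:
    return [c for c in counts.columns if c.endswith(f"_T{week}")]


def screen_cohort(
    counts: pd.DataFrame,
    phenotypes: pd.DataFrame,
    labels: pd.DataFrame,
    de_fdr: float = 0.20,
    corr_p: float = 0.05,
    baseline_p: float = 0.20,
    pseudocount: float = 1.0,
    criterion2_variable: str = "t8",
) -> ScreenResult:
    """Run the full screening funnel on a cohort.

    Baseline DE compares patient week-0 samples with healthy controls in a
    NB GLM with age, sex and RIN as covariates.  Correlations use
    covariate-adjusted log2 expression, adjusted per timepoint, against
    the week-8 MADRS ratio; `criterion2_variable` selects the week-8 level
    ("t8") or the week-8 minus week-0 change ("delta") for criterion 2.
    """
    if criterion2_variable not in ("t8", "delta"):
        raise ValueError("criterion2_variable must be 't8' or 'delta'")
    pheno = phenotypes.set_index("subject_id") if "subject_id" in phenotypes.columns else phenotypes
    sf = size_factors(counts)

    hc_cols = [c for c in counts.columns if c.endswith("_HC")]
    t0_cols = _patient_cols(counts, 0)
    if not hc_cols or not t0_cols:
        raise ValueError("counts must contain patient _T0 and control _HC samples")
    de_cols = t0_cols + hc_cols
    de_subjects = [c.rsplit("_", 1)[0] for c in de_cols]
    de_cov = pheno.loc[de_subjects, ["age", "sex", "rin"]].reset_index(drop=True)
    group = np.array([1.0] * len(t0_cols) + [0.0] * len(hc_cols))
    de = nb_wald_de(counts[de_cols], group, sf.loc[de_cols].values, covariates=de_cov)

    # ordered by labels' subject index so every downstream table aligns
    patients = [sid for sid in labels.index if f"{sid}_T0" in counts.columns]
    delta = labels.loc[patients, "delta_madrs_t8"]

    adjusted: dict[int, pd.DataFrame] = {}
    for week in (0, 2, 8):
        cols = [f"{sid}_T{week}" for sid in patients]
        expr = normalize_log2(counts[cols], sf.loc[cols].values, pseudocount)
        cov = pheno.loc[patients, ["age", "sex", "rin"]].reset_index(drop=True)
        adj = residualize(expr, cov)
        adj.columns = patients  # subject ids, shared order across weeks
        adjusted[week] = adj

    missing = counts[[f"{sid}_T{w}" for sid in patients for w in (0, 8)]].isna().any(axis=1)
    if criterion2_variable == "t8":
        expr2 = adjusted[8]
    else:
        expr2 = adjusted[8] - adjusted[0].values
    corr_t8 = pearson_screen(expr2, delta.values)
    corr_t0 = pearson_screen(adjusted[0], delta.values)

    result = select_candidates(de, corr_t8, corr_t0, de_fdr, corr_p, baseline_p, missing)
    result.de = de
    result.adjusted_expression = adjusted
    result.delta_madrs = delta
    return result
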