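"""Supporting statistics: group-comparison tables, brain case-control tests, qPCR quantification.

Wraps the standard scipy routines behind the conventions the pipeline
uses: Pearson chi-square without continuity correction for r x c
contingency tables (Fisher's exact test reserved for 2 x 2 tables with
small expected counts), one-way ANOVA accepting either raw values or
(n, mean, sd) summary triples, Tukey HSD and Dunnett many-to-one post hoc
comparisons, pooled-variance two-sample t tests on log2 expression, and
relative qPCR quantification by the 2^-ddCt method against an endogenous
control gene.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


def _as_table(table) -> np.ndarray:
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("contingency table must be at least 2 x 2")
    if np.any(t < 0) or np.any(t != np.rint(t)):
        raise ValueError("contingency table must hold nonnegative integer counts")
    return t


def chi2_independence(table) -> tuple[float, int, float]:
    """Pearson chi-square test of independence, no continuity correction.

    Returns (statistic, df, upper-tail p).
    """
    t = _as_table(table)
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("contingency table has a zero margin")
    stat, p, df, _ = stats.chi2_contingency(t, correction=False)
    return float(stat), int(df), float(p)


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2 x 2 table (hypergeometric tail sum)."""
    t = _as_table(table)
    if t.shape != (2, 2):
        raise ValueError("Fisher exact test implemented for 2 x 2 tables only; use chi2_independence")
    return float(stats.fisher_exact(t, alternative="two-sided")[1])


def anova_oneway(groups=None, summaries=None) -> tuple[float, int, int, float]:
    """One-way ANOVA from raw groups or (n, mean, sd) summary triples.

    Returns (F, df_between, df_within, p).  The summary route decomposes
    SSB from size-weighted mean deviations and SSW from sum (n_g - 1) sd_g^2,
    so raw data and its own summaries give identical results.
    """
    if (groups is None) == (summaries is None):
        raise ValueError("provide exactly one of `groups` or `summaries`")
    if groups is not None:
        summaries = [
            (len(g), float(np.mean(g)), float(np.std(g, ddof=1))) for g in groups
        ]
        for n, _, _ in summaries:
            if n < 2:
                raise ValueError("each group needs at least 2 observations")
    if len(summaries) < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    ns = np.array([s[0] for s in summaries], dtype=float)
    means = np.array([s[1] for s in summaries], dtype=float)
    sds = np.array([s[2] for s in summaries], dtype=float)
    if np.any(ns < 2):
        raise ValueError("each group needs at least 2 observations")
    N = ns.sum()
    k = len(ns)
    grand = np.sum(ns * means) / N
    ssb = float(np.sum(ns * (means - grand) ** 2))
    ssw = float(np.sum((ns - 1) * sds**2))
    df1, df2 = k - 1, int(N - k)
    if ssw == 0:
        raise ValueError("zero within-group variance; F undefined")
    F = (ssb / df1) / (ssw / df2)
    return float(F), int(df1), df2, float(stats.f.sf(F, df1, df2))


@dataclass
class PairwiseComparison:
    group_a: int
    group_b: int
    statistic: float
    p_adjusted: float


def tukey_hsd(groups) -> list[PairwiseComparison]:
    """Tukey HSD all-pairs comparisons (studentized range on within-group MS)."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 3:
        # degenerates to a pooled two-sample t test
        t, _, p = two_sample_t(groups[0], groups[1])
        return [PairwiseComparison(0, 1, t, p)]
    res = stats.tukey_hsd(*groups)
    out = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            out.append(PairwiseComparison(i, j, float(res.statistic[i, j]), float(res.pvalue[i, j])))
    return out


def dunnett(groups, control_index: int = 0) -> list[PairwiseComparison]:
    """Dunnett many-to-one comparisons of each group against a control."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    control = groups[control_index]
    if len(control) == 0:
        raise ValueError("control group is empty")
    treatments = [g for i, g in enumerate(groups) if i != control_index]
    t_idx = [i for i in range(len(groups)) if i != control_index]
    res = stats.dunnett(*treatments, control=control)
    return [
        PairwiseComparison(control_index, t_idx[i], float(res.statistic[i]), float(res.pvalue[i]))
        for i in range(len(treatments))
    ]


def two_sample_t(values_a, values_b) -> tuple[float, int, float]:
    """Two-tailed pooled-variance t test. Returns (t, df, p)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least 2 observations")
    df = len(a) + len(b) - 2
    sp2 = ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)) / df
    if sp2 == 0:
        raise ValueError("zero pooled variance; t undefined")
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / len(a) + 1 / len(b)))
    return float(t), int(df), float(2 * stats.t.sf(abs(t), df))


@dataclass
class DdctResult:
    """Per-condition relative expression of a target gene by 2^-ddCt."""

    delta_ct: pd.Series        # mean dCt per condition
    ddct: pd.Series            # dCt minus the control condition's mean dCt
    fold_change: pd.Series     # 2^-ddCt
    replicate_dct: pd.DataFrame


def ddct(
    ct_table: pd.DataFrame,
    target_gene: str,
    reference_gene: str,
    control_condition: str,
) -> DdctResult:
    """Relative qPCR quantification (2^-ddCt) versus an endogenous control.

    `ct_table` has columns condition, replicate, gene, ct.  dCt is
    computed per replicate as Ct_target - Ct_reference, ddCt per condition
    as mean dCt minus the control condition's mean dCt.
    """
    required = {"condition", "replicate", "gene", "ct"}
    if not required <= set(ct_table.columns):
        raise ValueError(f"ct_table needs columns {sorted(required)}")
    wide = ct_table.pivot_table(index=["condition", "replicate"], columns="gene", values="ct")
    for gene in (target_gene, reference_gene):
        if gene not in wide.columns:
            raise ValueError(f"gene {gene!r} absent from the Ct table")
        if wide[gene].isna().any():
            missing = wide.index[wide[gene].isna()].tolist()
            raise ValueError(f"missing Ct for {gene!r} in replicate(s) {missing}")
    dct = (wide[target_gene] - wide[reference_gene]).rename("dct").reset_index()
    mean_dct = dct.groupby("condition")["dct"].mean()
    if control_condition not in mean_dct.index:
        raise ValueError(f"control condition {control_condition!r} absent")
    ddct_vals = mean_dct - mean_dct[control_condition]
    return DdctResult(
        delta_ct=mean_dct,
        ddct=ddct_vals,
        fold_change=np.exp2(-ddct_vals).rename("fold_change"),
        replicate_dct=dct,
    )
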