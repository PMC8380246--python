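"""Three-step association of RNA growth parameters with treatment response.

Step 1 screens each RNA with a binary logistic regression of responder
status (week-8 MADRS ratio <= 0.5) on that RNA's intercept and
standardized slope factor scores; RNAs whose slope Wald p < 0.05 advance.
Step 2 fits one multivariable binary logistic model with all advancing
RNAs' slopes plus covariates (age, sex, anxiety history, suicidality).
Step 3 fits one multivariable multinomial model of early/later/non-
response (nonresponders as base category) with the same predictors.
Slope coefficients are reported as risk ratios per 1 SD of slope with
Wald 95% CIs, and BH FDR is applied over the family of slope tests
(advancing RNAs x 3 contrasts, pooling the binary and both multinomial
contrasts).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .screening import bh_adjust

CONTRASTS = ("responders_vs_nr", "early_vs_nr", "later_vs_nr")
_SEPARATION_BOUND = 20.0


@dataclass
class LogisticResult:
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    converged: bool
    separation: bool


def logistic_fit(binary_outcome, design_matrix: pd.DataFrame) -> LogisticResult:
    """ML binary logistic regression (IRLS/Newton via statsmodels).

    Coefficients larger than 20 in absolute value are flagged as probable
    perfect separation.
    """
    y = np.asarray(binary_outcome, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    X = design_matrix if isinstance(design_matrix, pd.DataFrame) else pd.DataFrame(design_matrix)
    model = sm.Logit(y, X.astype(float))
    with np.errstate(all="ignore"):
        res = model.fit(disp=0, maxiter=200, warn_convergence=False)
        if not res.mle_retvals.get("converged", True):
            res = model.fit(disp=0, method="bfgs", maxiter=500, warn_convergence=False)
    separation = bool(np.any(np.abs(res.params.values) > _SEPARATION_BOUND)) or not res.mle_retvals.get(
        "converged", True
    )
    return LogisticResult(
        params=res.params, bse=res.bse, pvalues=res.pvalues, converged=res.mle_retvals.get("converged", True),
        separation=separation,
    )


@dataclass
class MultinomialResult:
    params: pd.DataFrame   # predictors x non-base classes (log RR vs base)
    bse: pd.DataFrame
    pvalues: pd.DataFrame
    classes: list[str]
    base: str
    converged: bool


def multinomial_fit(outcome, design_matrix: pd.DataFrame, base_category) -> MultinomialResult:
    """Multinomial logistic regression against a designated base category.

    Newton-Raphson ML via statsmodels MNLogit; one logit equation per
    non-base class.
    """
    y = pd.Series(outcome).astype(str)
    classes = sorted(y.unique())
    base = str(base_category)
    if base not in classes:
        raise ValueError(f"base category {base!r} not among outcome classes {classes}")
    counts = y.value_counts()
    if (counts < 1).any() or len(classes) < 2:
        raise ValueError("every outcome class must be nonempty")
    order = [base] + [c for c in classes if c != base]
    codes = y.map({c: i for i, c in enumerate(order)}).values
    X = design_matrix if isinstance(design_matrix, pd.DataFrame) else pd.DataFrame(design_matrix)
    res = sm.MNLogit(codes, X.astype(float)).fit(method="newton", disp=0, maxiter=200)
    nonbase = order[1:]
    params = pd.DataFrame(res.params.values, index=X.columns, columns=nonbase)
    bse = pd.DataFrame(res.bse.values, index=X.columns, columns=nonbase)
    pvals = pd.DataFrame(res.pvalues.values, index=X.columns, columns=nonbase)
    return MultinomialResult(params, bse, pvals, order, base, res.mle_retvals.get("converged", True))


def wald_rr(log_rr: float, se: float) -> dict[str, float]:
    """Risk ratio with Wald 95% CI and two-sided normal p from (log RR, SE)."""
    if se <= 0:
        raise ValueError("standard error must be positive")
    return {
        "rr": float(np.exp(log_rr)),
        "ci_low": float(np.exp(log_rr - 1.96 * se)),
        "ci_high": float(np.exp(log_rr + 1.96 * se)),
        "p": float(2.0 * stats.norm.sf(abs(log_rr) / se)),
    }


def step1_screen(
    intercept_scores: pd.DataFrame,
    slope_scores: pd.DataFrame,
    responder,
    step1_p: float = 0.05,
) -> tuple[pd.DataFrame, list[str]]:
    """Per-RNA binary logistic screen of responder status on intercept + slope.

    Intercept scores are centered for numerical conditioning (slope
    inference is unchanged); when a boundary (rank-1 Psi) growth fit makes
    the two scores exactly collinear the redundant intercept column is
    dropped.  RNAs whose slope Wald p < `step1_p` advance; fits flagged as
    separated are excluded.
    """
    responder = np.asarray(responder, dtype=float)
    subjects = slope_scores.index
    rows = []
    advancing: list[str] = []
    for rna in slope_scores.columns:
        i_score = intercept_scores[rna].values
        s_score = slope_scores[rna].values
        collinear = abs(np.corrcoef(i_score, s_score)[0, 1]) > 0.99
        cols = {"const": 1.0, "slope_score": s_score}
        if not collinear:
            cols["intercept_score"] = i_score - i_score.mean()
        res = logistic_fit(responder, pd.DataFrame(cols, index=subjects))
        rows.append(
            {
                "gene": rna,
                "slope_coef": res.params["slope_score"],
                "slope_p": res.pvalues["slope_score"],
                "intercept_coef": res.params.get("intercept_score", np.nan),
                "intercept_p": res.pvalues.get("intercept_score", np.nan),
                "intercept_dropped": collinear,
                "separation": res.separation,
            }
        )
        if not res.separation and res.pvalues["slope_score"] < step1_p:
            advancing.append(rna)
    return pd.DataFrame(rows).set_index("gene"), advancing


@dataclass
class ThreeStepResult:
    table: pd.DataFrame                 # AssociationTable: RNA x contrast rows
    step1: pd.DataFrame                 # per-RNA screening statistics
    advancing: list[str]
    fdr_family_size: int
    n_per_class: dict[str, int]


def run_three_step(
    intercept_scores: pd.DataFrame,
    slope_scores: pd.DataFrame,
    labels: pd.DataFrame,
    covariate_table: pd.DataFrame,
    step1_p: float = 0.05,
    include_intercepts_joint: bool = False,
) -> ThreeStepResult:
    """Run the full three-step slope-response association.

    `intercept_scores` / `slope_scores` are subjects x RNAs tables of
    factor scores (slopes already standardized to unit SD); `labels` is
    the classification table (needs `label` and `responder` columns);
    `covariate_table` holds age, sex, anxiety and suicidality per subject.
    Returns the Table-2-shaped association table plus step-1 statistics.
    """
    subjects = slope_scores.index
    lab = labels.loc[subjects]
    cov = covariate_table.loc[subjects, ["age", "sex", "anxiety", "suicidality"]].astype(float)
    responder = lab["responder"].values.astype(float)

    step1, advancing = step1_screen(intercept_scores, slope_scores, responder, step1_p)

    n_per_class = lab["label"].value_counts().to_dict()
    if not advancing:
        empty = pd.DataFrame(
            columns=["gene", "contrast", "log_rr", "se", "p", "fdr", "rr", "ci_low", "ci_high"]
        )
        return ThreeStepResult(empty, step1, [], 0, n_per_class)

    Xj = pd.concat(
        [
            pd.Series(1.0, index=subjects, name="const"),
            slope_scores[advancing],
            cov,
        ],
        axis=1,
    )
    if include_intercepts_joint:
        ints = intercept_scores[advancing].copy()
        ints.columns = [f"{c}_intercept" for c in ints.columns]
        Xj = pd.concat([Xj, ints], axis=1)

    step2 = logistic_fit(responder, Xj)
    step3 = multinomial_fit(lab["label"].values, Xj, base_category="nonresponder")

    rows = []
    for rna in advancing:
        rows.append(("responders_vs_nr", rna, step2.params[rna], step2.bse[rna]))
    for contrast, cls in (("early_vs_nr", "early_responder"), ("later_vs_nr", "later_responder")):
        for rna in advancing:
            rows.append((contrast, rna, step3.params.loc[rna, cls], step3.bse.loc[rna, cls]))
    table = pd.DataFrame(rows, columns=["contrast", "gene", "log_rr", "se"])
    w = [wald_rr(b, s) for b, s in zip(table["log_rr"], table["se"])]
    table["p"] = [x["p"] for x in w]
    table["rr"] = [x["rr"] for x in w]
    table["ci_low"] = [x["ci_low"] for x in w]
    table["ci_high"] = [x["ci_high"] for x in w]
    table["fdr"] = bh_adjust(table["p"].values)
    table = table[["gene", "contrast", "log_rr", "se", "p", "fdr", "rr", "ci_low", "ci_high"]]
    return ThreeStepResult(table, step1, advancing, len(table), n_per_class)
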