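"""Synthetic cohort generator.

Emulates an 8-week antidepressant trial: MADRS depression scores at weeks
0, 2, 4, 6, 8 drawn from four latent trajectory classes (early responder,
later responder, flat nonresponder, relapse nonresponder), and bulk
RNA-seq counts at weeks 0, 2 and 8 for patients plus a baseline-only
healthy-control group.  Counts are negative binomial with per-sample size
factors and covariate effects (age, sex, RIN).  Marker genes are shifted
versus controls at baseline, carry a response-class-specific linear slope
on the log2 scale over weeks 0-8 (zero class effect at week 0), and so
satisfy, in expectation, all three criteria of the screening funnel.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

WEEKS = np.array([0, 2, 4, 6, 8])
EXPR_WEEKS = np.array([0, 2, 8])
CLASS_NAMES = ("early_responder", "later_responder", "nr_flat", "nr_relapse")

#: Default mean MADRS curves per latent class at weeks 0, 2, 4, 6, 8.
#: Chosen to reproduce the qualitative trajectory shapes of the trial
#: (fast early drop; gradual response; flat nonresponse; relapse after an
#: initial drop); the trial reports no numeric per-class means, so these
#: are package parameters, not ground truth.
DEFAULT_CLASS_MEANS = np.array(
    [
        [30.0, 13.0, 10.0, 8.0, 6.0],   # early responder
        [30.0, 24.0, 18.0, 13.0, 10.0],  # later responder
        [31.0, 29.0, 28.0, 29.0, 28.0],  # nonresponder, flat
        [30.0, 18.0, 15.0, 20.0, 26.0],  # nonresponder, relapse
    ]
)


class ConfigurationError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic cohort.

    Defaults follow the trial's reported design: 153 patients, 104
    controls, trajectory-class proportions 22.9/32.0/30.1/15.0%, MADRS
    inclusion threshold of 21 at week 0, age 18-61, 62.7% female,
    RIN 6-10.
    """

    n_patients: int = 153
    n_controls: int = 104
    class_proportions: tuple[float, float, float, float] = (0.229, 0.320, 0.301, 0.150)
    madrs_class_means: np.ndarray = field(default_factory=lambda: DEFAULT_CLASS_MEANS.copy())
    madrs_noise_sd: float = 3.0
    n_genes: int = 2000
    n_marker_genes: int = 4
    baseline_lfc_markers: float = 1.0   # log2 case-vs-control shift, all patient timepoints
    slope_effect: float = 0.1           # log2 expression per week, responder classes only
    dispersion_range: tuple[float, float] = (0.05, 0.5)
    subject_slope_sd: float = 0.05      # log2 units per week; idiosyncratic expression drift
    size_factor_log_sd: float = 0.15
    covariate_effect_sd: tuple[float, float, float] = (0.005, 0.10, 0.05)  # age, sex, RIN (log2 units)
    seed: int = 0

    def __post_init__(self) -> None:
        props = np.asarray(self.class_proportions, dtype=float)
        if props.shape != (4,) or np.any(props < 0):
            raise ConfigurationError("class_proportions must be 4 nonnegative fractions")
        if abs(props.sum() - 1.0) > 1e-12:
            raise ConfigurationError(f"class_proportions must sum to 1 (got {props.sum()!r})")
        means = np.asarray(self.madrs_class_means, dtype=float)
        if means.shape != (4, 5):
            raise ConfigurationError("madrs_class_means must be a 4x5 matrix")
        if np.any(means[:, 0] < 21):
            raise ConfigurationError("week-0 class means must be >= 21 (inclusion criterion)")
        if self.madrs_noise_sd < 0:
            raise ConfigurationError("madrs_noise_sd must be nonnegative")
        if self.n_patients <= 0 or self.n_controls <= 0 or self.n_genes <= 0:
            raise ConfigurationError("cohort sizes and n_genes must be positive")
        if not 0 <= self.n_marker_genes <= self.n_genes:
            raise ConfigurationError("n_marker_genes must be in [0, n_genes]")
        lo, hi = self.dispersion_range
        if lo <= 0 or hi < lo:
            raise ConfigurationError("dispersion_range lower bound must be > 0 and <= upper")
        if self.size_factor_log_sd < 0:
            raise ConfigurationError("size_factor_log_sd must be nonnegative")
        if self.subject_slope_sd < 0:
            raise ConfigurationError("subject_slope_sd must be nonnegative")


@dataclass
class CohortTables:
    """In-memory cohort: phenotypes, MADRS panel, count matrix and marker truth."""

    phenotypes: pd.DataFrame   # subject_id, group, true_class, age, sex, rin, anxiety, suicidality
    madrs: pd.DataFrame        # patients x weeks 0,2,4,6,8 (integers)
    counts: pd.DataFrame       # genes x samples; columns <subject>_T0/_T2/_T8 or <subject>_HC
    truth: pd.DataFrame        # marker gene ids with baseline lfc and class slope effects


def simulate_madrs(config: SimulationConfig, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Draw per-patient MADRS rows: class mean curve + iid Gaussian noise.

    Rows are rounded to integers and truncated to [0, 60]; week-0 values
    are additionally truncated to >= 21 to respect the inclusion criterion.

    Returns (madrs matrix n_patients x 5, true class labels).
    """
    classes = rng.choice(4, size=config.n_patients, p=np.asarray(config.class_proportions, dtype=float))
    means = np.asarray(config.madrs_class_means, dtype=float)[classes]
    noise = rng.normal(0.0, config.madrs_noise_sd, size=means.shape) if config.madrs_noise_sd > 0 else 0.0
    madrs = np.clip(np.rint(means + noise), 0, 60)
    madrs[:, 0] = np.maximum(madrs[:, 0], 21)
    labels = np.array([CLASS_NAMES[c] for c in classes])
    return madrs.astype(int), labels


def _simulate_phenotypes(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_patients + config.n_controls
    ids = [f"S{i + 1:04d}" for i in range(config.n_patients)] + [
        f"C{i + 1:04d}" for i in range(config.n_controls)
    ]
    group = ["patient"] * config.n_patients + ["control"] * config.n_controls
    return pd.DataFrame(
        {
            "subject_id": ids,
            "group": group,
            "age": rng.uniform(18, 61, size=n),
            "sex": rng.binomial(1, 0.627, size=n),  # female = 1
            "rin": rng.uniform(6, 10, size=n),
            "anxiety": rng.binomial(1, 0.497, size=n),
            "suicidality": rng.binomial(1, 0.752, size=n),
        }
    )


def simulate_counts(
    config: SimulationConfig,
    true_class: np.ndarray,
    phenotypes: pd.DataFrame,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """Draw the gene x sample negative-binomial count matrix.

    The log2 mean of gene g in sample j is

        base_g + subject random slope * week
               + marker shift (patients, all timepoints)
               + class slope * week (markers, patient samples)
               + covariate effects (age, sex, RIN)

    scaled by a lognormal per-sample size factor.  Counts are drawn
    gamma-Poisson: a per-gene, per-subject gamma multiplier with variance
    alpha_g (the gene's dispersion) is shared across that subject's
    timepoints, and counts are Poisson given the multiplier.  Marginally
    each sample is therefore exactly NB with variance mu + alpha*mu^2,
    while the shared multiplier gives repeated measures the stable
    within-subject correlation the downstream growth model assumes.

    Returns (counts, truth table, size factors).
    """
    if config.n_marker_genes > config.n_genes:
        raise ConfigurationError("n_marker_genes exceeds n_genes")
    genes = [f"G{i + 1:05d}" for i in range(config.n_genes)]
    marker_idx = rng.choice(config.n_genes, size=config.n_marker_genes, replace=False)
    is_marker = np.zeros(config.n_genes, dtype=bool)
    is_marker[marker_idx] = True

    base_log2 = rng.uniform(3.0, 9.0, size=config.n_genes)
    dispersion = rng.uniform(*config.dispersion_range, size=config.n_genes)
    beta_cov = np.column_stack(
        [rng.normal(0.0, sd, size=config.n_genes) for sd in config.covariate_effect_sd]
    )  # genes x (age, sex, rin)

    pats = phenotypes[phenotypes.group == "patient"].reset_index(drop=True)
    ctrls = phenotypes[phenotypes.group == "control"].reset_index(drop=True)

    sample_ids: list[str] = []
    sample_week: list[float] = []
    sample_is_patient: list[bool] = []
    sample_subject_row: list[int] = []
    for i in range(len(pats)):
        for w in EXPR_WEEKS:
            sample_ids.append(f"{pats.subject_id[i]}_T{w}")
            sample_week.append(float(w))
            sample_is_patient.append(True)
            sample_subject_row.append(i)
    for i in range(len(ctrls)):
        sample_ids.append(f"{ctrls.subject_id[i]}_HC")
        sample_week.append(0.0)
        sample_is_patient.append(False)
        sample_subject_row.append(i)

    week = np.array(sample_week)
    is_pat = np.array(sample_is_patient)
    subj_row = np.array(sample_subject_row)
    src = np.where(is_pat[:, None], pats[["age", "sex", "rin"]].values[subj_row * is_pat],
                   ctrls[["age", "sex", "rin"]].values[subj_row * ~is_pat])
    age = src[:, 0] - 39.5
    sex = src[:, 1].astype(float)
    rin = src[:, 2] - 8.0

    responder = np.isin(true_class, ("early_responder", "later_responder"))
    class_slope_sample = np.where(is_pat & responder[subj_row * is_pat], config.slope_effect, 0.0)

    # stable subject effect: gamma multiplier with variance alpha_g shared
    # across the subject's timepoints (gamma-Poisson = NB marginally)
    shape = (1.0 / dispersion)[:, None]
    u_pat = rng.gamma(shape, 1.0 / shape, size=(config.n_genes, len(pats)))
    u_ctl = rng.gamma(shape, 1.0 / shape, size=(config.n_genes, len(ctrls)))
    rand_slope = rng.normal(0.0, config.subject_slope_sd, size=(config.n_genes, len(pats)))
    u_sample = np.where(is_pat[None, :], u_pat[:, subj_row * is_pat], u_ctl[:, subj_row * ~is_pat])
    slope_effect_sample = np.where(
        is_pat[None, :], rand_slope[:, subj_row * is_pat] * week[None, :], 0.0
    )

    log2q = (
        base_log2[:, None]
        + slope_effect_sample
        + is_marker[:, None] * (config.baseline_lfc_markers * is_pat[None, :])
        + is_marker[:, None] * (class_slope_sample[None, :] * week[None, :])
        + beta_cov[:, 0:1] * age[None, :]
        + beta_cov[:, 1:2] * sex[None, :]
        + beta_cov[:, 2:3] * rin[None, :]
    )
    size_f = np.exp(rng.normal(0.0, config.size_factor_log_sd, size=len(sample_ids)))
    mu = size_f[None, :] * u_sample * np.exp2(log2q)
    counts = rng.poisson(mu)

    counts_df = pd.DataFrame(counts, index=pd.Index(genes, name="gene"), columns=sample_ids)
    truth = pd.DataFrame(
        {
            "gene": [genes[i] for i in sorted(marker_idx)],
            "baseline_lfc": config.baseline_lfc_markers,
            "slope_early_responder": config.slope_effect,
            "slope_later_responder": config.slope_effect,
        }
    )
    return counts_df, truth, size_f


def simulate_cohort(config: SimulationConfig, rng: np.random.Generator | None = None) -> CohortTables:
    """Generate a full synthetic cohort (phenotypes -> MADRS -> counts, one RNG stream)."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    phenotypes = _simulate_phenotypes(config, rng)
    madrs, true_class = simulate_madrs(config, rng)
    counts, truth, _ = simulate_counts(config, true_class, phenotypes, rng)

    pat_ids = phenotypes.loc[phenotypes.group == "patient", "subject_id"].values
    madrs_df = pd.DataFrame(
        madrs, index=pd.Index(pat_ids, name="subject_id"), columns=[f"week_{w}" for w in WEEKS]
    )
    phenotypes = phenotypes.copy()
    phenotypes["true_class"] = np.concatenate([true_class, np.array(["control"] * config.n_controls)])
    return CohortTables(phenotypes=phenotypes, madrs=madrs_df, counts=counts, truth=truth)


def write_cohort(tables: CohortTables, directory: str | Path) -> dict[str, Path]:
    """Write the cohort as delimited text (counts.tsv, phenotypes.csv, madrs.csv, truth.tsv)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": directory / "counts.tsv",
        "phenotypes": directory / "phenotypes.csv",
        "madrs": directory / "madrs.csv",
        "truth": directory / "truth.tsv",
    }
    tables.counts.to_csv(paths["counts"], sep="\t")
    tables.phenotypes.to_csv(paths["phenotypes"], index=False)
    tables.madrs.to_csv(paths["madrs"])
    tables.truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths


def config_to_dict(config: SimulationConfig) -> dict:
    d = dataclasses.asdict(config)
    d["madrs_class_means"] = np.asarray(config.madrs_class_means).tolist()
    return d
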