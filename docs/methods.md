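# Methods

This note documents the models, parameter choices and numerical decisions
behind `adtraj`, and what its synthetic-cohort tests do and do not show
about real data.

## Trajectory classification

Response is rule-based: with `ΔMADRS_t = MADRS_t / MADRS_0`, a subject is a
responder iff `ΔMADRS_8 ≤ 0.5` (boundary inclusive — "a 50% reduction"
includes the exact 50% case) and an *early* responder iff additionally
`ΔMADRS_2 ≤ 0.5`. Nonresponders are descriptively subtyped: *relapse* when
the MADRS nadir precedes week 8 and the score then rises by more than 20%
of baseline — our operationalization of a qualitatively described pattern —
else *flat*. Subtypes are merged for all analyses; the rule-based labels,
not cluster assignments, define the analysis groups, with longitudinal
k-means reported alongside for concordance.

The longitudinal k-means treats the five-week MADRS panel as a point in R^5
and runs Lloyd's algorithm (Euclidean distance). Determinism rules: distance
ties assign to the lowest-index centroid; an emptied cluster is re-seeded at
the point farthest from its current centroid (excluding points just used to
re-seed another cluster); restarts default to 50 with a mandatory seed, best
restart by inertia; k is selected by the Calinski–Harabasz criterion
`[B/(k−1)] / [W/(n−k)]`, with W = 0 reported as +inf.

## Normalization and screening funnel

Counts are normalized with median-of-ratios size factors
`s_j = median_g(c_gj / geomean_g)` over genes positive in every sample, log2
transformed with a pseudocount (default 1; the choice is exposed because the
analysis depends on it at low counts), and adjusted per timepoint for age,
sex and RIN by per-gene OLS residualization with the gene's grand mean added
back.

The baseline differential-expression stage is a negative binomial GLM
(`Var = μ + αμ²`) with log link, size factors as offsets and age/sex/RIN as
covariates, fitted by IRLS vectorized across genes. The per-gene dispersion
is estimated by maximizing the Cox–Reid adjusted profile likelihood
(`ℓ(α) − ½ log det(X'WX)`) by golden-section search on log α in
[1e−8, 10], alternating three times with the IRLS β updates from a
method-of-moments start. Inference is a Wald z on the group coefficient with
BH adjustment. This engine deliberately omits empirical-Bayes dispersion
shrinkage, LFC shrinkage, independent filtering and outlier replacement: the
pipeline's contribution is the funnel and the longitudinal modelling, and at
the cohort sizes involved (≥100 samples per group) per-gene ML dispersion is
adequate; bit-compatibility with any specific DE tool is a non-goal.
All-zero genes are reported with p = 1 and a flag rather than dropped.

Funnel order and thresholds (all configurable): (1) baseline DE, BH FDR
≤ 0.20; (2) after excluding genes with missing data at week 0 or 8, Pearson
correlation of expression with ΔMADRS_8 at p < 0.05; (3) exclusion of genes
whose *baseline* expression correlates with ΔMADRS_8 at p < 0.2 (retention
requires p ≥ 0.2). Criterion 2 uses the covariate-adjusted week-8 expression
level by default; the week-8 − week-0 change is available via
`criterion2_variable="delta"` since the defining phrase "correlation with
the change in MADRS at T8" does not pin down the expression variable.
ΔMADRS is always the week-8/week-0 ratio. Note an intrinsic ceiling:
criterion 3 discards genes with *null* baseline correlation at rate 0.2, so
even infinitely powered criteria 1–2 give expected marker recall ≤ 0.8.

## Latent growth model

Each RNA's adjusted log2 expression at weeks (0, 2, 8) follows
`y_i = Λη_i + ε_i`, `η_i ~ N(μ, Ψ)`, `ε_i ~ N(0, diag(θ))` with fixed
`Λ = [[1,0],[1,2],[1,8]]` (weeks as slope loadings; the association results
are invariant to rescaling the slope column, so the time unit is a
convention). The ML discrepancy

`F = ln|Σ| − ln|S| + tr(SΣ⁻¹) − 3 + (ȳ−μ_y)'Σ⁻¹(ȳ−μ_y)`, `Σ = ΛΨΛ' + diag(θ)`

is minimized by L-BFGS-B with an analytic gradient, parameterizing Ψ by its
Cholesky factor and θ by logs (bounds 1e−12…1e12) so Σ stays positive
definite; starts come from per-subject OLS growth coefficients
(method of moments). Nine observed moments minus eight parameters give
df = 1. `T = (n−1)·F` by default (Wishart convention; `n·F` exposed since
the convention of the original software is not documented). Near-singular
sample covariances (e.g. noise-free data) receive a 1e−8 relative ridge so
`ln|S|` stays finite; θ is then driven to the ridge scale and (μ, Ψ) to the
sample moments. Independence baseline for CFI/TLI: free means and
variances, zero covariances, closed form `F_b = ln|diag S| − ln|S|`,
df = 3.

Fit indices follow the standard definitions: CFI with the non-centrality
floored at 0, TLI capped at 1 when the baseline fits no worse than chance,
GFI = 1 − tr[(Σ̂⁻¹S − I)²]/tr[(Σ̂⁻¹S)²], RMSEA = √(max(T−df,0)/(df(n−1))),
SRMR over the six unique covariance entries standardized by √(s_ii s_jj)
(mean residuals excluded; the mean structure is near-saturated here). The
conventional cut-offs (indices > 0.90 good; RMSEA/SRMR < 0.08 good) are
reported, not enforced.

Factor scores use the regression method `η̂ = μ + ΨΛ'Σ⁻¹(y − Λμ)`; the
slope score is z-scored across subjects (sample SD) so association effects
are per 1 SD of slope. Shrinkage means `Var(slope score) ≤ ψ_ss`.

## Three-step association

Step 1 fits, per RNA, a binary logistic regression of responder status on
that RNA's intercept score and standardized slope score; the slope Wald
p < 0.05 gates advancement (the intercept is reported but not gating).
Intercept scores are centered for conditioning. A boundary growth fit with
rank-1 Ψ makes the two scores exactly collinear; the redundant intercept
column is then dropped (flagged `intercept_dropped`). Probable perfect
separation (|coef| > 20 or non-convergence after a BFGS retry) excludes the
RNA with a flag.

Step 2 fits one binary logistic model with all advancing RNAs' slopes plus
age, sex (female = 1), anxiety history and suicidality. Step 3 fits one
multinomial model (early/later/nonresponder, nonresponders as base) with
the same predictors via Newton–Raphson ML. Joint models include slopes only
(intercepts optional via `include_intercepts_joint`), since only slope risk
ratios are scientifically interpreted. Risk ratios are `exp(b)` with Wald
95% CIs using the normal quantile 1.96. BH FDR is applied over the family
of all slope tests — advancing RNAs × 3 contrasts, pooling the binary and
both multinomial contrasts; with 8 RNAs this gives the family of 24 whose
BH minimum (≈0.024) matches the published FDR column, which a family of 8
does not. The family size and membership are emitted for auditability.

## Synthetic cohort generator

The generator defines the study conditions for all simulation tests.
MADRS: four latent classes with proportions (0.229, 0.320, 0.301, 0.150) —
early responder, later responder, flat nonresponder, relapse nonresponder —
each a mean curve (defaults chosen to reproduce the published qualitative
shapes; no numeric curves are printed, so these are package parameters)
plus iid N(0, 3²) noise, rounded, truncated to [0, 60] and to ≥21 at week 0
(the trial's inclusion criterion). Covariates: age ~ U(18, 61),
sex ~ Bernoulli(0.627) (female), RIN ~ U(6, 10), anxiety ~ Bernoulli(0.497),
suicidality ~ Bernoulli(0.752) — the cohort's reported ranges and rates.

Counts are gamma-Poisson: gene g in subject i gets a stable multiplier
`u_gi ~ Gamma(1/α_g, α_g)` (mean 1, variance α_g) shared across the
subject's timepoints, and counts are Poisson with mean
`s_j · u_gi · 2^{log2 q_gj}`. Marginally each sample is therefore *exactly*
NB with dispersion α_g ~ U(0.05, 0.5), which keeps the NB Wald test's null
calibration testable, while the shared multiplier supplies the stable
inter-individual variation — i.e. the latent intercept variance — that the
growth model assumes; without it the true Ψ is singular and the
intercept+slope factor scores are perfectly collinear, so no data resembling
the real analysis could be generated. A normal per-subject random slope
(SD 0.05 log2/week) adds idiosyncratic drift. The mean model `log2 q`
contains the gene baseline (U(3, 9)), a +1 log2 case-control shift for
marker genes at every patient timepoint, a class slope of +0.1 log2/week for
marker genes in responder classes only (zero at week 0, so criterion 3 is
satisfiable), and small gene-specific covariate effects
(SDs 0.005/age-year, 0.10/sex, 0.05/RIN unit). Size factors are lognormal
(log SD 0.15). One RNG stream is used in the fixed order phenotypes → MADRS
→ counts, so identical seeds give byte-identical cohorts.

What the generator does *not* emulate: batch or site effects, library-prep
covariance between genes, count outliers, heavy-tailed dispersion, missing
visits, dropout, or treatment-arm structure. Passing tests therefore
demonstrate correctness of the statistical machinery under the assumed
model, not robustness to real-data pathologies.

## Simulation scales and numerical choices

Simulation test sizes were chosen as the smallest that make the assertions
statistically sharp: growth-model recovery at n = 5000 × 10 replicates
(every parameter within 3 Monte-Carlo SEs; θ at week 8 has the largest
sampling variance because of the leverage of t = 8); null operating
characteristics on 150 patients × 2000 genes × 3 replicates (NB Wald type-I
and step-1 advance rates pooled over 6000 tests, both expected in
[0.03, 0.07]); end-to-end power with 4 markers among 32 candidates drawn
from a 500-gene transcriptome at n = 1000 × 5 replicates. The candidates
are embedded in a larger simulated transcriptome because median-of-ratios
factors estimated from only 32 genes are noisy and biased by the markers
themselves — as they would be in any real analysis, normalization uses the
full matrix. In the power setting all 4 markers reach FDR < 0.05 in every
replicate while false positives average ≤1 per replicate; the residual
false positives are inherent to the design (step-1 selection plus BH's
proportional control when many true discoveries are present), with the
per-gene null z statistics verified calibrated.

Other numerics: NB IRLS caps the linear predictor at ±30 and adds a 1e−10
ridge to X'WX so degenerate genes (a group of all zeros) remain solvable;
golden-section dispersion search uses 40 iterations; the LGM convergence
tolerance is ftol = 1e−12 with at most 500 iterations; BH is computed by
statsmodels' step-up implementation. BH is not idempotent (re-adjusting
adjusted values changes them); the tests assert dominance and
rank-monotonicity instead. Chi-square tests on contingency tables use no
continuity correction — this convention reproduces the published cohort
table's p-values — with Fisher's exact test reserved for 2×2 tables.

## Known limitations

Three timepoints permit only linear growth (no quadratic or piecewise
trajectories) and leave df = 1 for model fit. Missing data are handled by
complete-case analysis, not FIML. The two-step use of factor scores (fit
growth model, then regress on scores) ignores score-estimation uncertainty;
a one-step structural model would propagate it but is not what the
published analysis describes. The DE engine's inference at small n (< 10
per group) is anticonservative without dispersion shrinkage; the pipeline's
intended regime is ≥50 samples per group.
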