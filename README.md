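# adtraj

Trajectory-based discovery of **treatment-emergent** peripheral gene-expression
markers of antidepressant response.

## The problem

In an 8-week escitalopram trial (CAN-BIND-1 design), depression severity is
measured with the Montgomery–Åsberg Depression Rating Scale (MADRS) at weeks
0, 2, 4, 6 and 8, and blood RNA-seq is collected at weeks 0, 2 and 8, together
with baseline-only healthy controls. The scientific question is not *which
baseline markers predict response* but *which RNAs change during treatment in
a way that tracks response* — mediators that could monitor treatment efficacy
within weeks of initiation. `adtraj` implements that analysis end to end for
researchers working with longitudinal clinical + expression cohorts:

1. **Trajectory classification.** A responder shows ≥50% MADRS reduction at
   week 8 (ratio `ΔMADRS = MADRS_T8 / MADRS_T0 ≤ 0.5`); early responders meet
   the criterion already at week 2. Longitudinal k-means with the
   Calinski–Harabasz criterion describes the trajectory groups.
2. **Screening funnel.** RNAs are retained when they are (i) differentially
   expressed patients-vs-controls at baseline (negative-binomial GLM Wald
   test with median-of-ratios normalization, BH FDR ≤ 20%), (ii) correlated
   with ΔMADRS at week 8 (Pearson p < 0.05), and (iii) **not** correlated
   with ΔMADRS at baseline (p ≥ 0.2).
3. **Latent growth model.** Each selected RNA's adjusted log2 expression
   y ~ N(Λη, ΛΨΛ′ + Θ) with loadings Λ = [1, t] at weeks t = 0, 2, 8: a random
   intercept and a random slope per subject, fitted by maximum likelihood,
   with χ², CFI, TLI, GFI, RMSEA and SRMR fit indices and regression-method
   factor scores.
4. **Three-step association.** Per-RNA logistic screen of responder status on
   intercept + slope; joint multivariable logistic; joint multinomial
   (early / later / nonresponder, nonresponders as base) adjusted for age,
   sex, anxiety history and suicidality. Slope effects are reported as risk
   ratios per 1 SD of slope with Wald 95% CIs and BH FDR.
5. **Supporting statistics** for cohort tables (χ², Fisher, ANOVA), postmortem
   brain case-control tests (t, ANOVA + Tukey) and in-vitro qPCR
   (2^−ΔΔCt + Dunnett).

Because the underlying clinical data are not publicly deposited, the package
ships a **synthetic cohort generator** with the statistical structure the
analysis assumes (four MADRS trajectory classes; gamma-Poisson counts that
are marginally negative binomial with per-sample size factors, covariate
effects, and marker genes with class-specific expression slopes), so every
stage is testable.

## Worked example

```python
import numpy as np
from adtraj import (SimulationConfig, simulate_cohort, classify_cohort,
                    screen_cohort, run_three_step)
from adtraj.growth import fit_gene_panel

cohort = simulate_cohort(SimulationConfig(n_patients=400, n_genes=400,
                                          n_marker_genes=3, seed=5))
labels = classify_cohort(cohort.madrs)
print(labels.label.value_counts().to_dict())
# {'nonresponder': 194, 'later_responder': 135, 'early_responder': 71}

screen = screen_cohort(cohort.counts, cohort.phenotypes, labels)
print(screen.stage_counts)
# {'universe': 400, 'criterion1_de': 3, 'not_missing': 3,
#  'criterion2_corr_t8': 3, 'criterion3_no_baseline_corr': 3}

markers = sorted(cohort.truth.gene)                       # ['G00004', 'G00089', 'G00159']
nulls = [g for g in cohort.counts.index if g not in set(markers)]
candidates = markers + list(np.random.default_rng(5).choice(nulls, 13, replace=False))
_, table, intercepts, slopes = fit_gene_panel(screen.adjusted_expression, candidates)
assoc = run_three_step(intercepts, slopes, labels,
                       cohort.phenotypes.set_index("subject_id"))
print(assoc.table[assoc.table.fdr < 0.05]
      [["gene", "contrast", "rr", "ci_low", "ci_high", "fdr"]].round(3).head(3))
#      gene          contrast     rr  ci_low  ci_high  fdr
# 0  G00004  responders_vs_nr  5.170   2.856    9.358  0.0
# 1  G00089  responders_vs_nr  4.556   2.582    8.041  0.0
# 2  G00159  responders_vs_nr  8.524   4.465   16.274  0.0
```

The label split follows the generator's 22.9 / 32.0 / 45.1% trajectory-class
design; the funnel retains exactly the three simulated markers out of 400
genes. In the association table, `rr` is the multiplicative change in the
odds of being an (early/later) responder versus nonresponder per 1 SD
increase in that RNA's expression slope, and `fdr` is the BH-adjusted Wald p
over all slope tests — here all three markers (and no null RNA) reach
FDR < 0.05 in every contrast. The scripts in `examples/` walk through each
capability with commentary.

A thin CLI mirrors the library: `adtraj simulate | classify | kml | screen |
growth | associate | tablestats | ddct | run` (see `adtraj --help`).

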