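"""Published summary statistics from the CAN-BIND-1 escitalopram trial analysis.

The underlying clinical and sequencing data are not publicly deposited,
but the published analysis prints group-comparison tables and the
multinomial risk-ratio table for the eight slope-associated RNAs.  Those
printed numbers are inputs for validation: the package's statistics,
recomputed from them, should match the printed values at their printed
precision.

``TABLE1_CATEGORICAL`` holds 2 x 3 contingency tables (trait present /
absent by nonresponder / later responder / early responder) with the
printed chi-square p-values; ``TABLE1_AGE`` the per-group age summaries;
``TABLE2`` the printed log risk ratio, SE, p and FDR per RNA and contrast
(risk ratios per 1 SD of RNA slope, nonresponders as base category).
"""

from __future__ import annotations

import pandas as pd

# group sizes: nonresponders 69, later responders 49, early responders 35
GROUP_NS = {"nonresponder": 69, "later_responder": 49, "early_responder": 35}

#: trait -> ([[with NR, with LR, with ER], [without NR, without LR, without ER]], printed p)
TABLE1_CATEGORICAL: dict[str, tuple[list[list[int]], float]] = {
    "female_sex": ([[41, 29, 26], [28, 20, 9]], 0.274),
    "anxiety_history": ([[30, 28, 18], [39, 21, 17]], 0.334),
    "gad": ([[19, 8, 8], [50, 41, 27]], 0.360),
    "social_phobia": ([[10, 19, 5], [59, 30, 30]], 0.003),
    "suicidality": ([[47, 41, 27], [22, 8, 8]], 0.149),
}

#: age: (n, mean, sd) per response group, printed ANOVA p = 0.762
TABLE1_AGE = {
    "summaries": [(69, 36.12, 13.05), (49, 36.55, 11.90), (35, 34.57, 12.39)],
    "p": 0.762,
}

_TABLE2_ROWS = [
    # contrast, gene, log_rr, se, p, fdr, rr, ci_low, ci_high
    ("responders_vs_nr", "BET1", 0.776, 0.471, 0.100, 0.159, 2.17, 0.86, 5.47),
    ("responders_vs_nr", "CERCAM", 1.064, 0.323, 0.001, 0.023, 2.90, 1.54, 5.46),
    ("responders_vs_nr", "DARS-AS1", -0.817, 0.387, 0.035, 0.076, 0.44, 0.21, 0.94),
    ("responders_vs_nr", "FAM228B", 1.079, 0.430, 0.012, 0.041, 2.94, 1.27, 6.83),
    ("responders_vs_nr", "HBEGF", 0.748, 0.340, 0.028, 0.066, 2.11, 1.09, 4.11),
    ("responders_vs_nr", "MCM8", 0.563, 0.303, 0.063, 0.116, 1.76, 0.97, 3.18),
    ("responders_vs_nr", "NME7", 0.259, 0.302, 0.392, 0.450, 1.30, 0.72, 2.34),
    ("responders_vs_nr", "TERF1", 0.095, 0.382, 0.803, 0.803, 1.10, 0.52, 2.32),
    ("early_vs_nr", "BET1", 0.659, 0.368, 0.073, 0.125, 1.93, 0.94, 3.97),
    ("early_vs_nr", "CERCAM", 0.794, 0.260, 0.002, 0.023, 2.21, 1.33, 3.68),
    ("early_vs_nr", "DARS-AS1", -0.879, 0.309, 0.004, 0.023, 0.42, 0.23, 0.76),
    ("early_vs_nr", "FAM228B", 0.814, 0.340, 0.017, 0.050, 2.26, 1.16, 4.40),
    ("early_vs_nr", "HBEGF", 0.799, 0.282, 0.005, 0.023, 2.22, 1.28, 3.87),
    ("early_vs_nr", "MCM8", 0.333, 0.244, 0.173, 0.244, 1.40, 0.86, 2.25),
    ("early_vs_nr", "NME7", 0.297, 0.240, 0.217, 0.289, 1.35, 0.84, 2.15),
    ("early_vs_nr", "TERF1", 0.211, 0.296, 0.476, 0.497, 1.24, 0.69, 2.21),
    ("later_vs_nr", "BET1", 0.632, 0.396, 0.110, 0.165, 1.88, 0.87, 4.09),
    ("later_vs_nr", "CERCAM", 0.647, 0.287, 0.024, 0.065, 1.91, 1.09, 3.35),
    ("later_vs_nr", "DARS-AS1", -0.920, 0.342, 0.007, 0.028, 0.40, 0.20, 0.78),
    ("later_vs_nr", "FAM228B", 0.695, 0.371, 0.061, 0.116, 2.00, 0.97, 4.15),
    ("later_vs_nr", "HBEGF", 0.888, 0.315, 0.005, 0.023, 2.43, 1.31, 4.51),
    ("later_vs_nr", "MCM8", 0.228, 0.267, 0.394, 0.450, 1.26, 0.74, 2.12),
    ("later_vs_nr", "NME7", 0.296, 0.266, 0.265, 0.335, 1.34, 0.80, 2.26),
    ("later_vs_nr", "TERF1", 0.244, 0.328, 0.456, 0.497, 1.28, 0.67, 2.43),
]

TABLE2 = pd.DataFrame(
    _TABLE2_ROWS,
    columns=["contrast", "gene", "log_rr", "se", "p", "fdr", "rr", "ci_low", "ci_high"],
)

#: the four RNAs whose slope independently predicted response status
SIGNIFICANT_RNAS = ("CERCAM", "DARS-AS1", "FAM228B", "HBEGF")
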