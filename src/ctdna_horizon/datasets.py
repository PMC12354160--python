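"""Published benchmark values bundled as reference inputs.

Summary statistics of a prospective multicancer early-detection cohort
(26 cancer cases, 26 matched controls; plasma drawn ~0.4-3.7 months before
diagnosis at the Early timepoint and ~3.1-3.5 years before at the Very Early
timepoint). These printed numbers are inputs for worked examples and
benchmark arithmetic — sensitivity with its Wilson interval, MAF
fold-changes and detected-mutation fractions — not outputs of this package.
MAFs are percentages as printed; ``None`` marks "Mutation not detectable" /
"Sample not available".
"""

from __future__ import annotations

#: Early-positive participants: per-timepoint mean MAF (%) and days to
#: diagnosis; ratio is the printed Early / Very Early MAF fold.
REFERENCE_POSITIVES = [
    {"participant": "INDIA 2206", "cancer": "Rectal", "stage": "III",
     "days_early": 96, "maf_early_pct": 4.31,
     "days_very_early": 1208, "maf_very_early_pct": None, "ratio": None},
    {"participant": "INDIA 2207", "cancer": "Liver", "stage": "Unknown",
     "days_early": 84, "maf_early_pct": 2.04,
     "days_very_early": 1230, "maf_very_early_pct": 0.05, "ratio": 39.7},
    {"participant": "INDIA 2210", "cancer": "Colon", "stage": "II",
     "days_early": 104, "maf_early_pct": 0.33,
     "days_very_early": 1270, "maf_very_early_pct": None, "ratio": None},
    {"participant": "INDIA 2215", "cancer": "Pancreatic", "stage": "Unknown",
     "days_early": 20, "maf_early_pct": 3.37,
     "days_very_early": None, "maf_very_early_pct": None, "ratio": None},
    {"participant": "INDIA 2225", "cancer": "Colon", "stage": "Unknown",
     "days_early": 30, "maf_early_pct": 2.50,
     "days_very_early": 1117, "maf_very_early_pct": 0.05, "ratio": 50.0},
    {"participant": "INDIA 2228", "cancer": "Lung", "stage": "Unknown",
     "days_early": 112, "maf_early_pct": 26.26,
     "days_very_early": 1197, "maf_very_early_pct": 0.33, "ratio": 79.2},
    {"participant": "INDIA 2233", "cancer": "Colon", "stage": "I",
     "days_early": 12, "maf_early_pct": 1.39,
     "days_very_early": 1117, "maf_very_early_pct": 0.16, "ratio": 8.6},
    {"participant": "INDIA 2245", "cancer": "Breast", "stage": "Unknown",
     "days_early": 47, "maf_early_pct": 13.40,
     "days_very_early": 1139, "maf_very_early_pct": None, "ratio": None},
]

#: positives among cancer cases at the Early timepoint
SENSITIVITY_COUNTS = (8, 26)

#: lung case, targeted-panel MAFs (%) at Early vs Very Early (115-fold drop)
TARGETED_FOLD_EXAMPLE_PCT = (11.2, 0.097)

#: bona-fide personalized-panel mutations detected at Very Early
#: (detected, assessed) per participant
PERSONALIZED_DETECTED_COUNTS = {
    "INDIA 2228": (90, 92),
    "INDIA 2225": (24, 30),
    "INDIA 2207": (12, 19),
    "INDIA 2233": (4, 21),
}
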