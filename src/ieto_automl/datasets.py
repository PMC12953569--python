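"""Published summary-level data from the Tibetan healthcare-seeking survey.

The multi-center survey behind this package (1,879 residents, seven public
hospitals, 2024-2025) did not deposit record-level data; what is public are
the baseline-characteristics comparisons between the training and testing
splits (group means/SDs for continuous variables, 2x2 counts for binary
ones) and the cross-validated classifier metric tables. Those printed
summaries are reproduced here so that the cohort-statistics and
metric-identity routines can be exercised against them directly.
"""

from __future__ import annotations

N_TOTAL = 1879
N_DELAYED = 789
N_TRAIN = 1503
N_TEST = 376

# Continuous baseline variables: (train mean, train sd, test mean, test sd)
BASELINE_CONTINUOUS = {
    "age": (48.52, 11.32, 47.81, 12.91),
    "dist_village": (1.06, 0.25, 1.09, 0.33),
    "dist_township": (4.03, 1.23, 4.15, 1.17),
    "dist_county": (21.62, 5.87, 21.53, 6.01),
    "township_quality": (8.18, 2.45, 7.95, 2.06),
    "county_quality": (9.13, 3.01, 9.28, 2.95),
}

# Binary baseline variables: counts (train yes, train no, test yes, test no),
# "yes" being the first printed level (male / above-primary excluded: for
# gender the first level is male, for education "primary school or below").
BASELINE_BINARY = {
    "gender": (654, 849, 153, 223),
    "education": (592, 911, 147, 229),
    "occupation": (718, 785, 162, 214),
    "chinese_communication": (1127, 376, 287, 89),
    "financial_difficulty": (653, 850, 181, 195),
    "chronic_disease": (706, 797, 183, 193),
    "symptom_severity": (613, 890, 152, 224),
    "musculoskeletal": (265, 1238, 69, 307),
    "cardiopulmonary": (506, 997, 131, 245),
    "gastrointestinal": (246, 1257, 69, 307),
    "neurological": (189, 1314, 48, 328),
}


def pooled_proportion(variable: str) -> float:
    """Whole-cohort proportion of the first level of a binary variable."""
    a, b, c, d = BASELINE_BINARY[variable]
    return (a + c) / (a + b + c + d)


# Classifier metric rows (PRE, SEN, SPE, ACC, F1, ROC-AUC, PR-AUC) as
# printed for the cross-validated training evaluation ...
TRAINING_METRICS = {
    "LR": (0.6659, 0.8672, 0.3486, 0.6595, 0.7533, 0.7381, 0.8004),
    "KNN": (0.7388, 0.9389, 0.5032, 0.7644, 0.8269, 0.7488, 0.8207),
    "AdaBoost": (0.7368, 0.9557, 0.4890, 0.7688, 0.8321, 0.8918, 0.9311),
    "XGBoost": (0.7986, 0.9357, 0.6467, 0.8200, 0.8617, 0.8989, 0.9311),
    "LightGBM": (0.8225, 0.8641, 0.7208, 0.8067, 0.8428, 0.8732, 0.8939),
    "AutoML": (0.8922, 0.9589, 0.8265, 0.9059, 0.9243, 0.9563, 0.9559),
}

# ... and for the held-out testing evaluation.
TESTING_METRICS = {
    "LR": (0.7099, 0.8631, 0.4516, 0.7020, 0.7790, 0.7642, 0.8206),
    "SVM": (0.6950, 0.9170, 0.3742, 0.7045, 0.7907, 0.6847, 0.6459),
    "AdaBoost": (0.7412, 0.9627, 0.4774, 0.7727, 0.8375, 0.8780, 0.9160),
    "XGBoost": (0.8014, 0.9378, 0.6387, 0.8207, 0.8642, 0.8821, 0.9055),
    "LightGBM": (0.7955, 0.8714, 0.6516, 0.7854, 0.8317, 0.8430, 0.8863),
    "AutoML": (0.8582, 0.9295, 0.7613, 0.8636, 0.8924, 0.9196, 0.9313),
}

METRIC_NAMES = ("PRE", "SEN", "SPE", "ACC", "F1", "ROC_AUC", "PR_AUC")
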