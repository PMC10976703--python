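"""Default study parameters for the synthetic cohort generator.

The defaults encode the published group statistics of a four-group memory-clinic
cohort (cognitively normal controls, MCI non-converters, MCI converters, and
AD dementia patients): regional FDG-PET SUVr distributions, demographics and
baseline cognition, conversion/observation intervals, and the group-by-visit
trajectory coefficients of the longitudinal marginal (GEE) model.

All SUVr values are pons-referenced ratios (dimensionless); cognition is MMSE
(0-30 points) and CASI total (0-100 points); intervals are in years.
"""

from __future__ import annotations

# Diagnostic groups: cognitively normal, MCI non-converter, MCI converter, AD dementia.
GROUPS = ("CN", "MCI_NC", "MCI_C", "AD")

# The seven signet VOIs of the individual-based analysis.
VOI_NAMES = (
    "FRONTAL",
    "PARIETAL",
    "MTL",
    "LAT_TEMPORAL",
    "PCC",
    "PRECUNEUS",
    "OCCIPITAL",
)

# Published group sizes (n controls, n MCI-NC, n MCI-C, n AD).
DEFAULT_GROUP_SIZES = {"CN": 40, "MCI_NC": 38, "MCI_C": 44, "AD": 42}

# Baseline FDG-PET SUVr, mean +/- SD per (group, VOI), pons reference.
REGIONAL_SUVR = {
    ("CN", "FRONTAL"): (1.41, 0.10),
    ("CN", "MTL"): (1.10, 0.07),
    ("CN", "LAT_TEMPORAL"): (1.40, 0.12),
    ("CN", "PCC"): (1.61, 0.13),
    ("CN", "PRECUNEUS"): (1.61, 0.12),
    ("CN", "PARIETAL"): (1.50, 0.10),
    ("CN", "OCCIPITAL"): (1.60, 0.11),
    ("MCI_NC", "FRONTAL"): (1.45, 0.04),
    ("MCI_NC", "MTL"): (1.06, 0.05),
    ("MCI_NC", "LAT_TEMPORAL"): (1.38, 0.04),
    ("MCI_NC", "PCC"): (1.60, 0.20),
    ("MCI_NC", "PRECUNEUS"): (1.61, 0.05),
    ("MCI_NC", "PARIETAL"): (1.49, 0.04),
    ("MCI_NC", "OCCIPITAL"): (1.59, 0.05),
    ("MCI_C", "FRONTAL"): (1.35, 0.06),
    ("MCI_C", "MTL"): (0.91, 0.07),
    ("MCI_C", "LAT_TEMPORAL"): (1.23, 0.08),
    ("MCI_C", "PCC"): (1.37, 0.14),
    ("MCI_C", "PRECUNEUS"): (1.48, 0.09),
    ("MCI_C", "PARIETAL"): (1.36, 0.08),
    ("MCI_C", "OCCIPITAL"): (1.56, 0.08),
    ("AD", "FRONTAL"): (1.30, 0.07),
    ("AD", "MTL"): (0.86, 0.02),
    ("AD", "LAT_TEMPORAL"): (1.19, 0.11),
    ("AD", "PCC"): (1.20, 0.07),
    ("AD", "PRECUNEUS"): (1.31, 0.08),
    ("AD", "PARIETAL"): (1.21, 0.06),
    ("AD", "OCCIPITAL"): (1.39, 0.12),
}

# Demographics and baseline cognition per group:
# age (mean, sd) years; male fraction; education (mean, sd) years;
# APOE e4 carrier fraction; MMSE (mean, sd); CASI total (mean, sd);
# clinical follow-up (mean, sd) years.
DEMOGRAPHICS = {
    "CN": {
        "age": (62.6, 11.6),
        "male_fraction": 23 / 40,
        "education": (13.6, 3.7),
        "apoe4_fraction": 0.238,
        "mmse": (28.1, 2.1),
        "casi": (92.6, 6.1),
        "followup": (4.4, 1.8),
    },
    "MCI_NC": {
        "age": (72.1, 7.60),
        "male_fraction": 15 / 38,
        "education": (6.9, 5.0),
        "apoe4_fraction": 0.378,
        "mmse": (23.5, 4.36),
        "casi": (77.84, 13.9),
        "followup": (6.4, 3.8),
    },
    "MCI_C": {
        "age": (74.7, 7.04),
        "male_fraction": 19 / 44,
        "education": (7.1, 4.9),
        "apoe4_fraction": 0.609,
        "mmse": (21.8, 3.7),
        "casi": (74.9, 12.2),
        "followup": (6.7, 3.6),
    },
    "AD": {
        "age": (77.0, 7.6),
        "male_fraction": 21 / 42,
        "education": (7.5, 5.3),
        "apoe4_fraction": 0.579,
        "mmse": (17.4, 2.9),
        "casi": (63.1, 15.3),
        "followup": (6.6, 3.2),
    },
}

# Time from the baseline scan to dementia conversion in converters:
# truncated normal, mean/SD as reported, bounds equal to the reported range.
CONVERSION_INTERVAL = {"mean": 3.70, "sd": 1.68, "low": 1.0, "high": 8.0}

# Observation time after the baseline scan in non-converters.
NONCONVERTER_FOLLOWUP = {"mean": 4.34, "sd": 1.26, "low": 2.0, "high": 7.0}

# Marginal-model (GEE) coefficients used by the trajectory generator.
# Group-by-visit offsets relative to the subject's baseline score;
# visit 1 is the reference (offset 0) and controls have no drift.
TRAJECTORY_OFFSETS_MMSE = {
    "CN": (0.0, 0.0, 0.0, 0.0, 0.0, 0.0),
    "AD": (0.0, -0.847, -1.020, -2.256, -3.004, -5.325),
    "MCI_C": (0.0, -0.339, -0.888, -1.990, -2.730, -5.116),
    "MCI_NC": (0.0, -0.687, 0.557, -0.076, -0.237, -1.206),
}
TRAJECTORY_OFFSETS_CASI = {
    "CN": (0.0, 0.0, 0.0, 0.0, 0.0, 0.0),
    "AD": (0.0, -1.573, -3.177, -8.341, -15.092, -21.842),
    "MCI_C": (0.0, -1.260, -2.628, -7.282, -15.957, -22.565),
    "MCI_NC": (0.0, -1.890, 4.240, 0.248, -2.682, -8.594),
}

# Demographic main effects on cognition (score points per unit).
COVARIATE_EFFECTS = {
    "MMSE": {"education_years": 0.415, "male": 1.198},
    "CASI": {"education_years": 1.376, "male": 4.694},
}

# Dementia is operationalized as MMSE falling below this score.
DEMENTIA_MMSE_THRESHOLD = 20

# Hypometabolism call: Z below this threshold (strict).
Z_THRESHOLD = -2.0
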