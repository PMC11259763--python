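"""Fixed column schema shared by the cohort generator and the preprocessing stage.

The feature set is 19 clinical variables: age, sex, BMI, 13 preoperative
laboratory values, surgery type, anesthesia type and an emergency-surgery
flag; the outcome is binary 30-day in-hospital mortality.
"""

from __future__ import annotations

#: 13 preoperative laboratory features, in canonical order.
LABS: list[str] = [
    "wbc",      # white blood cells, 10^3/uL
    "hb",       # hemoglobin, g/dL
    "plt",      # platelets, 10^3/uL
    "na",       # sodium, mmol/L
    "k",        # potassium, mmol/L
    "bun",      # blood urea nitrogen, mg/dL
    "cr",       # creatinine, mg/dL
    "alb",      # albumin, g/dL
    "got",      # aspartate transaminase, IU/L
    "gpt",      # alanine transaminase, IU/L
    "glu",      # glucose, mg/dL
    "pt_inr",   # prothrombin time, INR
    "aptt",     # activated partial thromboplastin time, s
]

#: 15 continuous features (standardized before modelling).
CONT_FEATURES: list[str] = ["age", "bmi"] + LABS

SURGERY_CATEGORIES: list[str] = [
    "general",
    "otolaryngologic",
    "urologic",
    "orthopedic",
    "gynecological",
    "plastic",
    "other",
]

ANESTHESIA_CATEGORIES: list[str] = [
    "general",
    "neuroaxial",
    "mac",
    "regional",
    "other",
]

SEX_CATEGORIES: list[str] = ["female", "male"]

#: categorical feature -> fixed vocabulary
CATEGORICAL_VOCABS: dict[str, list[str]] = {
    "sex": SEX_CATEGORIES,
    "surgery_type": SURGERY_CATEGORIES,
    "anesthesia_type": ANESTHESIA_CATEGORIES,
}

#: binary 0/1 features kept as single columns
BINARY_FEATURES: list[str] = ["emergency"]

#: raw cohort CSV column order (fixed external contract)
COLUMNS: list[str] = (
    ["age", "sex", "bmi"]
    + LABS
    + ["surgery_type", "anesthesia_type", "emergency", "outcome", "site"]
)

FEATURE_COLUMNS: list[str] = [c for c in COLUMNS if c not in ("outcome", "site")]


def encoded_columns() -> list[str]:
    """Model-matrix column order: standardized continuous features, a single
    female indicator, full one-hot groups for surgery and anesthesia (no
    reference category dropped), then the emergency flag.  p = 29."""
    cols = list(CONT_FEATURES)
    cols.append("sex")
    cols += [f"surgery_{c}" for c in SURGERY_CATEGORIES]
    cols += [f"anesthesia_{c}" for c in ANESTHESIA_CATEGORIES]
    cols.append("emergency")
    return cols


ENCODED_COLUMNS: list[str] = encoded_columns()
N_ENCODED: int = len(ENCODED_COLUMNS)

#: laboratory panels measured together; lab pairs within a block are given a
#: strong positive correlation by the generator
LAB_BLOCKS: list[list[str]] = [
    ["wbc", "hb", "plt"],            # complete blood count
    ["na", "k", "bun", "cr"],        # chemistry / renal panel
    ["alb", "got", "gpt"],           # liver panel
    ["pt_inr", "aptt"],              # coagulation panel
]
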