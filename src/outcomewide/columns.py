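"""Column-name contract shared by every module.

All panels are long-format pandas DataFrames with one row per respondent.
Wave-2 variables carry a ``_w2`` suffix; Wave-1 variables either carry
``_w1`` (items also measured at Wave 2) or no suffix (demographics and
retrospective childhood items, which are measured once).
"""

COUNTRY = "country"
RESPONDENT = "respondent_id"
STRATUM = "stratum_id"
PSU = "psu_id"
WEIGHT = "sampling_weight"
RETAINED = "retained"
ATTRITION_WEIGHT = "attrition_weight"
ANALYSIS_WEIGHT = "analysis_weight"

#: Wave-1 demographic covariates (Model 1 block, first part).
DEMOGRAPHICS = [
    "age",
    "gender",
    "education",
    "employed",
    "married",
    "urban",
    "income_quintile",
    "immigrant",
    "religious_attendance",
]

#: Retrospective childhood covariates (Model 1 block, second part).
CHILDHOOD = [
    "mother_relationship",
    "father_relationship",
    "parents_married_age12",
    "abused_growing_up",
    "outsider_growing_up",
    "health_growing_up",
    "financial_status_growing_up",
    "religious_attendance_age12",
]

MODEL1_COVARIATES = DEMOGRAPHICS + CHILDHOOD

#: Focal exposure single item, four ordered categories 1..4
#: (never / rarely / often / always).
EXPOSURE_ITEM = "mastery_w1"

EXPOSURE_CATEGORIES = ["never", "rarely", "often", "always"]

CONFOUNDER_PREFIX = "conf_"
PC_PREFIX = "pc_"
WAVE2_SUFFIX = "_w2"


def confounder_columns(n: int) -> list[str]:
    return [f"{CONFOUNDER_PREFIX}{i + 1:02d}" for i in range(n)]


def outcome_column(name: str) -> str:
    return f"{name}{WAVE2_SUFFIX}"
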