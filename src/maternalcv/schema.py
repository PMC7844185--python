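"""Column layout shared by the cohort generator and every downstream stage.

A cohort table is a plain :class:`pandas.DataFrame` with one row per
respondent.  The columns are fixed: identifiers, demographic factors,
raw questionnaire items, and a ground-truth column carrying the latent
outcome the generator used (absent in real survey exports).
"""

from __future__ import annotations

COUNTRIES = ("CN", "IT", "NL")

ID_COLUMN = "respondent_id"
COUNTRY_COLUMN = "country"
LATENT_OUTCOME = "latent_mental_health"

# ---------------------------------------------------------------- items
# 27 mental-health items: BSI-18 style somatization / depression /
# anxiety blocks plus a 10-item post-traumatic stress block.
MH_ITEMS = tuple(f"mh_{i:02d}" for i in range(1, 28))
MH_SUBSCALES = {
    "somatization": MH_ITEMS[0:6],
    "depression": MH_ITEMS[6:11],
    "anxiety": MH_ITEMS[11:17],
    "ptsd": MH_ITEMS[17:27],
}
MH_SUBSCALE_SIZES = (6, 5, 6, 10)

RES_ITEMS = tuple(f"res_{i:02d}" for i in range(1, 15))        # 1..5
LIFE_STRESS_ITEMS = tuple(f"ls_{i}" for i in range(1, 8))      # 1..4
WORK_STRESS_ITEM = "work_stress_item"                          # 1..10
JOB_CHANGE_ITEMS = tuple(f"jc_{i:02d}" for i in range(1, 14))  # 0/1
CONFLICT_ITEMS = tuple(f"conflict_{i}" for i in range(1, 7))   # 1..5
FI_ITEMS = tuple(f"fi_{i:02d}" for i in range(1, 21))          # 1..5

#: (low, high) inclusive integer range per item group
ITEM_RANGES = {
    MH_ITEMS: (1, 5),
    RES_ITEMS: (1, 5),
    LIFE_STRESS_ITEMS: (1, 4),
    (WORK_STRESS_ITEM,): (1, 10),
    JOB_CHANGE_ITEMS: (0, 1),
    CONFLICT_ITEMS: (1, 5),
    FI_ITEMS: (1, 5),
}

ALL_ITEM_COLUMNS = (
    MH_ITEMS
    + RES_ITEMS
    + LIFE_STRESS_ITEMS
    + (WORK_STRESS_ITEM,)
    + JOB_CHANGE_ITEMS
    + CONFLICT_ITEMS
    + FI_ITEMS
)

# --------------------------------------------------------- demographics
ROLE_COLUMN = "role"
ROLE_LEVELS = ("mother", "father")

AGE_LEVELS = ("18-30", "30-35", "35-40", "40-60")
MARITAL_LEVELS = ("married", "divorced_other")
EDUCATION_LEVELS = ("college_or_below", "university", "postgraduate")
EMPLOYMENT_LEVELS = ("employed", "unemployed")
HEALTH_LEVELS = ("poor", "fine", "good")

#: categorical / discrete demographic columns and their admissible levels
CATEGORICAL_LEVELS = {
    ROLE_COLUMN: ROLE_LEVELS,
    "maternal_age": AGE_LEVELS,
    "marital_status": MARITAL_LEVELS,
    "education": EDUCATION_LEVELS,
    "employment": EMPLOYMENT_LEVELS,
    "physical_health": HEALTH_LEVELS,
    "household_income": (1, 2, 3, 4, 5),
    "n_children": (1, 2, 3, 4),
    "age_youngest_child": tuple(range(0, 17)),
    "grandparental_support": (0, 1),
}

DEMOGRAPHIC_COLUMNS = (
    ROLE_COLUMN,
    "maternal_age",
    "marital_status",
    "education",
    "employment",
    "physical_health",
    "household_income",
    "n_children",
    "age_youngest_child",
    "grandparental_support",
)

#: derived composite scores with their closed ranges
SCORE_RANGES = {
    "mental_health": (1.0, 5.0),
    "resilience": (14, 70),
    "life_stress": (7, 28),
    "work_stress": (1, 10),
    "job_change_index": (0, 13),
    "family_conflict": (6, 30),
    "father_involvement": (1.0, 5.0),
}

COHORT_COLUMNS = (
    (ID_COLUMN, COUNTRY_COLUMN)
    + DEMOGRAPHIC_COLUMNS
    + ALL_ITEM_COLUMNS
    + (LATENT_OUTCOME,)
)
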