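"""Column dictionary for the adolescent musculoskeletal-pain survey.

The raw cohort table has one row per respondent.  Scoring the instruments
(:mod:`mskprisk.instruments`) turns it into a scored table, and one-hot
encoding (:mod:`mskprisk.screen`) turns that into the 63-column numeric
feature matrix the risk model consumes.

Naming follows the field convention used throughout the package:

``mobile_dependency``
    Total score of the 22-item Mobile Dependency Test (TDM), range 0-88.
``sleep_factor_1`` .. ``sleep_factor_6``
    Sleep Disturbances Scale for School-age Children (SDSC) factor scores.
``activity_*``
    Weekly practice frequency of a sport, 1 (never) to 5 (daily).
``home_*``
    Binary household-chore responsibility flags.
``pain_*``
    Visual-analogue pain intensity 0-10 for the four index body regions.
"""

from __future__ import annotations

# ---------------------------------------------------------------------------
# raw survey columns
# ---------------------------------------------------------------------------

PAIN_REGIONS = ["pain_neck", "pain_shoulders", "pain_midback", "pain_lowback"]

N_TDM_ITEMS = 22
TDM_ITEM_COLS = [f"tdm_item_{i:02d}" for i in range(1, N_TDM_ITEMS + 1)]
TDM_ITEM_MAX = 4  # Likert 0-4 per item, total 0-88

SLEEP_FACTOR_COLS = [f"sleep_factor_{k}" for k in range(1, 7)]
#: Upper end of each SDSC factor scale (lower end is 0).
SLEEP_FACTOR_MAX = {
    "sleep_factor_1": 4.0,
    "sleep_factor_2": 3.0,
    "sleep_factor_3": 3.2,
    "sleep_factor_4": 3.0,
    "sleep_factor_5": 4.0,
    "sleep_factor_6": 4.0,
}

ACTIVITY_COLS = [
    "activity_football",
    "activity_weightlifting",
    "activity_dance",
    "activity_basketball",
    "activity_cycling",
    "activity_running",
    "activity_swimming",
    "activity_volleyball",
    "activity_tennis",
    "activity_skating",
    "activity_gymnastics",
    "activity_martialarts",
]

CHORE_COLS = [
    "home_laundry",
    "home_room",
    "home_cleaning",
    "home_pets",
    "home_dishes",
    "home_cooking",
    "home_garden",
    "home_groceries",
]

#: daily-habit numeric items (hours, counts, 0-10 self ratings)
HABIT_COLS = [
    "mobile_hours",
    "tv_hours",
    "videogame_hours",
    "reading_hours",
    "outdoor_hours",
    "desk_hours",
    "sitting_hours",
    "screen_breaks",
    "sleep_hours",
    "backpack_weight",
    "stress_level",
]

BINARY_COLS = ["genre", "home_area", "school_area", "mobile_wifi", "mobile_dataplan"]

#: categorical variables and their ordered levels; the first level of each
#: group is the baseline of the logistic regression and is dropped before
#: the correlation screen.
CATEGORICALS = {
    "age_group": ["10_12", "13_15", "16_18"],
    "school_grade": ["5", "6", "7", "8", "9", "10", "11"],
    "transport": ["walk", "bus", "car", "bike", "motorbike"],
    "ipaq": ["very_low", "low", "moderate", "high", "very_high"],
}

RAW_COLUMNS = (
    ["respondent_id", "genre", "age_years", "home_area", "school_area",
     "school_grade", "transport", "met_minutes_week",
     "mobile_wifi", "mobile_dataplan"]
    + TDM_ITEM_COLS
    + HABIT_COLS
    + SLEEP_FACTOR_COLS
    + ACTIVITY_COLS
    + CHORE_COLS
    + PAIN_REGIONS
)


def onehot_columns(group: str) -> list[str]:
    """Indicator column names for a categorical group, in level order."""
    return [f"{group}_{lvl}" for lvl in CATEGORICALS[group]]


#: encoded feature-matrix columns, in fixed order (one-hot groups first,
#: then binaries, then numeric items) — 63 columns in total.
FEATURE_COLUMNS = (
    onehot_columns("age_group")
    + onehot_columns("school_grade")
    + onehot_columns("transport")
    + onehot_columns("ipaq")
    + BINARY_COLS
    + ["mobile_dependency"]
    + HABIT_COLS
    + SLEEP_FACTOR_COLS
    + ACTIVITY_COLS
    + CHORE_COLS
)

#: feature -> categorical group id (None for non one-hot features)
FEATURE_GROUPS: dict[str, str | None] = {name: None for name in FEATURE_COLUMNS}
for _g in CATEGORICALS:
    for _c in onehot_columns(_g):
        FEATURE_GROUPS[_c] = _g

#: baseline indicator dropped from each one-hot group before screening
REFERENCE_LEVELS = {g: f"{g}_{levels[0]}" for g, levels in CATEGORICALS.items()}

OUTCOME_COLUMN = "mskp_positive"
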