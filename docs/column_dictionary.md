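# Cohort column dictionary

One row per respondent in `cohort.csv`.

| column(s) | type / range | meaning |
|---|---|---|
| `respondent_id` | string | unique row id |
| `genre` | 0/1 | 0 boy, 1 girl |
| `age_years` | integer 10–18 | age |
| `home_area`, `school_area` | 0/1 | 0 rural, 1 urban |
| `school_grade` | integer 5–11 | school year |
| `transport` | categorical | walk / bus / car / bike / motorbike |
| `met_minutes_week` | real ≥ 0 | weekly MET-minutes (drives the IPAQ category) |
| `mobile_wifi`, `mobile_dataplan` | 0/1 | connectivity flags |
| `tdm_item_01` … `tdm_item_22` | integer 0–4 | Mobile Dependency Test items (total 0–88) |
| `mobile_hours`, `tv_hours`, `videogame_hours`, `reading_hours`, `outdoor_hours`, `desk_hours`, `sitting_hours`, `sleep_hours`, `backpack_weight`, `stress_level` | real | daily-habit items |
| `screen_breaks` | integer 1–5 | break frequency during screen use |
| `sleep_factor_1` … `sleep_factor_6` | real on factor scale | SDSC factors (1 difficulty initiating sleep, 2 nightmares, 3 night awakenings, 4 somnambulism, 5 tiredness and difficulty waking, 6 daytime sleepiness) |
| `activity_*` (12 sports) | integer 1–5 | weekly practice frequency, 1 never … 5 daily |
| `home_*` (8 chores) | 0/1 | household-chore responsibility flags |
| `pain_neck`, `pain_shoulders`, `pain_midback`, `pain_lowback` | integer 0–10 | visual-analogue pain intensity per region |

Scoring adds `mobile_dependency` (TDM total), `ipaq` (five-level category),
`mskp_index` (0–12) and `mskp_positive` (index ≥ 4).  One-hot encoding of
`age_group` (from `age_years`), `school_grade`, `transport` and `ipaq`
yields the 63-column feature matrix (`mskprisk.schema.FEATURE_COLUMNS`).
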