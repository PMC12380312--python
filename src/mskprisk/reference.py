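"""Published reference values for the adolescent MSKP survey.

The package ships the survey's reported effect table (parameter ranges,
maximum odds ratios and their Bonferroni-corrected 90% CIs, plus the
reported per-SD coefficient and sample SD of the tiredness/difficulty-waking
sleep factor) and headline counts.  These are the *inputs* the synthetic
cohort emulates and the arithmetic reproductions start from — never
something the pipeline fits.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

#: reported cohort composition: 526 negatives + 154 positives = 680
REPORTED_POSITIVES = 154
REPORTED_N = 680


def reference_effect_table() -> pd.DataFrame:
    """Reported effect table: parameter, range, maximum OR and 90% CI."""
    with resources.files("mskprisk.data").joinpath("reference_effects.csv").open() as fh:
        return pd.read_csv(fh)


def reference_row(parameter: str) -> pd.Series:
    table = reference_effect_table().set_index("parameter")
    if parameter not in table.index:
        raise KeyError(f"no reference row for {parameter!r}")
    return table.loc[parameter]
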