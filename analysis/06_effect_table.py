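"""Effect-size table and headline odds-ratio readings.

Reads the fitted run, renders the report, and prints the effect table
(maximum odds ratio per feature with Bonferroni-corrected 90% CI) plus the
percent-change interpretation of the strongest effects.
"""

import json
from pathlib import Path

import pandas as pd

from mskprisk.effects import percent_change
from mskprisk.report import render_report

OUTDIR = Path(__file__).resolve().parents[1] / "results" / "run"

if __name__ == "__main__":
    table = pd.read_csv(OUTDIR / "effect_table.csv")
    print(table[["parameter", "range", "max_or", "ci_low", "ci_high"]]
          .round(3).to_string(index=False))
    top = table.iloc[0]
    print(f"\nstrongest risk factor: {top['parameter']} "
          f"(max OR {top['max_or']:.3f}, "
          f"{percent_change(top['max_or']):+.1f}% odds across its range)")
    protective = table[table["max_or"] < 1]
    for _, row in protective.iterrows():
        print(f"protective: {row['parameter']} "
              f"({percent_change(row['max_or']):+.1f}% odds across its range)")
    path = render_report(OUTDIR)
    print(f"\nreport -> {path}")
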