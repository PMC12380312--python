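"""Score every instrument and compute the MSKP index per respondent.

Applies the complete-case rule, sums the 22-item mobile-dependency test,
bands the four regional pain intensities into the 0-12 MSKP index
(positive if >= 4), and reports the cohort prevalence with its Wilson 95%
interval alongside the distribution summary table.
"""

import json
from pathlib import Path

from mskprisk.config import RunConfig
from mskprisk.runner import stage_score

OUTDIR = Path(__file__).resolve().parents[1] / "results" / "run"

if __name__ == "__main__":
    cfg = RunConfig.from_yaml(OUTDIR / "config.yaml")
    stage_score(cfg, OUTDIR)
    prev = json.loads((OUTDIR / "prevalence.json").read_text())
    print(f"scored {prev['n']} respondents ({prev['excluded']} excluded); "
          f"{prev['positives']} positive MSKP cases")
    print(f"prevalence {prev['prevalence_pct']}% "
          f"[95% CI {prev['ci95_pct'][0]}% - {prev['ci95_pct'][1]}%]")
    print(f"distribution summary -> {OUTDIR/'summary_table.csv'}")
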