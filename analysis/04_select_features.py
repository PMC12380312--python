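"""Second feature-selection step: Lasso under repeated stratified CV.

Fits the L1-penalised logistic model (lambda=10) on all 60 fold-models of
the 20x3 stratified plan and keeps only features whose median fold
coefficient is nonzero (median odds ratio per SD != 1).
"""

import json
from pathlib import Path

from mskprisk.config import RunConfig
from mskprisk.runner import stage_select

OUTDIR = Path(__file__).resolve().parents[1] / "results" / "run"

if __name__ == "__main__":
    cfg = RunConfig.from_yaml(OUTDIR / "config.yaml")
    selected = stage_select(cfg, OUTDIR)
    sel = json.loads((OUTDIR / "selected.json").read_text())
    print(f"Lasso selection at lambda={sel['lambda']:g}: "
          f"mean CV AUC {sel['mean_auc']:.3f}")
    print(f"median-nonzero rule keeps {len(selected)} features:")
    for f in selected:
        print(f"  {f}")
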