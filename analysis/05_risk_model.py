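"""Definitive risk model: train the CV ensemble and stratify risk tertiles.

Splits the cohort 60/20/20 (train / risk definition / risk evaluation,
stratified), grid-searches the penalty on the training part, freezes the
60-member ensemble, places tertile cutpoints on the risk-definition scores
and measures the per-band prevalence on the untouched evaluation part.
"""

import json
from pathlib import Path

from mskprisk.config import RunConfig
from mskprisk.runner import stage_fit

OUTDIR = Path(__file__).resolve().parents[1] / "results" / "run"

if __name__ == "__main__":
    cfg = RunConfig.from_yaml(OUTDIR / "config.yaml")
    wf = stage_fit(cfg, OUTDIR)
    bands = wf.bands
    ev = wf.evaluation
    print(f"ensemble penalty lambda={wf.cv_result.best_lambda:g}, "
          f"train mean CV AUC {wf.cv_result.mean_auc:.3f}")
    print(f"score cutpoints: {bands.lower_cut:.3f} / {bands.upper_cut:.3f}")
    print("band  expected  observed  n(eval)")
    for band in bands.labels:
        exp = bands.expected_prevalence[band]
        obs = ev.observed_prevalence[band]
        fmt = lambda v: "undefined" if v is None else f"{100*v:5.1f}%"
        print(f"{band:6s} {fmt(exp):>9s} {fmt(obs):>9s} {ev.band_sizes[band]:5d}")
    print(f"evaluation-set AUC {ev.auc:.3f}")
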