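"""First feature-selection step: the Spearman correlation screen.

One-hot encodes and standardizes the 63 survey features, clusters them by
average linkage on 1-|rho|, and keeps one representative per cluster
(largest |rho| with the outcome).  Reports how many features survive and
which were removed as collinear.
"""

import json
from pathlib import Path

from mskprisk.config import RunConfig
from mskprisk.runner import stage_screen

OUTDIR = Path(__file__).resolve().parents[1] / "results" / "run"

if __name__ == "__main__":
    cfg = RunConfig.from_yaml(OUTDIR / "config.yaml")
    result = stage_screen(cfg, OUTDIR)
    n_total = len(result.kept) + len(result.dropped)
    print(f"correlation screen (|rho| >= {cfg.screen_threshold}): "
          f"{n_total} -> {len(result.kept)} features")
    collapsed = {k: v for k, v in result.dropped.items()
                 if v["representative"] is not None}
    for name, info in collapsed.items():
        print(f"  dropped {name} (represented by {info['representative']})")
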