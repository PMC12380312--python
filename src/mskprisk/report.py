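"""Markdown run report.

Every number in the report is read back from a serialised artifact of the
run directory — nothing is recomputed at render time — so regenerating the
report from the same run is byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

_REQUIRED = ["prevalence.json", "summary_table.csv", "screen.json",
             "selected.json", "bands.json", "evaluation.json",
             "effect_table.csv"]


def _fmt_prev(value) -> str:
    return "undefined" if value is None else f"{100 * value:.1f}%"


def render_report(run_dir: str | Path) -> Path:
    run_dir = Path(run_dir)
    missing = [f for f in _REQUIRED if not (run_dir / f).exists()]
    if missing:
        raise FileNotFoundError(f"incomplete run, missing artifacts: {missing}")

    prev = json.loads((run_dir / "prevalence.json").read_text())
    summary = pd.read_csv(run_dir / "summary_table.csv")
    scr = json.loads((run_dir / "screen.json").read_text())
    sel = json.loads((run_dir / "selected.json").read_text())
    bands = json.loads((run_dir / "bands.json").read_text())
    ev = json.loads((run_dir / "evaluation.json").read_text())
    eff = pd.read_csv(run_dir / "effect_table.csv")

    lines = ["# MSKP risk-model run report", ""]
    lines += ["## Cohort", "",
              f"- respondents scored: {prev['n']} "
              f"(excluded as incomplete: {prev['excluded']})",
              f"- positive MSKP cases: {prev['positives']}",
              f"- prevalence: {prev['prevalence_pct']}% "
              f"[95% CI: {prev['ci95_pct'][0]}% - {prev['ci95_pct'][1]}%]", ""]

    lines += ["### Distribution of relevant variables", "",
              summary.to_markdown(index=False), ""]

    n_total = scr["n_kept"] + len(scr["dropped"])
    lines += ["## Feature selection", "",
              f"- correlation screen: {n_total} -> {scr['n_kept']} features",
              f"- Lasso selection (lambda={sel['lambda']:g}, "
              f"mean CV AUC {sel['mean_auc']:.3f}): "
              f"{scr['n_kept']} -> {len(sel['selected'])} features",
              f"- selected: {', '.join(sel['selected'])}", ""]

    lines += ["## Risk bands", "",
              f"- score cutpoints: {bands['lower_cut']:.3f} / "
              f"{bands['upper_cut']:.3f} (tertiles of the risk-definition set)",
              "",
              "| band | expected prevalence | observed prevalence | n (evaluation) |",
              "|------|--------------------:|--------------------:|---------------:|"]
    for band in ("low", "medium", "high"):
        lines.append(
            f"| {band} | {_fmt_prev(bands['expected_prevalence'][band])} "
            f"| {_fmt_prev(ev['observed_prevalence'][band])} "
            f"| {ev['band_sizes'][band]} |")
    lines += ["", f"- evaluation-set AUC: {ev['auc']:.3f}", ""]

    cols = ["parameter", "range", "max_or", "ci_low", "ci_high"]
    lines += ["## Effect table (maximum odds ratios, Bonferroni-corrected CI)",
              "", eff[cols].round(3).to_markdown(index=False), ""]

    out = run_dir / "report.md"
    out.write_text("\n".join(lines))
    return out
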