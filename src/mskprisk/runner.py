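"""Stage-by-stage pipeline orchestration.

Each stage reads the artifacts of the previous one from the run directory
and writes its own with provenance, so every stage is independently
re-runnable from the command line and a full run is deterministic under a
fixed config.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve

from . import effects, instruments, lasso, pipeline, schema, screen, synthetic
from .config import RunConfig

log = logging.getLogger("mskprisk")


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_jsonable))


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def _provenance(outdir: Path, config: RunConfig) -> None:
    from . import __version__
    _write_json(outdir / "provenance.json",
                {"config_digest": config.digest(), "seed": config.seed,
                 "package_version": __version__})
    config.to_yaml(outdir / "config.yaml")


def stage_simulate(config: RunConfig, outdir: Path) -> pd.DataFrame:
    spec = synthetic.CohortSpec(n_respondents=config.n_respondents,
                                seed=config.seed,
                                target_prevalence=config.target_prevalence)
    cohort = synthetic.generate_cohort(spec)
    synthetic.write_cohort(cohort, outdir / "cohort.csv", spec)
    log.info("simulate: %d respondents", len(cohort))
    return cohort


def stage_score(config: RunConfig, outdir: Path) -> pd.DataFrame:
    cohort = pd.read_csv(outdir / "cohort.csv")
    scored, exclusions = instruments.score_cohort(cohort)
    scored.to_csv(outdir / "scored.csv", index=False)
    with open(outdir / "exclusions.jsonl", "w") as fh:
        for rec in exclusions:
            fh.write(json.dumps(rec) + "\n")

    n, pos = len(scored), int(scored[schema.OUTCOME_COLUMN].sum())
    point, lo, hi = effects.prevalence_ci(pos, n)
    _write_json(outdir / "prevalence.json",
                {"n": n, "positives": pos, "excluded": len(exclusions),
                 "prevalence_pct": round(point * 100, 1),
                 "ci95_pct": [round(lo * 100, 1), round(hi * 100, 1)]})
    _summary_table(scored).to_csv(outdir / "summary_table.csv", index=False)
    log.info("score: %d scored, %d excluded, prevalence %.1f%%",
             n, len(exclusions), 100 * point)
    return scored


def _summary_table(scored: pd.DataFrame) -> pd.DataFrame:
    """Cohort-description table (distribution of the relevant variables)."""
    rows = [
        ("Girls - Boys", f"{100 * scored['genre'].mean():.1f}% - "
                         f"{100 * (1 - scored['genre'].mean()):.1f}%"),
        ("Age (mean, SD)", f"{scored['age_years'].mean():.1f} "
                           f"({scored['age_years'].std(ddof=0):.1f})"),
        ("Mobile dependency (mean, SD)",
         f"{scored['mobile_dependency'].mean():.1f} "
         f"({scored['mobile_dependency'].std(ddof=0):.1f})"),
    ]
    for k, col in enumerate(schema.SLEEP_FACTOR_COLS, start=1):
        hi = schema.SLEEP_FACTOR_MAX[col]
        rows.append((f"Sleep factor {k} above midscale",
                     f"{100 * (scored[col] > hi / 2).mean():.1f}%"))
    for lvl in schema.CATEGORICALS["ipaq"]:
        rows.append((f"IPAQ {lvl}", f"{100 * (scored['ipaq'] == lvl).mean():.1f}%"))
    for col in schema.PAIN_REGIONS:
        rows.append((f"{col} reported", f"{100 * (scored[col] > 0).mean():.1f}%"))
    return pd.DataFrame(rows, columns=["variable", "distribution"])


def stage_screen(config: RunConfig, outdir: Path) -> screen.ScreenResult:
    scored = pd.read_csv(outdir / "scored.csv")
    fm = screen.encode(scored)
    fm.values.assign(**{schema.OUTCOME_COLUMN: scored[schema.OUTCOME_COLUMN]}) \
        .to_csv(outdir / "features.csv", index=False)
    std_fm, _ = screen.standardize(fm)
    y = scored[schema.OUTCOME_COLUMN].to_numpy()
    result = screen.screen(std_fm, y, threshold=config.screen_threshold)
    _write_json(outdir / "screen.json", result.summary())
    result.correlation.to_csv(outdir / "spearman.csv")
    _write_json(outdir / "linkage.json",
                {"merges": result.linkage.tolist() if result.linkage is not None else []})
    log.info("screen: %d -> %d features", fm.values.shape[1], len(result.kept))
    return result


def stage_select(config: RunConfig, outdir: Path) -> list[str]:
    feats = pd.read_csv(outdir / "features.csv")
    y = feats.pop(schema.OUTCOME_COLUMN).to_numpy()
    kept = json.loads((outdir / "screen.json").read_text())["kept"]
    X = screen.Standardizer().fit_transform(feats[kept])
    plan = lasso.CvPlan(n_repeats=config.n_repeats, n_folds=config.n_folds,
                        seed=config.seed)
    grid = ([config.selection_lambda] if config.selection_lambda is not None
            else config.lambda_grid)
    result = lasso.cross_validate(X, y, plan, grid)
    selected = lasso.select_by_median(result.or_distribution)
    _write_json(outdir / "select_ensemble.json",
                {"lambda": result.best_lambda, "mean_auc": result.mean_auc,
                 "members": result.ensemble.to_records()})
    dist = result.or_distribution
    pd.concat([dist.per_fold.T, dist.summary()], axis=1) \
        .to_csv(outdir / "or_distributions.csv")
    _write_json(outdir / "selected.json",
                {"selected": selected, "lambda": result.best_lambda,
                 "mean_auc": result.mean_auc})
    log.info("select: lambda=%g, %d -> %d features, mean AUC %.3f",
             result.best_lambda, len(kept), len(selected), result.mean_auc)
    return selected


def stage_fit(config: RunConfig, outdir: Path) -> pipeline.RiskModelWorkflow:
    """Definitive-model workflow: split, train, place bands, evaluate."""
    feats = pd.read_csv(outdir / "features.csv")
    y = feats.pop(schema.OUTCOME_COLUMN).to_numpy()
    selected = json.loads((outdir / "selected.json").read_text())["selected"]
    plan = lasso.CvPlan(n_repeats=config.n_repeats, n_folds=config.n_folds,
                        seed=config.seed)
    wf = pipeline.RiskModelWorkflow(plan=plan,
                                    lambda_grid=tuple(config.lambda_grid))
    wf.fit(feats, y, feature_names=selected)

    _write_json(outdir / "split.json",
                {k: v.tolist() for k, v in wf.split.parts().items()})
    _write_json(outdir / "ensemble.json",
                {"lambda": wf.cv_result.best_lambda,
                 "mean_auc_by_lambda": {str(k): v for k, v in
                                        wf.cv_result.mean_auc_by_lambda.items()},
                 "members": wf.cv_result.ensemble.to_records()})
    _write_json(outdir / "bands.json", wf.bands.to_dict())
    _write_json(outdir / "evaluation.json", wf.evaluation.to_dict())

    ev = wf.split.evaluation_idx
    X_eval = wf.standardizer.transform(feats.iloc[ev][selected])
    scores = pipeline.ensemble_score(wf.cv_result.ensemble, X_eval)
    per_subject = pd.DataFrame({
        "row": ev, "score": scores, "band": wf.bands.assign(scores),
        "outcome": y[ev]})
    per_subject.to_csv(outdir / "per_subject.csv", index=False)
    fpr, tpr, _ = roc_curve(y[ev], scores)
    pd.DataFrame({"fpr": fpr, "tpr": tpr}).to_csv(outdir / "roc.csv", index=False)

    summary = effects.effect_summary(
        wf.cv_result.ensemble, feats.iloc[wf.split.train_idx][selected],
        family_level=config.ci_family_level, ci_method=config.ci_method)
    summary.to_csv(outdir / "effect_table.csv")
    log.info("fit: lambda=%g, eval AUC %.3f", wf.cv_result.best_lambda,
             wf.evaluation.auc)
    return wf


def run_pipeline(config: RunConfig, outdir: str | Path) -> Path:
    """Execute every stage end-to-end into ``outdir`` and render the report."""
    from .report import render_report

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _provenance(outdir, config)
    stages = [("simulate", stage_simulate), ("score", stage_score),
              ("screen", stage_screen), ("select", stage_select),
              ("fit", stage_fit)]
    for name, fn in stages:
        try:
            fn(config, outdir)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
    render_report(outdir)
    return outdir
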