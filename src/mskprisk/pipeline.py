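"""Definitive-model workflow: stratified 60/20/20 split, CV-ensemble training,
tertile risk bands, and held-out band evaluation.

The definitive risk model is the frozen ensemble of the 60 cross-validation
fold-models (not a refit on all data); a respondent's model score is the
arithmetic mean of the member predicted probabilities.  Score tertiles on
the risk-definition subset give two cutpoints; each band's expected
prevalence is the positive fraction of the definition subset falling in it,
and the untouched risk-evaluation subset measures the observed prevalence
per band.  Band intervals are left-closed/right-open.

Leakage control is structural: the workflow records which respondent rows
entered standardization, training, penalty choice and cut placement, and
asserts that evaluation rows appear in none of them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from .lasso import CvEnsemble, CvPlan, CvResult, cross_validate, auc
from .screen import Standardizer

BAND_LABELS = ("low", "medium", "high")


@dataclass(frozen=True)
class WorkflowSplit:
    """Disjoint, exhaustive, prevalence-preserving 60/20/20 row partition."""

    train_idx: np.ndarray
    definition_idx: np.ndarray
    evaluation_idx: np.ndarray
    seed: int

    def parts(self) -> dict[str, np.ndarray]:
        return {"train": self.train_idx, "definition": self.definition_idx,
                "evaluation": self.evaluation_idx}


def split_workflow(y: np.ndarray, seed: int,
                   fractions: tuple[float, float, float] = (0.6, 0.2, 0.2)
                   ) -> WorkflowSplit:
    """Stratified train / risk-definition / risk-evaluation partition."""
    y = np.asarray(y, dtype=int)
    n = len(y)
    if n < 30:
        raise ValueError(f"need at least 30 respondents to split, got {n}")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    idx = np.arange(n)
    f_train, f_def, f_eval = fractions
    try:
        rest, eval_idx = train_test_split(idx, test_size=f_eval, random_state=seed,
                                          stratify=y)
        train_idx, def_idx = train_test_split(
            rest, test_size=f_def / (f_train + f_def), random_state=seed,
            stratify=y[rest])
    except ValueError as exc:
        raise ValueError(f"outcome class too rare to stratify the split: {exc}") from exc
    for name, part in [("train", train_idx), ("definition", def_idx),
                       ("evaluation", eval_idx)]:
        if len(np.unique(y[part])) < 2:
            raise ValueError(f"{name} part contains a single outcome class")
    return WorkflowSplit(np.sort(train_idx), np.sort(def_idx),
                         np.sort(eval_idx), seed)


def ensemble_score(ensemble: CvEnsemble, X: pd.DataFrame) -> np.ndarray:
    """Model score: mean predicted probability over the ensemble members.

    Rows must be standardized with the *training* statistics.
    """
    probs = np.stack([m.predict_proba(X) for m in ensemble.members])
    return probs.mean(axis=0)


@dataclass
class RiskBands:
    """Two tertile cutpoints and the expected prevalence per band."""

    lower_cut: float
    upper_cut: float
    expected_prevalence: dict[str, float | None]
    labels: tuple[str, str, str] = BAND_LABELS

    def assign(self, scores: np.ndarray) -> np.ndarray:
        """Band label per score; intervals are left-closed, right-open."""
        scores = np.asarray(scores, dtype=float)
        out = np.where(scores < self.lower_cut, self.labels[0],
                       np.where(scores < self.upper_cut, self.labels[1],
                                self.labels[2]))
        return out

    def to_dict(self) -> dict:
        return {"lower_cut": self.lower_cut, "upper_cut": self.upper_cut,
                "expected_prevalence": self.expected_prevalence}


def _band_prevalences(labels: np.ndarray, outcomes: np.ndarray
                      ) -> dict[str, float | None]:
    """Positive fraction per band; an empty band is undefined (None), not 0."""
    out: dict[str, float | None] = {}
    for band in BAND_LABELS:
        mask = labels == band
        out[band] = float(outcomes[mask].mean()) if mask.any() else None
    return out


def define_bands(scores: np.ndarray, outcomes: np.ndarray) -> RiskBands:
    """Tertile risk bands from risk-definition scores.

    Cutpoints sit at the order statistic immediately above each empirical
    tertile boundary, which together with the right-open interval convention
    makes tertile balance exact up to ties (bands of n/3 +- 1).
    """
    scores = np.asarray(scores, dtype=float)
    outcomes = np.asarray(outcomes, dtype=int)
    if len(np.unique(scores)) < 3:
        raise ValueError("degenerate score distribution: fewer than 3 distinct scores")
    ordered = np.sort(scores)
    n = len(ordered)
    lower = ordered[int(np.ceil(n / 3))]
    upper = ordered[int(np.ceil(2 * n / 3))]
    bands = RiskBands(lower_cut=float(lower), upper_cut=float(upper),
                      expected_prevalence={})
    bands.expected_prevalence = _band_prevalences(bands.assign(scores), outcomes)
    return bands


@dataclass
class BandEvaluation:
    observed_prevalence: dict[str, float | None]
    expected_prevalence: dict[str, float | None]
    auc: float
    band_sizes: dict[str, int]

    def to_dict(self) -> dict:
        return {"observed_prevalence": self.observed_prevalence,
                "expected_prevalence": self.expected_prevalence,
                "auc": self.auc, "band_sizes": self.band_sizes}


def evaluate_bands(bands: RiskBands, scores: np.ndarray,
                   outcomes: np.ndarray) -> BandEvaluation:
    """Observed per-band prevalence and overall AUC on held-out rows."""
    scores = np.asarray(scores, dtype=float)
    outcomes = np.asarray(outcomes, dtype=int)
    labels = bands.assign(scores)
    overall_auc = (auc(outcomes, scores)
                   if len(np.unique(outcomes)) == 2 else float("nan"))
    return BandEvaluation(
        observed_prevalence=_band_prevalences(labels, outcomes),
        expected_prevalence=dict(bands.expected_prevalence),
        auc=overall_auc,
        band_sizes={b: int((labels == b).sum()) for b in BAND_LABELS},
    )


@dataclass
class RiskModelWorkflow:
    """End-to-end definitive-model run with structural leakage tracking."""

    plan: CvPlan
    lambda_grid: tuple[float, ...]
    split: WorkflowSplit | None = None
    standardizer: Standardizer | None = None
    cv_result: CvResult | None = None
    bands: RiskBands | None = None
    evaluation: BandEvaluation | None = None
    definition_scores: np.ndarray | None = None
    _touched: dict[str, set] = field(default_factory=dict)

    def fit(self, features: pd.DataFrame, y: np.ndarray,
            feature_names: list[str] | None = None) -> "RiskModelWorkflow":
        """Split, standardize on train, train the ensemble, place the bands
        and evaluate them on the held-out rows."""
        y = np.asarray(y, dtype=int)
        if feature_names is not None:
            features = features[feature_names]
        self.split = split_workflow(y, seed=self.plan.seed)
        tr, de, ev = (self.split.train_idx, self.split.definition_idx,
                      self.split.evaluation_idx)

        self.standardizer = Standardizer().fit(features.iloc[tr])
        self._touched["standardization"] = set(tr)

        X_train = self.standardizer.transform(features.iloc[tr])
        self.cv_result = cross_validate(X_train, y[tr], self.plan,
                                        self.lambda_grid)
        self._touched["training"] = set(tr)
        self._touched["lambda_choice"] = set(tr)

        X_def = self.standardizer.transform(features.iloc[de])
        self.definition_scores = ensemble_score(self.cv_result.ensemble, X_def)
        self.bands = define_bands(self.definition_scores, y[de])
        self._touched["cut_placement"] = set(de)

        X_eval = self.standardizer.transform(features.iloc[ev])
        eval_scores = ensemble_score(self.cv_result.ensemble, X_eval)
        self.evaluation = evaluate_bands(self.bands, eval_scores, y[ev])
        self.assert_no_leakage()
        return self

    def assert_no_leakage(self) -> None:
        """Evaluation rows must not have influenced any fitted statistic."""
        if self.split is None:
            raise RuntimeError("workflow not fitted")
        eval_rows = set(self.split.evaluation_idx)
        for stage, rows in self._touched.items():
            overlap = eval_rows & rows
            if overlap:
                raise AssertionError(
                    f"evaluation rows leaked into {stage}: {sorted(overlap)[:5]}...")
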