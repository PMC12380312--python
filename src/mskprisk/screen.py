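"""Encoding, standardization and the correlation-driven first selection step.

Collinear survey features destabilise logistic regression, so before any
penalised fitting the feature set is pruned with a Spearman-correlation
hierarchy: features are clustered by average linkage on the distance
``1 - |rho|`` and, within every cluster merged below the cut, a single
representative survives.  The published analysis did this step manually from
the dendrogram; here the rule is automatic and deterministic — the kept
representative is the feature most rank-correlated (in absolute value) with
the outcome, ties broken alphabetically — and is documented as a departure
from the manual screen.  The baseline indicator of every one-hot group is
always dropped first.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import warnings

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.stats import spearmanr

from . import schema

DEFAULT_THRESHOLD = 0.5


@dataclass
class FeatureMatrix:
    """Named numeric matrix plus per-column metadata."""

    values: pd.DataFrame
    groups: dict[str, str | None] = field(default_factory=dict)
    constant_columns: list[str] = field(default_factory=list)

    @property
    def names(self) -> list[str]:
        return list(self.values.columns)

    def meta(self) -> pd.DataFrame:
        v = self.values
        return pd.DataFrame({
            "min": v.min(), "max": v.max(), "mean": v.mean(),
            "sd": v.std(ddof=0),
            "group": [self.groups.get(c) for c in v.columns],
        })


def encode(scored: pd.DataFrame) -> FeatureMatrix:
    """One-hot encode the scored cohort into the numeric feature matrix.

    Categorical variables expand to one indicator column per declared level
    (sharing a group id); numeric items pass through unchanged.  Column
    order is fixed by the schema.  Unseen category levels raise.
    """
    feats = pd.DataFrame(index=scored.index)
    for group, levels in schema.CATEGORICALS.items():
        if group == "age_group":
            age = scored["age_years"].to_numpy()
            raw = np.where(age <= 12, "10_12", np.where(age <= 15, "13_15", "16_18"))
        elif group == "school_grade":
            raw = scored["school_grade"].astype(int).astype(str).to_numpy()
        else:
            raw = scored[group].astype(str).to_numpy()
        unseen = set(raw) - set(levels)
        if unseen:
            raise ValueError(f"unseen {group} level(s): {sorted(unseen)}")
        for lvl in levels:
            feats[f"{group}_{lvl}"] = (raw == lvl).astype(float)
    for col in schema.FEATURE_COLUMNS:
        if col not in feats.columns:
            feats[col] = scored[col].astype(float)
    feats = feats[list(schema.FEATURE_COLUMNS)]
    constant = [c for c in feats.columns if feats[c].nunique() <= 1]
    return FeatureMatrix(values=feats, groups=dict(schema.FEATURE_GROUPS),
                         constant_columns=constant)


class Standardizer:
    """Column-wise z-scoring with stored training statistics.

    Zero-variance columns are mapped to all zeros and flagged rather than
    divided by zero; the stored statistics make the transform reusable on
    held-out rows and invertible elsewhere.
    """

    def __init__(self) -> None:
        self.mean_: pd.Series | None = None
        self.sd_: pd.Series | None = None
        self.flagged_: list[str] = []

    def fit(self, values: pd.DataFrame) -> "Standardizer":
        if values.isna().any().any():
            raise ValueError("feature matrix contains missing values")
        self.mean_ = values.mean()
        sd = values.std(ddof=0)
        self.flagged_ = sd.index[sd == 0].tolist()
        self.sd_ = sd.replace(0.0, 1.0)
        return self

    def transform(self, values: pd.DataFrame) -> pd.DataFrame:
        if self.mean_ is None:
            raise RuntimeError("Standardizer not fitted")
        out = (values[self.mean_.index] - self.mean_) / self.sd_
        out[self.flagged_] = 0.0
        return out

    def fit_transform(self, values: pd.DataFrame) -> pd.DataFrame:
        return self.fit(values).transform(values)

    def inverse_transform(self, values: pd.DataFrame) -> pd.DataFrame:
        return values * self.sd_ + self.mean_


def standardize(m: FeatureMatrix) -> tuple[FeatureMatrix, Standardizer]:
    """Standardize a feature matrix, returning the fitted statistics."""
    st = Standardizer()
    out = st.fit_transform(m.values)
    return FeatureMatrix(values=out, groups=dict(m.groups),
                         constant_columns=list(st.flagged_)), st


def spearman_matrix(values: pd.DataFrame) -> pd.DataFrame:
    """Spearman correlation matrix (average ranks for ties).

    Constant columns get correlation 0 with everything (diagonal stays 1).
    """
    if len(values) < 3:
        raise ValueError("need at least 3 rows for a rank correlation")
    arr = values.to_numpy(dtype=float)
    p = arr.shape[1]
    const = arr.std(axis=0) == 0
    with np.errstate(all="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if p == 2:
            r = spearmanr(arr[:, 0], arr[:, 1]).statistic
            rho = np.array([[1.0, r], [r, 1.0]])
        else:
            rho = np.atleast_2d(spearmanr(arr).statistic)
    rho[const, :] = 0.0
    rho[:, const] = 0.0
    rho = np.nan_to_num(rho, nan=0.0)
    np.fill_diagonal(rho, 1.0)
    return pd.DataFrame(rho, index=values.columns, columns=values.columns)


@dataclass
class ScreenResult:
    kept: list[str]
    dropped: dict[str, dict]  # name -> {cluster, reason, representative}
    correlation: pd.DataFrame
    linkage: np.ndarray | None

    def summary(self) -> dict:
        return {"n_kept": len(self.kept), "kept": self.kept,
                "dropped": self.dropped}


def screen(m: FeatureMatrix, y: np.ndarray | pd.Series,
           threshold: float = DEFAULT_THRESHOLD) -> ScreenResult:
    """Correlation screen: cluster features at ``|rho| >= threshold`` and keep
    one representative per cluster.

    The merge tree is average linkage over the distance ``1 - |rho|`` and is
    cut at height ``1 - threshold``; within each multi-feature cluster the
    representative is the feature with the largest absolute Spearman
    correlation with the outcome.  Reference levels of one-hot groups are
    dropped before clustering.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must lie in (0, 1), got {threshold}")
    y = np.asarray(y, dtype=float)

    dropped: dict[str, dict] = {}
    cols = list(m.values.columns)
    for group, ref in schema.REFERENCE_LEVELS.items():
        if ref in cols:
            cols.remove(ref)
            dropped[ref] = {"cluster": None, "reason": "one-hot reference level",
                            "representative": None}
    values = m.values[cols]
    corr = spearman_matrix(values)

    dist = 1.0 - np.abs(corr.to_numpy())
    # one-hot siblings of the same categorical are complementary, not
    # redundant: their negative correlation is structural, so they are never
    # allowed to merge into one cluster
    group_of = [m.groups.get(c) for c in cols]
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            if group_of[i] is not None and group_of[i] == group_of[j]:
                dist[i, j] = dist[j, i] = 1.0
    np.fill_diagonal(dist, 0.0)
    link = hierarchy.linkage(squareform(dist, checks=False), method="average")
    labels = hierarchy.fcluster(link, t=1.0 - threshold, criterion="distance")

    out_corr = np.array([_outcome_spearman(values[c].to_numpy(), y) for c in cols])
    kept: list[str] = []
    for cluster_id in np.unique(labels):
        members = [c for c, lab in zip(cols, labels) if lab == cluster_id]
        strengths = {c: abs(out_corr[cols.index(c)]) for c in members}
        rep = sorted(members, key=lambda c: (-strengths[c], c))[0]
        kept.append(rep)
        for c in members:
            if c != rep:
                dropped[c] = {"cluster": int(cluster_id),
                              "reason": f"|rho| >= {threshold} cluster",
                              "representative": rep}
    kept.sort(key=cols.index)
    return ScreenResult(kept=kept, dropped=dropped, correlation=corr, linkage=link)


def _outcome_spearman(x: np.ndarray, y: np.ndarray) -> float:
    if x.std() == 0 or y.std() == 0:
        return 0.0
    return float(spearmanr(x, y).statistic)
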