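"""Instrument scoring: TDM total, SDSC sleep factors, IPAQ category and the
musculoskeletal-pain (MSKP) severity index.

The MSKP index aggregates visual-analogue pain intensities (0-10) over four
body regions — neck, shoulders, middle back, lower back.  Each region's
intensity is banded into a rating: 0 for no pain, 1 for intensities 1-3,
2 for 4-7, 3 for intensities above 7.  The index is the sum of the four
ratings (0-12) and a respondent is a positive case when it is >= 4; since a
single region contributes at most 3 points, positivity requires meaningful
pain in at least two regions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import schema

MSKP_POSITIVE_CUTOFF = 4
MSKP_INDEX_MAX = 12

#: weekly MET-minute cutpoints for the five IPAQ activity levels
#: (very_low < 600 <= low < 1500 <= moderate < 3000 <= high < 4500 <= very_high)
IPAQ_CUTPOINTS = (600.0, 1500.0, 3000.0, 4500.0)


class ValidationError(ValueError):
    """Raised when an item response is outside its declared range."""


@dataclass(frozen=True)
class MskpResult:
    """Banded region ratings, severity index (0-12) and positivity flag."""

    region_ratings: tuple[int, int, int, int]
    index: int
    positive: bool


@dataclass(frozen=True)
class InstrumentScores:
    respondent_id: object
    tdm_total: int
    sleep_factors: tuple[float, ...]
    ipaq_category: str
    mskp: MskpResult


def rate_region(intensity: int, record: object = None) -> int:
    """Band a 0-10 pain intensity into a 0-3 region rating.

    0 -> 0 (no pain), 1-3 -> 1, 4-7 -> 2, 8-10 -> 3.
    """
    if not np.isfinite(intensity) or not float(intensity).is_integer():
        raise ValidationError(f"pain intensity must be an integer 0-10, got {intensity!r}"
                              + (f" (record {record!r})" if record is not None else ""))
    intensity = int(intensity)
    if not 0 <= intensity <= 10:
        raise ValidationError(f"pain intensity {intensity} outside 0-10"
                              + (f" (record {record!r})" if record is not None else ""))
    if intensity == 0:
        return 0
    if intensity <= 3:
        return 1
    if intensity <= 7:
        return 2
    return 3


def mskp_index(intensities: Sequence[int], record: object = None) -> MskpResult:
    """Compute the MSKP severity index from the four region intensities."""
    if len(intensities) != len(schema.PAIN_REGIONS):
        raise ValidationError(
            f"expected {len(schema.PAIN_REGIONS)} region intensities, got {len(intensities)}")
    ratings = tuple(rate_region(v, record=record) for v in intensities)
    index = int(sum(ratings))
    return MskpResult(region_ratings=ratings, index=index,
                      positive=index >= MSKP_POSITIVE_CUTOFF)


def tdm_total(items: Sequence[int], record: object = None) -> int:
    """Total Mobile Dependency Test score: plain sum of the 22 Likert items."""
    if len(items) != schema.N_TDM_ITEMS:
        raise ValidationError(
            f"expected {schema.N_TDM_ITEMS} TDM items, got {len(items)}")
    total = 0
    for i, v in enumerate(items, start=1):
        if pd.isna(v) or not float(v).is_integer() or not 0 <= int(v) <= schema.TDM_ITEM_MAX:
            raise ValidationError(f"TDM item {i} value {v!r} outside 0-{schema.TDM_ITEM_MAX}"
                                  + (f" (record {record!r})" if record is not None else ""))
        total += int(v)
    return total


def ipaq_category(met_minutes: float) -> str:
    """Five-level IPAQ activity category from weekly MET-minutes."""
    if pd.isna(met_minutes) or met_minutes < 0:
        raise ValidationError(f"MET-minutes must be non-negative, got {met_minutes!r}")
    labels = schema.CATEGORICALS["ipaq"]
    idx = int(np.searchsorted(IPAQ_CUTPOINTS, met_minutes, side="right"))
    return labels[idx]


# columns that must be present and non-missing for a record to be scored
_REQUIRED = (schema.TDM_ITEM_COLS + schema.SLEEP_FACTOR_COLS
             + ["met_minutes_week"] + schema.PAIN_REGIONS)


def score_cohort(records: pd.DataFrame) -> tuple[pd.DataFrame, list[dict]]:
    """Score every instrument for a cohort, dropping incomplete records.

    Complete-case rule: a record missing any scored item is excluded and
    listed in the exclusion report (one JSON-serialisable dict per exclusion
    with the record id and the missing fields).

    Returns the scored table (original columns plus ``mobile_dependency``,
    ``ipaq``, ``mskp_index`` and ``mskp_positive``) and the exclusion report.
    """
    exclusions: list[dict] = []
    missing = records[_REQUIRED].isna()
    for rid, row in missing[missing.any(axis=1)].iterrows():
        ident = records.loc[rid, "respondent_id"] if "respondent_id" in records else rid
        exclusions.append({"respondent_id": ident,
                           "missing_fields": sorted(row.index[row].tolist())})
    kept = records.loc[~missing.any(axis=1)].copy()
    if kept.empty:
        raise ValueError("empty cohort: every record was excluded as incomplete")

    kept["mobile_dependency"] = [
        tdm_total(row, record=rid)
        for rid, row in zip(kept.index, kept[schema.TDM_ITEM_COLS].to_numpy())
    ]
    kept["ipaq"] = [ipaq_category(v) for v in kept["met_minutes_week"]]
    results = [mskp_index(row, record=rid)
               for rid, row in zip(kept.index, kept[schema.PAIN_REGIONS].to_numpy())]
    kept["mskp_index"] = [r.index for r in results]
    kept[schema.OUTCOME_COLUMN] = [int(r.positive) for r in results]
    return kept, exclusions


def scores_for_record(row: pd.Series) -> InstrumentScores:
    """Score a single survey record (convenience wrapper)."""
    return InstrumentScores(
        respondent_id=row.get("respondent_id"),
        tdm_total=tdm_total(row[schema.TDM_ITEM_COLS].to_numpy()),
        sleep_factors=tuple(float(row[c]) for c in schema.SLEEP_FACTOR_COLS),
        ipaq_category=ipaq_category(row["met_minutes_week"]),
        mskp=mskp_index(row[schema.PAIN_REGIONS].to_numpy()),
    )


def enumerate_index_values() -> Iterable[tuple[tuple[int, int, int, int], MskpResult]]:
    """Yield the MSKP result for every one of the 11**4 intensity combinations."""
    for a in range(11):
        for b in range(11):
            for c in range(11):
                for d in range(11):
                    yield (a, b, c, d), mskp_index((a, b, c, d))
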