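"""Shared fixtures: one default synthetic cohort, scored and encoded once."""

from __future__ import annotations

import numpy as np
import pytest

from mskprisk import schema, synthetic
from mskprisk.instruments import score_cohort
from mskprisk.lasso import CvPlan, cross_validate, select_by_median
from mskprisk.screen import encode, screen, standardize


@pytest.fixture(scope="session")
def default_spec():
    return synthetic.CohortSpec(n_respondents=680, seed=0)


@pytest.fixture(scope="session")
def default_cohort(default_spec):
    return synthetic.generate_cohort(default_spec)


@pytest.fixture(scope="session")
def scored_cohort(default_cohort):
    scored, exclusions = score_cohort(default_cohort)
    assert not exclusions
    return scored


@pytest.fixture(scope="session")
def outcome(scored_cohort):
    return scored_cohort[schema.OUTCOME_COLUMN].to_numpy()


@pytest.fixture(scope="session")
def encoded(scored_cohort):
    return encode(scored_cohort)


@pytest.fixture(scope="session")
def standardized(encoded):
    fm, st = standardize(encoded)
    return fm


@pytest.fixture(scope="session")
def screen_result(standardized, outcome):
    return screen(standardized, outcome, threshold=0.5)


def run_selection(seed: int, lam: float = 10.0, threshold: float = 0.5,
                  n: int = 680) -> tuple[set, list]:
    """Full first+second feature-selection pass on a fresh cohort.

    Returns (selected feature set, screen-kept feature list).
    """
    spec = synthetic.CohortSpec(n_respondents=n, seed=seed)
    cohort = synthetic.generate_cohort(spec)
    scored, _ = score_cohort(cohort)
    y = scored[schema.OUTCOME_COLUMN].to_numpy()
    fm, _ = standardize(encode(scored))
    result = screen(fm, y, threshold=threshold)
    cv = cross_validate(fm.values[result.kept], y, CvPlan(seed=seed), [lam])
    return set(select_by_median(cv.or_distribution)), result.kept
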