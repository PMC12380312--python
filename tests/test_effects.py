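"""Effect statistics: OR per SD, maximum OR, Bonferroni CI, Wilson interval."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mskprisk import synthetic
from mskprisk.effects import (bonferroni_ci, effect_summary, max_odds_ratio,
                              or_per_sd, percent_change, prevalence_ci,
                              quantile_ci)
from mskprisk.lasso import CvPlan, cross_validate
from mskprisk.reference import (REPORTED_N, REPORTED_POSITIVES,
                                reference_effect_table, reference_row)
from mskprisk.screen import Standardizer


class TestOrPerSd:
    def test_null_effect(self):
        assert or_per_sd(0.0) == 1.0

    def test_reported_sleep_factor_coefficient(self):
        # the reported per-SD coefficient of the tiredness factor
        assert or_per_sd(0.039) == pytest.approx(1.0398, abs=1e-4)

    def test_series_expansion_point(self):
        assert or_per_sd(0.1) == pytest.approx(1.10517, abs=1e-5)


class TestMaxOddsRatio:
    def test_reproduces_reported_sleep_factor_entry(self):
        row = reference_row("sleep_factor_5")
        computed = max_odds_ratio(row["per_sd_coef"], row["sample_sd"],
                                  row["range_high"] - row["range_low"])
        # 1.1618 vs printed 1.163: agreement within input rounding
        assert computed == pytest.approx(row["max_or"], abs=0.002)

    def test_null_effect(self):
        assert max_odds_ratio(0.0, 1.7, 5.0) == 1.0

    def test_doubling_beta_squares_the_or(self):
        base = max_odds_ratio(0.2, 1.0, 3.0)
        assert max_odds_ratio(0.4, 1.0, 3.0) == pytest.approx(base ** 2)

    def test_constant_feature_rejected(self):
        with pytest.raises(ValueError):
            max_odds_ratio(0.5, 0.0, 1.0)

    @given(beta=st.floats(-2, 2), sd=st.floats(0.1, 5))
    @settings(max_examples=50, deadline=None)
    def test_range_of_one_sd_recovers_per_sd_or(self, beta, sd):
        assert max_odds_ratio(beta, sd, sd) == pytest.approx(
            or_per_sd(beta), rel=1e-12)


class TestPercentChange:
    @pytest.mark.parametrize("or_value,pct", [
        (1.117, 11.7),   # more likely at the maximum mobile-dependency score
        (0.943, -5.7),   # less likely with frequent football practice
        (1.0, 0.0),
    ])
    def test_reported_readings(self, or_value, pct):
        assert percent_change(or_value) == pytest.approx(pct, abs=1e-9)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            percent_change(0.0)


class TestBonferroniCi:
    def test_k1_is_plain_interval(self):
        rng = np.random.default_rng(0)
        values = np.exp(rng.normal(0.3, 0.1, 60))
        lo, hi, flag = bonferroni_ci(values, 0.90, 1)
        log = np.log(values)
        z = 1.6448536269514722  # N^-1(0.95)
        assert not flag
        assert lo == pytest.approx(np.exp(log.mean() - z * log.std(ddof=1)))
        assert hi == pytest.approx(np.exp(log.mean() + z * log.std(ddof=1)))

    def test_identical_values_flagged_degenerate(self):
        lo, hi, flag = bonferroni_ci(np.full(60, 1.3), 0.90, 5)
        assert flag and lo == hi == pytest.approx(1.3)

    def test_widening_monotone_in_k(self):
        rng = np.random.default_rng(1)
        values = np.exp(rng.normal(0.2, 0.15, 60))
        widths = []
        for k in (1, 2, 5, 13):
            lo, hi, _ = bonferroni_ci(values, 0.90, k)
            widths.append(np.log(hi) - np.log(lo))
        assert widths == sorted(widths)

    def test_contains_point_estimate(self):
        rng = np.random.default_rng(2)
        values = np.exp(rng.normal(-0.4, 0.2, 60))
        lo, hi, _ = bonferroni_ci(values, 0.90, 13)
        point = np.exp(np.log(values).mean())
        assert lo < point < hi

    def test_quantile_variant_within_support(self):
        rng = np.random.default_rng(3)
        values = np.exp(rng.normal(0.1, 0.3, 60))
        lo, hi, _ = quantile_ci(values, 0.90, 2)
        assert values.min() <= lo < hi <= values.max()


class TestPrevalenceCi:
    def test_reported_study_prevalence(self):
        point, lo, hi = prevalence_ci(REPORTED_POSITIVES, REPORTED_N)
        assert round(100 * point, 1) == 22.6
        assert round(100 * lo, 1) == 19.7
        assert round(100 * hi, 1) == 25.9

    def test_zero_positives_lower_bound(self):
        point, lo, hi = prevalence_ci(0, 50)
        assert point == 0.0 and lo == 0.0 and hi > 0.0

    def test_wilson_closed_form_oracle(self):
        # independent arithmetic: centre (x + z^2/2)/(n + z^2), half-width
        # z*sqrt(x(n-x)/n + z^2/4)/(n + z^2)
        x, n, z = 50, 100, 1.959963984540054
        centre = (x + z ** 2 / 2) / (n + z ** 2)
        half = z * np.sqrt(x * (n - x) / n + z ** 2 / 4) / (n + z ** 2)
        point, lo, hi = prevalence_ci(x, n)
        assert lo == pytest.approx(centre - half, abs=1e-10)
        assert hi == pytest.approx(centre + half, abs=1e-10)
        assert (round(100 * lo, 1), round(100 * hi, 1)) == (40.4, 59.6)

    @given(pos=st.integers(1, 99))
    @settings(max_examples=40, deadline=None)
    def test_interval_contains_point_within_unit_range(self, pos):
        point, lo, hi = prevalence_ci(pos, 100)
        assert 0.0 <= lo < point < hi <= 1.0

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            prevalence_ci(0, 0)


class TestEffectSummaryOnEnsembles:
    """CI behaviour measured on the default cohort's CV ensembles."""

    @pytest.fixture(scope="class")
    def ensembles(self):
        out = []
        names = list(synthetic.DEFAULT_PER_SD_LOG_ODDS)
        noise = ["sleep_factor_1", "sleep_factor_4", "stress_level",
                 "backpack_weight", "activity_dance"]
        for seed in range(8):
            spec = synthetic.CohortSpec(seed=seed)
            _, feats, y = synthetic.simulate_features(spec)
            raw = feats[names + noise]
            X = Standardizer().fit_transform(raw)
            cv = cross_validate(X, y, CvPlan(seed=seed), [10.0])
            out.append((cv.ensemble, raw))
        return out, names, noise

    def test_strong_effect_cis_exclude_unity(self, ensembles):
        runs, names, noise = ensembles
        k = len(names) + len(noise)
        for strong in ("sleep_factor_3", "sleep_factor_5"):
            excluded = 0
            for ensemble, raw in runs:
                table = effect_summary(ensemble, raw, family_level=0.90).table
                row = table.set_index("parameter").loc[strong]
                if row["ci_low"] > 1.0 or row["ci_high"] < 1.0:
                    excluded += 1
            assert excluded >= int(0.8 * len(runs)), strong

    def test_noise_cis_rarely_exclude_unity(self, ensembles):
        runs, names, noise = ensembles
        excl = 0
        for ensemble, raw in runs:
            table = effect_summary(ensemble, raw).table.set_index("parameter")
            for f in noise:
                row = table.loc[f]
                if row["ci_low"] > 1.0 or row["ci_high"] < 1.0:
                    excl += 1
        assert excl <= 0.2 * len(runs) * len(noise)

    def test_table_mirrors_published_layout(self, ensembles):
        runs, names, noise = ensembles
        table = effect_summary(runs[0][0], runs[0][1]).table
        assert {"parameter", "range", "max_or", "ci_low", "ci_high"} <= \
            set(table.columns)
        assert len(table) == len(names) + len(noise)
        # sorted by maximum OR, like the published table
        assert table["max_or"].is_monotonic_decreasing


class TestReferenceTable:
    def test_thirteen_reported_parameters(self):
        table = reference_effect_table()
        assert len(table) == 13
        assert (table["max_or"] > 0).all()

    def test_unknown_parameter_rejected(self):
        with pytest.raises(KeyError):
            reference_row("sleep_factor_9")
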