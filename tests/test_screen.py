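"""Encoding, standardization, Spearman matrix, correlation screen."""

import numpy as np
import pandas as pd
import pytest

from mskprisk import schema
from mskprisk.screen import (FeatureMatrix, Standardizer, encode, screen,
                             spearman_matrix, standardize)


class TestEncode:
    def test_shape_and_order(self, encoded):
        assert list(encoded.values.columns) == list(schema.FEATURE_COLUMNS)
        assert encoded.values.shape[1] == 63
        assert not encoded.values.isna().any().any()

    def test_onehot_groups_share_group_id(self, encoded):
        for col in schema.onehot_columns("age_group"):
            assert encoded.groups[col] == "age_group"
        assert encoded.groups["genre"] is None

    def test_binary_column_not_expanded(self, encoded):
        assert set(np.unique(encoded.values["genre"])) <= {0.0, 1.0}

    def test_unseen_level_raises(self, scored_cohort):
        bad = scored_cohort.copy()
        bad.loc[bad.index[0], "transport"] = "helicopter"
        with pytest.raises(ValueError, match="helicopter"):
            encode(bad)

    def test_single_level_cohort_flags_constant_siblings(self, scored_cohort):
        young = scored_cohort[scored_cohort["age_years"] <= 12]
        fm = encode(young)
        assert "age_group_13_15" in fm.constant_columns
        assert "age_group_16_18" in fm.constant_columns


class TestStandardize:
    def test_symmetric_triple(self):
        fm = FeatureMatrix(values=pd.DataFrame({"x": [1.0, 2.0, 3.0]}))
        out, st = standardize(fm)
        np.testing.assert_allclose(out.values["x"],
                                   np.array([-1, 0, 1]) * np.sqrt(1.5))

    def test_fitted_transform_is_idempotent_on_train(self, encoded):
        out, st = standardize(encoded)
        re = st.transform(encoded.values)
        keep = [c for c in re.columns if c not in st.flagged_]
        assert np.allclose(re[keep].mean(), 0.0, atol=1e-9)
        assert np.allclose(re[keep].std(ddof=0), 1.0, atol=1e-9)

    def test_constant_column_flagged_not_divided(self):
        fm = FeatureMatrix(values=pd.DataFrame({"c": [2.0, 2.0, 2.0],
                                                "x": [1.0, 2.0, 4.0]}))
        out, st = standardize(fm)
        assert st.flagged_ == ["c"]
        assert (out.values["c"] == 0).all()

    def test_inverse_transform_roundtrip(self, encoded):
        out, st = standardize(encoded)
        back = st.inverse_transform(out.values)
        keep = [c for c in back.columns if c not in st.flagged_]
        np.testing.assert_allclose(back[keep], encoded.values[keep], atol=1e-9)

    def test_stats_reusable_on_held_out_rows(self, encoded):
        st = Standardizer().fit(encoded.values.iloc[:400])
        held = st.transform(encoded.values.iloc[400:])
        assert held.shape[0] == len(encoded.values) - 400


class TestSpearman:
    def test_monotone_map_gives_unit_correlation(self):
        x = np.arange(1.0, 20.0)
        m = pd.DataFrame({"x": x, "x3": x ** 3, "neg": -x})
        rho = spearman_matrix(m)
        assert rho.loc["x", "x3"] == pytest.approx(1.0)
        assert rho.loc["x", "neg"] == pytest.approx(-1.0)

    def test_hand_ranked_tie_case(self):
        # ranks of (1,2,2,4) are (1, 2.5, 2.5, 4); of (1,3,2,4) are (1,3,2,4)
        # Pearson of the ranks = 4.5 / sqrt(4.5 * 5.0) = 0.948683...
        m = pd.DataFrame({"x": [1, 2, 2, 4], "y": [1, 3, 2, 4]})
        assert spearman_matrix(m).loc["x", "y"] == pytest.approx(
            0.9486832980505138, abs=1e-12)

    def test_constant_column_correlation_zero(self):
        m = pd.DataFrame({"c": [1.0, 1.0, 1.0, 1.0], "x": [1.0, 2, 3, 4]})
        rho = spearman_matrix(m)
        assert rho.loc["c", "x"] == 0.0
        assert rho.loc["c", "c"] == 1.0

    def test_too_few_rows(self):
        with pytest.raises(ValueError):
            spearman_matrix(pd.DataFrame({"x": [1.0, 2.0]}))


class TestScreen:
    def _toy(self, rng=None):
        rng = rng or np.random.default_rng(0)
        x = rng.standard_normal(200)
        z = rng.standard_normal(200)
        return FeatureMatrix(values=pd.DataFrame(
            {"a": x, "a_copy": x, "b": z}))

    def test_duplicate_column_collapses_to_one(self):
        fm = self._toy()
        y = (fm.values["a"] > 0).astype(int).to_numpy()
        res = screen(fm, y, threshold=0.5)
        assert ("a" in res.kept) != ("a_copy" in res.kept)
        assert "b" in res.kept

    def test_all_low_correlation_keeps_everything(self):
        rng = np.random.default_rng(1)
        fm = FeatureMatrix(values=pd.DataFrame(
            rng.standard_normal((300, 5)), columns=list("abcde")))
        y = rng.integers(0, 2, 300)
        res = screen(fm, y, threshold=0.5)
        assert sorted(res.kept) == list("abcde")

    def test_threshold_domain(self, standardized, outcome):
        for bad in (0.0, 1.0, -0.2):
            with pytest.raises(ValueError):
                screen(standardized, outcome, threshold=bad)

    def test_reference_levels_always_dropped(self, screen_result):
        for ref in schema.REFERENCE_LEVELS.values():
            assert ref in screen_result.dropped
            assert screen_result.dropped[ref]["reason"] == "one-hot reference level"

    def test_partition_and_representatives(self, screen_result, standardized):
        all_names = set(standardized.values.columns)
        assert set(screen_result.kept) | set(screen_result.dropped) == all_names
        assert not set(screen_result.kept) & set(screen_result.dropped)
        for name, info in screen_result.dropped.items():
            if info["representative"] is not None:
                assert info["representative"] in screen_result.kept

    def test_no_perfectly_correlated_survivors(self, screen_result):
        kept_corr = screen_result.correlation.loc[
            screen_result.kept, screen_result.kept].to_numpy()
        off = kept_corr[~np.eye(len(kept_corr), dtype=bool)]
        assert np.abs(off).max() < 1.0

    def test_default_cohort_kept_count(self, screen_result):
        # regression constant frozen from the default synthetic cohort
        assert 13 < len(screen_result.kept) < 63
        assert len(screen_result.kept) == EXPECTED_DEFAULT_KEPT

    def test_monotone_in_threshold(self, standardized, outcome):
        counts = [len(screen(standardized, outcome, threshold=t).kept)
                  for t in (0.3, 0.5, 0.7, 0.9)]
        assert counts == sorted(counts)

    def test_deterministic(self, standardized, outcome):
        a = screen(standardized, outcome, threshold=0.5)
        b = screen(standardized, outcome, threshold=0.5)
        assert a.kept == b.kept and a.dropped == b.dropped


EXPECTED_DEFAULT_KEPT = 58
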