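"""Cleaning cascade, Box-Cox fitting, Tukey fences and subsampling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import refmine as rm
from refmine import cleaning
from refmine.cleaning import (
    FilterRule, apply_filter_cascade, default_filter_rules,
    equal_weight_subsample, fit_box_cox, iterative_tukey_filter, tukey_fences,
)


class TestBoxCox:
    def test_lognormal_gives_lambda_zero(self, rng):
        x = np.exp(rng.standard_normal(100_000))
        assert abs(fit_box_cox(x).lam) < 0.05

    def test_gaussian_gives_lambda_near_one(self, rng):
        x = rng.normal(50, 1, 100_000)
        assert fit_box_cox(x).lam == pytest.approx(1.0, abs=0.2)

    def test_log_branch_at_one(self):
        assert cleaning.box_cox_transform([1.0], 0.0)[0] == 0.0

    def test_nonpositive_values_reported(self):
        with pytest.raises(ValueError, match="2 are <= 0"):
            fit_box_cox([1.0] * 10 + [0.0, -1.0])

    def test_too_few_values(self):
        with pytest.raises(ValueError):
            fit_box_cox([1.0, 2.0, 3.0])

    @given(lam=st.floats(-2, 2), seed=st.integers(0, 10))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_transform_preserves_order(self, lam, seed):
        x = np.random.default_rng(seed).uniform(0.1, 50, 50)
        t = cleaning.box_cox_transform(x, lam)
        np.testing.assert_array_equal(np.argsort(t), np.argsort(x))


class TestTukeyFences:
    def test_constant_vector(self):
        assert tukey_fences([5, 5, 5, 5]) == (5.0, 5.0)

    def test_hand_computed_octet(self):
        lo, hi = tukey_fences([1, 2, 3, 4, 5, 6, 7, 8])
        assert (lo, hi) == (-2.5, 11.5)

    def test_outlier_flagged(self):
        x = np.array([1, 2, 3, 4, 5, 6, 7, 8, 100])
        lo, hi = tukey_fences(x)
        flagged = x[(x < lo) | (x > hi)]
        np.testing.assert_array_equal(flagged, [100])

    def test_too_few(self):
        with pytest.raises(ValueError):
            tukey_fences([1, 2, 3])


def _frame(values, sex=0):
    return pd.DataFrame({"hcy": values, "sex": sex})


class TestIterativeTukey:
    def test_gaussian_group_removes_little(self, rng):
        df = _frame(rng.normal(12, 2, 10_000))
        kept, rep = iterative_tukey_filter(df, ["sex"])
        assert 1 - len(kept) / len(df) <= 0.02

    def test_contaminants_removed(self, rng):
        clean = rng.normal(12, 2, 9_500)
        contam = rng.normal(12 + 20, 2, 500)
        df = _frame(np.concatenate([clean, contam]))
        kept, rep = iterative_tukey_filter(df, ["sex"])
        assert (kept["hcy"] < 30).all()
        assert rep["groups"]["0"]["iterations"] <= 3

    def test_fixed_point(self, rng):
        df = _frame(rng.normal(12, 2, 5_000))
        once, _ = iterative_tukey_filter(df, ["sex"])
        twice, rep = iterative_tukey_filter(once, ["sex"])
        assert len(twice) == len(once)
        assert rep["groups"]["0"]["iterations"] == 1

    def test_small_group_errors(self):
        df = _frame([10.0] * 5)
        with pytest.raises(ValueError, match="group"):
            iterative_tukey_filter(df, ["sex"])


class TestFilterCascade:
    def test_default_rules_reference_limits(self, default_cohort):
        """Out-of-range covariates are excluded; bounds are inclusive."""
        df, _ = default_cohort
        cleaned, report = apply_filter_cascade(df, default_filter_rules())
        assert (cleaned["folate"] >= 4.0).all()
        assert cleaned["vitb12"].between(180, 914).all()
        f = cleaned[cleaned["sex"] == 0]
        m = cleaned[cleaned["sex"] == 1]
        assert f["alt"].between(7, 40).all() and m["alt"].between(9, 50).all()
        assert f["cr"].between(45, 84).all() and m["cr"].between(59, 104).all()

    def test_low_folate_excluded(self):
        df = pd.DataFrame({"id": ["a"], "sex": [0], "age": [30],
                           "hcy": [10.0], "folate": [3.9]})
        rules = [FilterRule("folate", "folate", lower=4.0)]
        out, _ = apply_filter_cascade(df, rules, dedupe=False, min_age=None)
        assert out.empty

    def test_sex_specific_alt_bound(self):
        df = pd.DataFrame({"id": ["a", "b"], "sex": [1, 0], "age": [30, 30],
                           "hcy": [10.0, 10.0], "alt": [45.0, 45.0]})
        rules = [FilterRule("alt", "alt", 7, 40, sex=0),
                 FilterRule("alt", "alt", 9, 50, sex=1)]
        out, _ = apply_filter_cascade(df, rules, dedupe=False, min_age=None)
        assert list(out["id"]) == ["a"]  # male 45 U/L is within 9-50

    def test_identity_with_no_rules(self, default_cohort):
        df, _ = default_cohort
        out, report = apply_filter_cascade(df, [], dedupe=False, min_age=None)
        pd.testing.assert_frame_equal(out, df)
        assert report.to_frame()["n_excluded"].sum() == 0

    def test_dedupe_keeps_first_visit(self):
        df = pd.DataFrame({
            "id": ["a", "a", "b"], "sex": [0, 0, 1], "age": [30, 31, 40],
            "hcy": [10.0, 11.0, 12.0], "visit_index": [2, 1, 1]})
        out, _ = apply_filter_cascade(df, [], dedupe=True, min_age=None)
        assert out.loc[out["id"] == "a", "hcy"].iloc[0] == 11.0

    def test_waterfall_conservation(self, default_cohort):
        df, _ = default_cohort
        _, report = apply_filter_cascade(df, default_filter_rules())
        tab = report.to_frame()
        assert tab["n_excluded"].sum() + tab["n_after"].iloc[-1] == len(df)
        assert (tab["n_after"] <= tab["n_before"]).all()

    def test_idempotence(self, default_cohort):
        df, _ = default_cohort
        once, _ = apply_filter_cascade(df, default_filter_rules())
        twice, rep = apply_filter_cascade(once, default_filter_rules())
        pd.testing.assert_frame_equal(twice, once)
        assert rep.to_frame()["n_excluded"].sum() == 0

    def test_unknown_covariate_raises(self, default_cohort):
        df, _ = default_cohort
        with pytest.raises(KeyError):
            apply_filter_cascade(df, [FilterRule("x", "nonexistent", 0, 1)])


class TestSubsample:
    def _cohort(self, per=300):
        rows = []
        k = 0
        rng = np.random.default_rng(3)
        for sex in (0, 1):
            for age in (20, 35, 45, 55, 65, 75, 85):
                for _ in range(per):
                    rows.append((f"r{k}", sex, age, rng.uniform(8, 16)))
                    k += 1
        return pd.DataFrame(rows, columns=["id", "sex", "age", "hcy"])

    def test_exact_counts(self):
        df = self._cohort(300)
        out = equal_weight_subsample(df, per_stratum_n=150, seed=1)
        assert len(out) == 14 * 150
        bands = cleaning.age_band(out["age"].to_numpy())
        sizes = out.groupby([out["sex"], bands]).size()
        assert (sizes == 150).all()

    def test_default_target_is_min_stratum(self):
        df = self._cohort(100)
        df = df.iloc[:-40]  # shrink the last stratum
        out = equal_weight_subsample(df, seed=1)
        bands = cleaning.age_band(out["age"].to_numpy())
        assert (out.groupby([out["sex"], bands]).size() == 60).all()

    def test_seeded_determinism(self):
        df = self._cohort(100)
        a = equal_weight_subsample(df, per_stratum_n=50, seed=9)
        b = equal_weight_subsample(df, per_stratum_n=50, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_empty_stratum_reported(self):
        df = self._cohort(50)
        df = df[~((df["sex"] == 1) & (df["age"] == 85))]
        with pytest.raises(ValueError, match="80\\+"):
            equal_weight_subsample(df)
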