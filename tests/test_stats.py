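"""Gated two-group tests, repeated-measures contrasts, regression rules."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import cordmotion as cm
from cordmotion.stats import (compare_two_groups, compare_multi_groups,
                              within_subject_segments, predict_motion)


class TestGate:
    def test_normal_samples_use_t(self, rng):
        a, b = rng.normal(0, 1, 120), rng.normal(0.2, 1, 120)
        res = compare_two_groups(a, b)
        assert res.test_used == "t"
        assert res.gate["a"]["normal"] and res.gate["b"]["normal"]

    def test_lognormal_sample_switches_to_mann_whitney(self, rng):
        a = rng.normal(0, 1, 100)
        b = np.exp(rng.normal(0, 1.2, 100))
        res = compare_two_groups(a, b)
        assert res.test_used == "mann_whitney"

    def test_identical_samples_null_statistic(self, rng):
        a = rng.normal(0, 1, 40)
        res = compare_two_groups(a, a.copy())
        assert res.p_value == pytest.approx(1.0, abs=1e-9)
        assert res.statistic == pytest.approx(0.0, abs=1e-9)

    def test_small_groups_descriptive_only(self):
        res = compare_two_groups([1.0, 2.0], [3.0, 4.0, 5.0])
        assert res.test_used == "descriptive"
        assert res.p_value is None

    def test_gate_is_pure_function_of_data(self, rng):
        a, b = rng.normal(0, 1, 30), rng.normal(0, 1, 30)
        r1 = compare_two_groups(a, b)
        r2 = compare_two_groups(a, b)
        assert r1.test_used == r2.test_used
        assert r1.p_value == r2.p_value


class TestWithinSubject:
    def test_identical_columns_no_significance(self, rng):
        base = rng.normal(10, 2, 20)
        wide = pd.DataFrame({s: base + rng.normal(0, 1, 20)
                             for s in ("C2/C3", "C5/C6", "C7/T1")})
        out = within_subject_segments(wide, "C5/C6")
        assert all(c.p_value > 0.05 for c in out["contrasts"])

    def test_bonferroni_adjustment_recorded(self, rng):
        wide = pd.DataFrame({
            "C2/C3": rng.normal(7, 1, 15),
            "C5/C6": rng.normal(13, 2, 15),
            "C7/T1": rng.normal(7, 1, 15)})
        out = within_subject_segments(wide, "C5/C6")
        assert out["n_contrasts"] == 2
        for c in out["contrasts"]:
            assert c.p_value == pytest.approx(
                min(1.0, c.gate["p_unadjusted"] * 2))

    def test_two_segment_input_reduces_to_paired_t(self, rng):
        a = rng.normal(10, 2, 18)
        b = a + rng.normal(1.0, 1.0, 18)
        wide = pd.DataFrame({"C2/C3": a, "C5/C6": b})
        out = within_subject_segments(wide, "C5/C6")
        t, p = sps.ttest_rel(a, b)
        # rm-ANOVA on two levels is the paired t-test (F = t^2)
        assert out["anova"].statistic == pytest.approx(t ** 2, rel=1e-6)
        assert out["anova"].p_value == pytest.approx(p, rel=1e-6)

    def test_too_few_complete_cases_raises(self):
        wide = pd.DataFrame({"C2/C3": [1.0, 2.0, np.nan],
                             "C5/C6": [2.0, 3.0, 4.0]})
        with pytest.raises(ValueError, match="complete cases"):
            within_subject_segments(wide, "C5/C6")

    def test_stenosis_contrasts_significant_in_calibrated_cohorts(self, small_cfg):
        """Cranial->stenosis increase and stenosis->caudal decrease both reach
        significance in nearly all replicate cohorts under calibrated effects."""
        hits = 0
        n_rep = 12
        for r in range(n_rep):
            cohort = cm.generate_cohort(small_cfg, seed=700 + r)
            m = cm.cohort_metrics([s for s in cohort if s.role == "patient"])
            wide = m.pivot(index="id", columns="segment", values="ptp_mm_s")
            wide = wide[["C2/C3", "C5/C6", "C7/T1"]]
            out = within_subject_segments(wide, "C5/C6")
            if all(c.p_value < 0.05 for c in out["contrasts"]):
                hits += 1
        assert hits >= 0.9 * n_rep


class TestMultiGroup:
    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            compare_multi_groups({"a": [1, 2], "b": []})

    def test_constant_groups_reported_as_ties(self):
        res = compare_multi_groups({"a": [2.0, 2.0], "b": [2.0, 2.0, 2.0]})
        assert res.extra.get("all_tied") is True
        assert res.p_value is None

    def test_shifted_groups_more_powerful_than_null(self, rng):
        n_rep, alpha = 150, 0.05
        null_rej = shift_rej = 0
        for _ in range(n_rep):
            g = {k: rng.normal(0, 1, 15) for k in "abc"}
            null_rej += compare_multi_groups(g).p_value < alpha
            g["c"] = g["c"] + 1.2
            shift_rej += compare_multi_groups(g).p_value < alpha
        assert shift_rej / n_rep > 0.8 > 3 * null_rej / n_rep


class TestRegression:
    @staticmethod
    def frame(rng, n=40, gender_effect=0.0, noise=1.0):
        gender = np.array(["male", "female"] * (n // 2))
        return pd.DataFrame({
            "outcome": gender_effect * (gender == "male") + rng.normal(0, noise, n),
            "amcc": rng.normal(2.3, 0.8, n),
            "age": rng.normal(55, 12, n),
            "gender": gender})

    def test_pure_gender_effect_detected(self, rng):
        n_rep = 60
        gender_hits = amcc_rej = age_rej = 0
        for _ in range(n_rep):
            df = self.frame(rng, gender_effect=2.5)
            res = predict_motion(df, "outcome", "amcc")
            gender_hits += res.pvalues["gender"] < 0.05
            amcc_rej += res.pvalues["amcc"] < 0.05
            age_rej += res.pvalues["age"] < 0.05
        assert gender_hits >= 0.9 * n_rep
        # null predictors reject only at ~alpha
        assert amcc_rej <= 8 and age_rej <= 8

    def test_constant_predictor_dropped_with_warning(self, rng):
        df = self.frame(rng)
        df["gender"] = "male"
        with pytest.warns(UserWarning, match="constant"):
            res = predict_motion(df, "outcome", "amcc")
        assert "gender" not in res.predictors

    def test_gross_outlier_excluded_and_nothing_else(self, rng):
        df = self.frame(rng)
        # high-leverage + high-influence point: extreme predictor and outcome
        df.loc[len(df)] = {"outcome": 40.0, "amcc": 9.0, "age": 100.0,
                           "gender": "male"}
        res = predict_motion(df, "outcome", "amcc")
        assert res.excluded_points == [len(df) - 1]

    def test_dual_criterion_is_a_conjunction(self, rng):
        """A high-leverage point on the regression plane (leverage only, low
        Cook's distance) must NOT be excluded."""
        df = self.frame(rng, noise=1.0)
        # place an extreme-x point exactly at the mean outcome trend: leverage
        # is large, residual ~0, so Cook flag stays off
        df.loc[len(df)] = {"outcome": float(df.outcome.mean()), "amcc": 10.0,
                           "age": 55.0, "gender": "male"}
        res = predict_motion(df, "outcome", "amcc")
        assert res.excluded_points == []

    def test_too_few_rows_rejected(self, rng):
        with pytest.raises(ValueError, match="at least 8"):
            predict_motion(self.frame(rng, n=6), "outcome", "amcc")


def test_build_tables_shapes(small_cfg):
    cohort = cm.generate_cohort(small_cfg, seed=50)
    m = cm.cohort_metrics(cohort)
    a = cm.cohort_anatomy_metrics(cohort)
    tables = cm.build_tables(cohort, m, a)
    motion = tables["motion"]
    assert set(motion.group) == {"C5/C6"}
    at = motion[(motion.segment == "C5/C6") & (motion.metric == "ptp_mm_s")]
    assert at.iloc[0].patient_n == 8 and at.iloc[0].control_n == 8
    assert at.iloc[0].offset == 0
    anat = tables["anatomy"]
    assert set(anat.metric) == {"amcc", "ascor_pct"}


def test_build_tables_single_gender_marked(default_cfg):
    cfg = cm.default_config()
    cfg.group_sizes = {"C3/C4": 6}
    cohort = cm.generate_cohort(cfg, seed=60)
    tables = cm.build_tables(cohort, cm.cohort_metrics(cohort))
    g = tables["gender"]
    assert (g.test_used == "not_applicable").all()


def test_build_tables_empty_cohort():
    tables = cm.build_tables([], pd.DataFrame())
    assert tables["motion"].empty and tables["gender"].empty
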