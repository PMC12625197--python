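"""QC chain and normalization: IQR fences, call rates, two-step filter,
LOD/CV, and the log2 -> linear -> log10 -> z-score chain."""

import numpy as np
import pandas as pd
import pytest

from nulisapipe import (
    AnalyteMatrix,
    compute_call_rates,
    compute_lod_cv,
    flag_iqr_outliers,
    normalize_npq,
    run_qc,
    two_step_call_rate_filter,
)
from nulisapipe.matrix import ScaleTransitionError, linear_to_log2
from nulisapipe.synthetic import CohortConfig, generate_cohort


def _mat(columns: dict, scale="log2_npq") -> AnalyteMatrix:
    df = pd.DataFrame(columns, dtype=float)
    df.index = [f"s{i}" for i in range(len(df))]
    return AnalyteMatrix(df, scale=scale)


class TestIQROutliers:
    def test_hand_computed_fences_mask_only_the_spike(self):
        m = _mat({"a": list(range(1, 10)) + [100]})
        out, report = flag_iqr_outliers(m)
        assert report.fences.loc["a", "lower"] == pytest.approx(-3.5)
        assert report.fences.loc["a", "upper"] == pytest.approx(14.5)
        assert out.values["a"].isna().sum() == 1
        assert np.isnan(out.values.loc["s9", "a"])
        # non-flagged values untouched, elementwise
        assert out.values["a"].iloc[:9].tolist() == list(range(1, 10))

    def test_constant_analyte_boundary_inclusive(self):
        m = _mat({"a": [5.0, 5.0, 5.0, 5.0]})
        out, report = flag_iqr_outliers(m)
        assert report.fences.loc["a"].tolist() == [5.0, 5.0]
        assert not out.values["a"].isna().any()

    def test_all_inside_fences_is_identity(self):
        m = _mat({"a": [1.0, 2.0, 3.0, 4.0, 5.0], "b": [2.0, 2.1, 2.2, 2.3, 2.4]})
        out, _ = flag_iqr_outliers(m)
        pd.testing.assert_frame_equal(out.values, m.values)

    def test_under_four_values_flagged_not_masked(self):
        m = _mat({"a": [1.0, 2.0, np.nan, np.nan, 1000.0]})
        out, report = flag_iqr_outliers(m)
        assert "a" in report.unfenced_analytes
        assert out.values.loc["s4", "a"] == 1000.0

    def test_synthetic_injected_outliers_are_caught(self):
        cfg = CohortConfig(
            n_per_group=100, n_analytes=20, outlier_rate=0.01, missing_rate=0.0, seed=5
        )
        cohort = generate_cohort(cfg)
        out, _ = flag_iqr_outliers(cohort.matrix)
        injected = cohort.truth["outlier_mask"]
        masked = out.values.isna().to_numpy()
        caught = masked[injected].mean()
        assert caught >= 0.99


class TestCallRates:
    def test_simple_fraction(self):
        m = _mat({"a": [1, np.nan, 3, np.nan, 5]})
        a_rates, _ = compute_call_rates(m)
        assert a_rates["a"] == pytest.approx(0.6)

    def test_fully_observed(self, tiny_matrix):
        a_rates, s_rates = compute_call_rates(tiny_matrix)
        assert (a_rates == 1.0).all() and (s_rates == 1.0).all()

    def test_sample_rate_counts_missing_cells(self):
        df = pd.DataFrame(np.ones((3, 4)), index=list("xyz"), columns=list("abcd"))
        df.loc["x", ["a", "b"]] = np.nan
        _, s_rates = compute_call_rates(AnalyteMatrix(df))
        assert s_rates["x"] == pytest.approx(0.5)

    def test_empty_matrix_errors(self):
        with pytest.raises(ValueError):
            compute_call_rates(AnalyteMatrix(pd.DataFrame()))


class TestTwoStepFilter:
    def test_low_rate_analyte_removed_at_first_step(self):
        cols = {"bad": [1, np.nan, np.nan, np.nan, np.nan, 1, 1, 1, np.nan, np.nan]}
        cols["good"] = [1.0] * 10
        m = _mat(cols)
        _, report = two_step_call_rate_filter(m)
        assert report.removed_analytes["bad"] == "step65"

    def test_borderline_sample_removed_at_second_step(self):
        # 5 analytes; sample s0 missing one -> rate 0.8: survives 65%, fails 85%
        df = pd.DataFrame(np.ones((10, 5)), columns=list("abcde"))
        df.index = [f"s{i}" for i in range(10)]
        df.loc["s0", "a"] = np.nan
        out, report = two_step_call_rate_filter(AnalyteMatrix(df))
        assert report.removed_samples["s0"] == "step85"
        assert "s0" not in out.sample_ids

    def test_two_step_trace_matches_hand_computation(self):
        # Analytes A..F x samples s0..s9.  F misses s0..s3 (rate 0.6 ->
        # step65).  s8/s9 miss A..D (rate 2/6 -> step65).  A..D sit at 0.8
        # before sample removal but at 1.0 after it, so the staged
        # recomputation retains them; s0..s3 (0.833 before F is dropped)
        # recover to 1.0; s7 misses only A -> 5/6 at step 1 but 4/5 = 0.8
        # after recomputation -> removed at step85.
        df = pd.DataFrame(np.ones((10, 6)), columns=list("ABCDEF"))
        df.index = [f"s{i}" for i in range(10)]
        df.loc[["s0", "s1", "s2", "s3"], "F"] = np.nan
        df.loc[["s8", "s9"], ["A", "B", "C", "D"]] = np.nan
        df.loc["s7", "A"] = np.nan
        out, report = two_step_call_rate_filter(AnalyteMatrix(df))
        assert report.removed_analytes == {"F": "step65"}
        assert report.removed_samples == {"s8": "step65", "s9": "step65", "s7": "step85"}
        assert sorted(out.analyte_ids) == list("ABCDE")
        assert sorted(out.sample_ids) == [f"s{i}" for i in range(7)]

    def test_invalid_thresholds_rejected(self):
        m = _mat({"a": [1.0] * 5})
        with pytest.raises(ValueError):
            two_step_call_rate_filter(m, (0.85, 0.65))
        with pytest.raises(ValueError):
            two_step_call_rate_filter(m, (0.0, 0.85))

    def test_idempotent_and_monotone_on_synthetic_cohort(self):
        cohort = generate_cohort(
            CohortConfig(n_per_group=50, n_analytes=15, missing_rate=0.1, seed=7)
        )
        once, _ = two_step_call_rate_filter(cohort.matrix)
        twice, report = two_step_call_rate_filter(once)
        assert not report.removed_analytes and not report.removed_samples
        # lowering thresholds never removes more
        loose, loose_rep = two_step_call_rate_filter(cohort.matrix, (0.5, 0.7))
        assert loose.shape[0] >= once.shape[0]
        assert loose.shape[1] >= once.shape[1]


class TestLodCv:
    def test_cv_ten_percent(self):
        m = _mat({"a": [9.0, 10.0, 11.0]}, scale="linear_npq")
        _, cv = compute_lod_cv(m, replicate_groups=[["s0", "s1", "s2"]])
        assert cv["a"] == pytest.approx(10.0)

    def test_identical_replicates_zero_cv(self):
        m = _mat({"a": [7.0, 7.0, 7.0]}, scale="linear_npq")
        _, cv = compute_lod_cv(m, replicate_groups=[["s0", "s1", "s2"]])
        assert cv["a"] == 0.0

    def test_lod_from_constant_controls(self):
        m = _mat({"a": [1.0, 1.0, 1.0]}, scale="linear_npq")
        lod, _ = compute_lod_cv(m, control_ids=["s0", "s1", "s2"])
        assert lod["a"] == pytest.approx(1.0)

    def test_no_replicates_reports_missing_not_error(self):
        m = _mat({"a": [1.0, 2.0]}, scale="linear_npq")
        lod, cv = compute_lod_cv(m)
        assert np.isnan(cv["a"]) and np.isnan(lod["a"])


class TestNormalizationChain:
    def test_log2_to_linear_to_log10(self):
        m = _mat({"a": [10.0, 10.0, 10.0, 10.0]})
        out = normalize_npq(m, "log10")
        assert out.values["a"].iloc[0] == pytest.approx(10 * np.log10(2), abs=1e-10)
        assert out.values["a"].iloc[0] == pytest.approx(3.0103, abs=1e-4)

    def test_zscore_uses_sample_sd(self):
        m = _mat({"a": [1.0, 2.0, 3.0]}, scale="log10")
        out = normalize_npq(m, "zscore")
        assert out.values["a"].tolist() == pytest.approx([-1.0, 0.0, 1.0])
        assert out.norm_params.loc["a", "sd"] == pytest.approx(1.0)

    def test_round_trip_recovers_input(self, tiny_matrix):
        lin = normalize_npq(tiny_matrix, "linear_npq")
        back = linear_to_log2(lin)
        assert np.allclose(back.values, tiny_matrix.values, atol=1e-12)

    def test_backward_transition_rejected(self):
        m = _mat({"a": [1.0, 2.0, 3.0]}, scale="zscore")
        with pytest.raises(ScaleTransitionError):
            normalize_npq(m, "log2_npq")

    def test_nonpositive_linear_value_reported(self):
        m = _mat({"a": [1.0, -2.0, 3.0]}, scale="linear_npq")
        with pytest.raises(ValueError, match="nonpositive"):
            normalize_npq(m, "log10")

    def test_missing_cells_stay_missing_and_zscore_is_exact(self, small_cohort):
        filtered, _ = run_qc(small_cohort.matrix)
        z = normalize_npq(filtered, "zscore")
        assert z.missing_mask.equals(filtered.missing_mask)
        means = z.values.mean(axis=0, skipna=True)
        sds = z.values.std(axis=0, ddof=1, skipna=True)
        assert np.abs(means).max() < 1e-10
        assert np.abs(sds - 1).max() < 1e-10
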