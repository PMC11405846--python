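import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from whiskadapt.adaptation import (
    alpha_index,
    attenuation_decomposition,
    equipopulated_bins,
    filter_outliers,
    fit_tuning_curve,
    loo_predictions,
    predict_response,
    wsa_index,
)


class TestFilterOutliers:
    def test_removes_five_percent_of_hundred(self):
        rng = np.random.default_rng(0)
        s = rng.normal(size=100)
        keep = filter_outliers(s)
        assert len(keep) == 95
        removed = np.setdiff1d(np.arange(100), keep)
        assert np.min(np.abs(s[removed])) >= np.max(np.abs(s[keep]))

    def test_single_extreme_value_removed_at_n20(self):
        s = np.r_[np.full(19, 0.1), 5.0]
        keep = filter_outliers(s)
        assert len(keep) == 19 and 19 not in keep

    def test_tied_values_removed_from_the_end(self):
        s = np.full(40, 0.2)
        keep = filter_outliers(s)
        # ceil(0.05 * 40) = 2 removed, by index from the end
        assert list(keep) == list(range(38))

    def test_small_samples_kept_with_warning(self):
        with pytest.warns(UserWarning, match="filter not applied"):
            keep = filter_outliers(np.arange(10.0))
        assert len(keep) == 10


class TestEquipopulatedBins:
    @pytest.mark.parametrize("n,per_bin", [(8, 2), (100, 25)])
    def test_equal_counts(self, n, per_bin):
        _, assign = equipopulated_bins(np.arange(n, dtype=float))
        assert all((assign == b).sum() == per_bin for b in range(4))

    def test_duplicates_spanning_a_quantile(self):
        v = np.array([1.0, 2.0, 2.0, 2.0, 2.0, 2.0, 3.0, 4.0, 5.0])
        _, assign = equipopulated_bins(v)
        counts = np.bincount(assign, minlength=4)
        assert counts.max() - counts.min() <= 1

    def test_fewer_values_than_bins_rejected(self):
        with pytest.raises(ValueError):
            equipopulated_bins([1.0, 2.0], n_bins=4)

    @settings(max_examples=50, derandomize=True)
    @given(
        v=st.lists(st.floats(-10, 10), min_size=4, max_size=200),
        n_bins=st.integers(2, 6),
    )
    def test_counts_differ_by_at_most_one(self, v, n_bins):
        if len(v) < n_bins:
            return
        _, assign = equipopulated_bins(v, n_bins=n_bins)
        counts = np.bincount(assign, minlength=n_bins)
        assert counts.max() - counts.min() <= 1


class TestFitTuningCurve:
    def test_recovers_exact_line(self):
        rng = np.random.default_rng(1)
        s = rng.uniform(0.0, 1.0, 40)
        c = 2.0 * s + 1.0
        tc = fit_tuning_curve(s, c)
        assert tc.slope == pytest.approx(2.0, abs=1e-9)
        assert tc.intercept == pytest.approx(1.0, abs=1e-9)

    def test_constant_counts_zero_slope(self):
        rng = np.random.default_rng(2)
        s = rng.uniform(0.0, 1.0, 40)
        tc = fit_tuning_curve(s, np.full(40, 3.0))
        assert tc.slope == pytest.approx(0.0, abs=1e-9)
        assert tc.intercept == pytest.approx(3.0, abs=1e-9)

    def test_bin_mean_points_on_line(self):
        # four bins whose means lie on y = 2x + 1
        s = np.repeat([1.0, 2.0, 3.0, 4.0], 6)
        c = 2.0 * s + 1.0
        tc = fit_tuning_curve(s, c, apply_outlier_filter=False)
        np.testing.assert_allclose(tc.bin_mean_strength, [1, 2, 3, 4])
        np.testing.assert_allclose(tc.bin_mean_count, [3, 5, 7, 9])
        assert tc.slope == pytest.approx(2.0)
        assert tc.intercept == pytest.approx(1.0)

    def test_degenerate_strengths_flagged(self):
        with pytest.warns(UserWarning, match="slope undefined"):
            tc = fit_tuning_curve(np.full(24, 0.3), np.arange(24.0))
        assert tc.degenerate and np.isnan(tc.slope)
        # outlier filter removes ceil(0.05*24)=2 trailing samples (ties by index)
        assert tc.intercept == pytest.approx(np.arange(22.0).mean())


class TestPredictResponse:
    def test_linear_prediction(self):
        tc = fit_tuning_curve(
            np.repeat([1.0, 2.0, 3.0, 4.0], 6),
            0.1 * np.repeat([1.0, 2.0, 3.0, 4.0], 6) + 1.0,
        )
        assert predict_response(tc, [5.0])[0] == pytest.approx(1.5)

    def test_floor_at_zero(self):
        tc = fit_tuning_curve(
            np.repeat([1.0, 2.0, 3.0, 4.0], 6),
            np.maximum(
                0.0, 2.0 * np.repeat([1.0, 2.0, 3.0, 4.0], 6) - 1.0
            ),
        )
        assert predict_response(tc, [-5.0])[0] == 0.0

    def test_degenerate_curve_constant_prediction(self):
        with pytest.warns(UserWarning):
            tc = fit_tuning_curve(np.full(24, 0.3), np.full(24, 2.0))
        with pytest.warns(UserWarning, match="constant prediction"):
            pred = predict_response(tc, [0.1, 0.9])
        np.testing.assert_allclose(pred, [2.0, 2.0])


class TestLeaveOneOut:
    def test_identical_to_direct_fit_on_noiseless_line(self):
        rng = np.random.default_rng(3)
        s = rng.uniform(0.0, 1.0, 30)
        c = 4.0 * s + 0.5
        tc = fit_tuning_curve(s, c)
        loo = loo_predictions(s, c)
        np.testing.assert_allclose(loo, predict_response(tc, s), atol=1e-9)

    def test_differs_from_in_sample_fit_on_noisy_data(self):
        rng = np.random.default_rng(4)
        s = rng.uniform(0.0, 1.0, 30)
        c = 4.0 * s + 0.5 + rng.normal(0.0, 1.0, 30)
        tc = fit_tuning_curve(s, c)
        loo = loo_predictions(s, c)
        assert np.max(np.abs(loo - predict_response(tc, s))) > 1e-6


class TestAlphaIndex:
    @pytest.mark.parametrize(
        "fr1,fr1p,frl,expected",
        [(10, 10, 4, 0.0), (10, 4, 4, 1.0), (10, 7, 4, 0.5)],
    )
    def test_limit_and_midpoint_values(self, fr1, fr1p, frl, expected):
        assert alpha_index(fr1, fr1p, frl) == pytest.approx(expected)

    def test_no_attenuation_undefined(self):
        with pytest.warns(UserWarning, match="undefined"):
            assert np.isnan(alpha_index(5.0, 4.0, 5.0))

    @settings(max_examples=50, derandomize=True)
    @given(
        fr1=st.floats(1, 100),
        fr1p=st.floats(0, 100),
        frl=st.floats(0, 100),
        a=st.floats(0.1, 10),
        b=st.floats(-5, 5),
    )
    def test_invariant_under_common_affine_rescaling(self, fr1, fr1p, frl, a, b):
        if abs(fr1 - frl) < 1e-6:
            return
        base = alpha_index(fr1, fr1p, frl)
        scaled = alpha_index(a * fr1 + b, a * fr1p + b, a * frl + b)
        assert scaled == pytest.approx(base, rel=1e-6, abs=1e-9)


class TestWsaIndex:
    @pytest.mark.parametrize(
        "fr_test,fr_pred,expected",
        [(3.0, 3.0, 0.0), (6.0, 2.0, 0.5), (2.0, 6.0, -0.5)],
    )
    def test_values(self, fr_test, fr_pred, expected):
        assert wsa_index(fr_test, fr_pred) == pytest.approx(expected)

    def test_zero_denominator_undefined(self):
        with pytest.warns(UserWarning, match="undefined"):
            assert np.isnan(wsa_index(0.0, 0.0))

    @settings(max_examples=50, derandomize=True)
    @given(a=st.floats(0, 50), b=st.floats(0, 50))
    def test_antisymmetric_and_bounded(self, a, b):
        if a + b <= 0:
            return
        i = wsa_index(a, b)
        assert wsa_index(b, a) == pytest.approx(-i)
        assert -1.0 <= i <= 1.0


class TestAttenuationDecomposition:
    def test_mixed_motor_and_sensory_matches_closed_form(self):
        """Noiseless linear population: half the attenuation from weaker
        touches, half from a dropped intercept; alpha matches the
        closed-form median-based expectation and lies strictly in (0, 1)."""
        rng = np.random.default_rng(5)
        a, b, r = 50.0, 6.0, 0.5
        s_first = rng.uniform(0.02, 0.06, 200)
        s_later = rng.uniform(0.01, 0.03, 800)
        fr_first = a * s_first + b
        fr_later = a * s_later + r * b
        res = attenuation_decomposition(s_first, fr_first, s_later, fr_later)
        med1, medl = np.median(s_first), np.median(s_later)
        expected = (b - r * b) / (a * (med1 - medl) + b - r * b)
        assert 0.0 < res.alpha < 1.0
        assert res.alpha == pytest.approx(expected, abs=1e-9)

    def test_requires_first_touches(self):
        with pytest.raises(ValueError, match="first touch"):
            attenuation_decomposition([], [], [0.1] * 30, [1.0] * 30)
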