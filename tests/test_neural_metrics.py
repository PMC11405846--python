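import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from whiskadapt.neural_metrics import (
    SpikeTrain,
    aligned_counts,
    count_spikes,
    is_touch_responsive,
    latency_from_rates,
    noise_window_starts,
    population_response,
    psth,
    response_latency,
    roc_auc,
    window_counts,
)


def train(times, unit="u00"):
    return SpikeTrain(unit_id=unit, session_id="s", times=np.asarray(times, float))


class TestCountSpikes:
    def test_half_open_window(self):
        t = train([5, 10, 35])
        assert count_spikes(t, 0, 30) == 2
        assert count_spikes(t, 30, 60) == 1

    def test_spike_at_right_edge_excluded(self):
        assert count_spikes(train([30.0]), 0, 30) == 0
        assert count_spikes(train([30.0]), 30, 60) == 1

    def test_invalid_window(self):
        with pytest.raises(ValueError):
            count_spikes(train([1.0]), 10, 10)

    @settings(max_examples=50, derandomize=True)
    @given(
        times=st.lists(st.floats(0, 100), max_size=50),
        split=st.floats(10, 90),
    )
    def test_partition_additivity(self, times, split):
        t = np.sort(np.asarray(times, float))
        tr = train(t)
        whole = count_spikes(tr, 0, 100)
        assert count_spikes(tr, 0, split) + count_spikes(tr, split, 100) == whole


class TestResponsiveness:
    def test_clear_response(self):
        # 5 spikes in each post window, none pre
        onsets = np.arange(10) * 1000.0
        spikes = np.sort(
            np.concatenate([o + np.linspace(1, 25, 5) for o in onsets])
        )
        r = is_touch_responsive(train(spikes), onsets)
        assert r.responsive is True
        assert r.effect == pytest.approx(5.0)

    def test_identical_distributions_not_responsive(self):
        onsets = (np.arange(10) + 1) * 1000.0
        spikes = np.sort(
            np.concatenate([[o - 10, o + 10] for o in onsets])
        )
        r = is_touch_responsive(train(spikes), onsets)
        assert r.responsive is False

    def test_small_noisy_difference_not_significant(self):
        # post mean 2.0 vs pre mean 1.9 with high variance at n=10
        onsets = (np.arange(10) + 1) * 1000.0
        post = [0, 5, 0, 4, 0, 6, 0, 3, 1, 1]
        pre = [5, 0, 4, 0, 6, 0, 3, 0, 1, 0]
        spikes = []
        for o, npost, npre in zip(onsets, post, pre):
            spikes.extend(o + np.linspace(1, 29, npost))
            spikes.extend(o - 30 + np.linspace(1, 29, npre))
        r = is_touch_responsive(train(np.sort(spikes)), onsets)
        assert r.responsive is False

    def test_too_few_touches_undetermined(self):
        r = is_touch_responsive(train([1.0]), [0.0, 100.0])
        assert r.responsive is None


class TestPsth:
    def test_rate_units(self):
        edges, rates = psth(train([1.5, 2.5]), [0.0], window=(0.0, 10.0))
        assert rates[1] == pytest.approx(1000.0)
        assert rates[2] == pytest.approx(1000.0)
        assert rates[0] == 0.0

    def test_no_spikes_all_zero(self):
        _, rates = psth(train([]), [0.0, 100.0])
        assert np.all(rates == 0)

    def test_averaging_over_identical_events(self):
        one = psth(train([1.5, 2.5]), [0.0], window=(0.0, 10.0))[1]
        two = psth(
            train([1.5, 2.5, 101.5, 102.5]), [0.0, 100.0], window=(0.0, 10.0)
        )[1]
        np.testing.assert_allclose(one, two)

    def test_empty_events_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            psth(train([1.0]), [])


class TestLatency:
    def test_step_response_latency(self):
        # silent baseline, all events respond starting 8 ms after onset
        onsets = np.arange(20) * 1000.0
        spikes = np.sort(np.concatenate([o + [8.5, 12.5] for o in onsets]))
        assert response_latency(train(spikes), onsets) == pytest.approx(8.0)

    def test_flat_psth_undefined(self):
        assert np.isnan(response_latency(train([]), np.arange(5) * 1000.0))

    def test_threshold_crossing_on_constructed_psth(self):
        # baseline alternating 8/12: mean 10, SD 2, threshold 14
        rates = np.array([8.0, 12.0] * 15 + [10.0] * 30)
        rates[30 + 12] = 15.0  # first crossing at 12 ms post
        rates[30 + 20] = 20.0
        latency, threshold = latency_from_rates(rates, n_baseline_bins=30)
        assert threshold == pytest.approx(14.0)
        assert latency == pytest.approx(12.0)


class TestRocAuc:
    def test_identical_multisets_chance(self):
        assert roc_auc([0, 1, 1, 3], [0, 1, 1, 3]) == 0.5

    def test_perfect_separation(self):
        assert roc_auc([2, 3], [0, 1]) == 1.0

    def test_exhaustive_pair_counting(self):
        # pairs: (0,1)<, (0,1)<, (2,1)>, (2,1)> -> AUC 0.5
        assert roc_auc([0, 2], [1, 1]) == 0.5

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([], [1])

    @settings(max_examples=50, derandomize=True)
    @given(
        a=st.lists(st.integers(0, 10), min_size=1, max_size=20),
        b=st.lists(st.integers(0, 10), min_size=1, max_size=20),
    )
    def test_antisymmetry(self, a, b):
        assert roc_auc(a, b) + roc_auc(b, a) == pytest.approx(1.0)

    @settings(max_examples=50, derandomize=True)
    @given(
        a=st.lists(st.integers(0, 10), min_size=1, max_size=20),
        b=st.lists(st.integers(0, 10), min_size=1, max_size=20),
    )
    def test_invariant_under_monotone_transform(self, a, b):
        f = lambda xs: [x**3 + 2 * x for x in xs]
        assert roc_auc(a, b) == pytest.approx(roc_auc(f(a), f(b)))


class TestNoiseWindows:
    def test_first_windows_tile_pre_touch_period(self):
        first, later = noise_window_starts(0.0, [100.0, 200.0], window_ms=30)
        assert first == [0.0, 30.0, 60.0]
        # inter-touch gap [130, 200) admits [130, 160) and [160, 190)
        assert later == [130.0, 160.0]

    def test_no_noise_window_overlaps_response_windows(self):
        rng = np.random.default_rng(0)
        onsets = np.sort(rng.uniform(100, 2000, 15))
        first, later = noise_window_starts(0.0, onsets, window_ms=30)
        for start in first + later:
            for on in onsets:
                assert start + 30 <= on or start >= on + 30

    def test_short_gaps_yield_no_later_windows(self):
        _, later = noise_window_starts(0.0, [100.0, 140.0], window_ms=30)
        assert later == []


class TestPopulationResponse:
    def test_summed_counts(self):
        t1 = train([5.0, 105.0, 110.0], unit="a")
        t2 = train([1.0, 2.0, 3.0, 101.0, 102.0, 103.0, 104.0], unit="b")
        np.testing.assert_array_equal(
            population_response([t1, t2], [0.0, 100.0]), [4, 6]
        )
        np.testing.assert_array_equal(
            population_response([t2, t1], [0.0, 100.0]), [4, 6]
        )

    def test_single_unit_identity(self):
        t1 = train([5.0, 105.0])
        np.testing.assert_array_equal(
            population_response([t1], [0.0, 100.0]),
            window_counts(t1, [0.0, 100.0]),
        )

    def test_empty_population_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            population_response([], [0.0])


class TestAlignedCounts:
    def test_pre_and_post_windows(self):
        t = train([-10.0 + 100, 5.0 + 100, 25.0 + 100])
        ar = aligned_counts(t, [100.0])
        assert ar.post[0] == 2 and ar.pre[0] == 1
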