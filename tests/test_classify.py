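"""CV estimation, mean frequency, pattern labels and autocorrelograms."""
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import spikepatterns as sp
from spikepatterns import classify_pattern, compute_cv, mean_frequency
from spikepatterns.classify import autocorrelogram
from spikepatterns.types import InsufficientDataError

from conftest import make_train


class TestComputeCV:
    def test_constant_intervals(self):
        assert compute_cv([0.2] * 10) == 0.0

    @pytest.mark.parametrize(
        "shape, expected, tol",
        [(1, 1.0, 0.03), (4, 0.5, 0.02), (16, 0.25, 0.02)],
    )
    def test_gamma_closed_form(self, shape, expected, tol):
        # gamma renewal intervals have CV = 1/sqrt(k) exactly
        rng = np.random.default_rng(shape)
        intervals = rng.gamma(shape, scale=1.0 / shape, size=5000)
        assert abs(compute_cv(intervals) - expected) < tol

    def test_validation(self):
        with pytest.raises(InsufficientDataError):
            compute_cv([1.0])
        with pytest.raises(ValueError):
            compute_cv([1.0, -1.0])

    @given(
        st.lists(st.floats(0.01, 10.0), min_size=3, max_size=30),
        st.floats(0.001, 1000.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_scale_invariance(self, intervals, factor):
        arr = np.asarray(intervals)
        assert compute_cv(arr * factor) == pytest.approx(
            compute_cv(arr), rel=1e-9, abs=1e-12
        )


class TestMeanFrequency:
    def test_count_over_window(self, mk_train):
        t = mk_train(np.arange(1, 301) * 1.0 - 0.5, t_stop=300.0)
        assert mean_frequency(t, sp.Epoch("w", 0, 300)) == 1.0

    def test_empty_window(self, mk_train):
        t = mk_train([250.0], t_stop=300.0)
        assert mean_frequency(t, sp.Epoch("w", 0, 100)) == 0.0

    def test_window_outside_observation(self, mk_train):
        t = mk_train([1.0], t_stop=10.0)
        with pytest.raises(ValueError):
            mean_frequency(t, sp.Epoch("w", 0, 20))

    def test_renewal_rate_recovery(self):
        # regular-simple regime: rate parameter 5.62 Hz
        rates = [
            mean_frequency(
                sp.generate_renewal_train(5.62, 0.28, 300.0, seed=s),
                sp.Epoch("w", 0, 300),
            )
            for s in range(50)
        ]
        assert np.mean(rates) == pytest.approx(5.62, abs=0.1)


class TestClassifyPattern:
    def test_regular_simple(self, cfg):
        train = sp.generate_renewal_train(5.62, 0.28, 300.0, seed=11)
        res = classify_pattern(train, cfg)
        assert res.label == "RS"
        assert res.cv_classification < 0.5
        assert res.burst_spike_fraction < 0.25

    def test_poisson_is_irregular_simple(self, cfg):
        train = sp.generate_renewal_train(1.16, 1.0, 300.0, seed=12)
        res = classify_pattern(train, cfg)
        assert res.label == "IS"
        assert res.cv_classification > 0.5

    def test_fast_burst_with_minority_burst_spikes(self, cfg):
        # 30% of spikes in 3-spike bursts at 8 ms ISI, irregular onsets
        rng = np.random.default_rng(5)
        onsets = np.cumsum(rng.exponential(9.0, size=10)) + 5.0
        times = sorted(
            {round(x, 6) for o in onsets for x in (o, o + 0.008, o + 0.016)}
            | set(np.round(np.cumsum(rng.exponential(4.0, size=70)) + 0.001, 6))
        )
        train = make_train([t for t in times if t < 300.0], t_stop=300.0)
        res = classify_pattern(train, cfg.with_(max_intra_burst_isi=0.05))
        if res.burst_spike_fraction >= 0.25:
            assert res.label == "IFB"
            assert res.intra_burst_freq > 70

    def test_regular_slow_burst(self, cfg):
        spec = sp.SyntheticSpec(label="RSB", burst_rate=0.177,
                                spikes_per_burst=(24, 42),
                                intra_burst_freq=13.0, seed=2)
        res = classify_pattern(sp.generate_burst_train(spec), cfg)
        assert res.label == "RSB"
        assert res.intra_burst_freq < 70
        assert res.cv_classification < 0.5

    def test_insufficient_spikes(self, cfg):
        res = classify_pattern(make_train([1, 2, 3], t_stop=300.0), cfg)
        assert res.label == "INSUFFICIENT"
        assert math.isnan(res.cv_classification)

    def test_cv_boundary_is_strict(self):
        # ISIs {2,4,6} s: sample sd 2, mean 4 -> CV exactly 0.5 -> irregular
        train = make_train([0.0, 2.0, 6.0, 12.0], t_stop=12.0)
        cfg = sp.ClassifierConfig(
            min_spikes_for_classification=4, max_intra_burst_isi=1e-3
        )
        assert compute_cv(train.isi()) == 0.5
        assert classify_pattern(train, cfg).label == "IS"

    def test_burst_fraction_boundary_inclusive(self):
        # 3 of 12 spikes grouped = exactly 25% -> bursting
        times = [0.0, 0.01, 0.02] + [10.0 + 3.0 * i for i in range(9)]
        cfg = sp.ClassifierConfig(
            min_spikes_for_classification=5, max_intra_burst_isi=0.1
        )
        res = classify_pattern(make_train(times, t_stop=40.0), cfg)
        assert res.burst_spike_fraction == 0.25
        assert res.label.endswith("B")

    def test_fast_slow_boundary_is_fast(self):
        # intra-burst ISIs of exactly 1/64 s with the limit set to 64 Hz:
        # a frequency exactly at the limit classifies as fast
        times = []
        for k in range(6):
            t0 = k * 10.0
            times += [t0, t0 + 1 / 64, t0 + 2 / 64]
        cfg = sp.ClassifierConfig(
            min_spikes_for_classification=5,
            max_intra_burst_isi=0.1,
            fast_slow_limit=64.0,
        )
        res = classify_pattern(make_train(times, t_stop=60.0), cfg)
        assert res.intra_burst_freq == 64.0
        assert res.label.endswith("FB")

    def test_too_few_bursts_defaults_to_irregular(self):
        # 3 bursts -> only 2 onset intervals: regularity cannot be shown
        times = []
        for t0 in (0.0, 10.0, 20.0):
            times += [t0, t0 + 0.01, t0 + 0.02]
        cfg = sp.ClassifierConfig(
            min_spikes_for_classification=5, max_intra_burst_isi=0.1
        )
        res = classify_pattern(make_train(times, t_stop=30.0), cfg)
        assert res.label.startswith("I")
        assert res.insufficient_regularity

    def test_mixed_burst_criterion(self, cfg):
        spec = sp.SyntheticSpec(label="IMB", burst_rate=0.19,
                                spikes_per_burst=(30, 50),
                                intra_burst_freq=(120.0, 10.0), seed=3)
        res = classify_pattern(sp.generate_burst_train(spec), cfg)
        assert res.label == "IMB"

    def test_deterministic(self, cfg):
        train = sp.generate_renewal_train(2.0, 0.8, 120.0, seed=4)
        assert classify_pattern(train, cfg) == classify_pattern(train, cfg)


class TestAutocorrelogram:
    def test_periodic_peaks_at_period_multiples(self, mk_train):
        period = 0.5
        train = mk_train(np.arange(1, 601) * period, t_stop=301.0)
        counts, edges = autocorrelogram(train, bin_width=0.1, max_lag=2.0)
        centres = 0.5 * (edges[:-1] + edges[1:])
        peak_bins = set(np.flatnonzero(counts > 0).tolist())
        expected = {
            int(np.clip(np.digitize(lag, edges) - 1, 0, len(counts) - 1))
            for lag in (0.5, 1.0, 1.5, 2.0)
        }
        assert peak_bins == expected
        assert all(counts[b] > 500 for b in peak_bins)

    def test_poisson_is_flat(self):
        rate, duration = 5.0, 300.0
        train = sp.generate_renewal_train(rate, 1.0, duration, seed=99)
        counts, edges = autocorrelogram(train, bin_width=0.01, max_lag=2.0)
        # expected pair count per bin for a Poisson process, allowing for
        # the shrinking coincidence window near the end of the recording
        n = len(train)
        expectation = n * rate * 0.01
        sd = math.sqrt(expectation)
        assert np.all(np.abs(counts - expectation) < 5 * sd)

    def test_single_spike_all_zero(self, mk_train):
        counts, _ = autocorrelogram(mk_train([1.0], t_stop=2.0))
        assert counts.sum() == 0

    def test_zero_lag_pairs_excluded(self, mk_train):
        train = mk_train([1.0, 1.4], t_stop=2.0)
        counts, edges = autocorrelogram(train, bin_width=0.1, max_lag=1.0)
        assert counts.sum() == 1      # the ordered pair (1.0 -> 1.4) only

    def test_frame_export(self, mk_train):
        train = mk_train([1.0, 1.4], t_stop=2.0)
        frame = sp.autocorrelogram_frame(train, 0.1, 1.0)
        assert list(frame.columns) == ["lag_s", "count"]
        assert frame["count"].sum() == 1
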