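import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from upcount import (TransientSignal, build_histogram, correct_coincidence,
                     detect_events, disintegration_metrics, effective_windows,
                     estimate_baseline)
from upcount.transient import (DegenerateBaselineError, SaturationError,
                               read_transient, write_transient)


def flat_signal(value=0.0, n=1000):
    return TransientSignal(np.full(n, float(value)), 100.0)


class TestEstimateBaseline:
    def test_constant_signal(self):
        mu, sigma = estimate_baseline(flat_signal(3.0))
        assert (mu, sigma) == (3.0, 0.0)

    @pytest.mark.parametrize("lam", [0.05, 0.2, 1.0, 5.0])
    def test_poisson_baseline_with_sparse_peaks(self, lam):
        """mu tracks the Poisson rate within 5% despite tall peaks."""
        rng = np.random.default_rng(int(lam * 100))
        x = rng.poisson(lam, 100_000).astype(float)
        x[rng.integers(0, x.size, 500)] += 80.0  # sparse particle peaks
        mu, _ = estimate_baseline(TransientSignal(x, 100.0))
        assert mu == pytest.approx(lam, rel=0.05)

    def test_deterministic(self):
        rng = np.random.default_rng(3)
        sig = TransientSignal(rng.poisson(0.5, 5000).astype(float), 100.0)
        assert estimate_baseline(sig) == estimate_baseline(sig)

    def test_short_signal_rejected(self):
        with pytest.raises(ValueError):
            estimate_baseline(flat_signal(n=50))


class TestDetectEvents:
    def test_flat_baseline_no_events(self):
        sig = flat_signal(0.0, 5000)
        assert detect_events(sig, 0.0, 0.0) == []

    def test_injected_peak_area_conserved(self):
        x = np.zeros(1000)
        x[500:503] = [40.0, 25.0, 10.0]
        events = detect_events(TransientSignal(x, 100.0), 0.0, 0.0)
        assert len(events) == 1
        assert events[0].area == pytest.approx(75.0)
        assert events[0].width_us == pytest.approx(300.0)

    def test_gap_merging_and_width_flag(self):
        x = np.zeros(2000)
        x[100:115] = 50.0  # 1500 us: wider than the fragment cutoff
        x[116] = 50.0      # bridged across a single sub-threshold dwell
        events = detect_events(TransientSignal(x, 100.0), 0.0, 0.0, max_gap=1)
        assert len(events) == 1
        assert "fragment_suspect" in events[0].flags

    def test_zero_baseline_area_equals_total_intensity(self):
        """Conservation: every count belongs to exactly one event."""
        rng = np.random.default_rng(8)
        x = np.zeros(20_000)
        for k in rng.integers(10, 19_990, 40):
            x[k:k + 3] += rng.uniform(30, 80, 3)
        sig = TransientSignal(x, 100.0)
        events = detect_events(sig, 0.0, 0.0, count_floor=0.0)
        assert sum(e.area for e in events) == pytest.approx(x.sum())

    def test_event_count_invariant_to_time_shift(self):
        rng = np.random.default_rng(9)
        x = rng.poisson(0.05, 50_000).astype(float)
        x[np.arange(100, 50_000, 500)] += 60.0
        a = detect_events(TransientSignal(x, 100.0), 0.05, 0.22)
        b = detect_events(TransientSignal(x, 100.0, start_time_s=12.0), 0.05, 0.22)
        assert len(a) == len(b)

    def test_closed_loop_with_simulator(self, ir_run):
        """Detected event count equals ground-truth desorbed count."""
        signal, _, log = ir_run
        mu, sigma = estimate_baseline(signal)
        events = detect_events(signal, mu, sigma)
        assert len(events) == (log.fate == "desorbed").sum()


class TestHistogram:
    def test_identical_areas_mode(self):
        x = np.zeros(5000)
        for k in range(0, 5000, 100):
            x[k] = 222.0
        events = detect_events(TransientSignal(x, 100.0), 0.0, 0.0)
        hist = build_histogram(events, bin_width=10.0)
        assert hist.mode_bin_center == 225.0
        assert hist.n_events == len(events)

    def test_lognormal_mode_recovered(self):
        """Monte-Carlo: histogram mode within one bin of the density mode."""
        from upcount.transient import ParticleEvent
        rng = np.random.default_rng(12)
        sigma, mode = 0.25, 220.0
        areas = rng.lognormal(np.log(mode) + sigma ** 2, sigma, 20_000)
        events = [ParticleEvent(i, i + 1, a, 100.0) for i, a in enumerate(areas)]
        hist = build_histogram(events, bin_width=10.0)
        assert abs(hist.mode_bin_center - mode) <= 10.0

    def test_no_events_rejected(self):
        with pytest.raises(ValueError):
            build_histogram([])


class TestCoincidence:
    def test_zero_events(self):
        assert correct_coincidence(0, 1000) == 0.0

    def test_low_occupancy_series_expansion(self):
        w = 100_000
        n = w // 100
        corrected = correct_coincidence(n, w)
        assert corrected == pytest.approx(1.005 * n, rel=1e-3)
        assert corrected >= n

    def test_saturation_rejected(self):
        with pytest.raises(SaturationError):
            correct_coincidence(100, 100)

    @given(st.integers(1, 9_999))
    @settings(max_examples=60, deadline=None)
    def test_monotone_and_convex(self, n):
        w = 10_000
        f = correct_coincidence
        assert f(n, w) >= n
        if n < w - 1:
            d1 = f(n + 1, w) - f(n, w)
            assert d1 > 0
            if n > 1:
                d0 = f(n, w) - f(n - 1, w)
                assert d1 >= d0  # convex in n

    def test_effective_windows(self):
        assert effective_windows(1_000_000, 4.0) == 250_000
        with pytest.raises(ValueError):
            effective_windows(100, 0.0)


class TestDisintegrationMetrics:
    def test_zero_events_unflagged(self):
        sig = flat_signal(0.05, 1000)
        assert disintegration_metrics(sig, [], 0.05, 0.2) == (1.0, 0.0, False)

    def test_clean_peaks_ratio_near_unity(self):
        rng = np.random.default_rng(13)
        x = rng.poisson(0.05, 100_000).astype(float)
        x[np.arange(500, 99_500, 1000)] += 80.0
        sig = TransientSignal(x, 100.0)
        mu, sigma = estimate_baseline(sig)
        events = detect_events(sig, mu, sigma)
        ratio, wide, flag = disintegration_metrics(sig, events, mu, sigma)
        assert ratio == pytest.approx(1.0, abs=0.15)
        assert not flag


class TestTransientIO:
    def test_roundtrip(self, tmp_path):
        rng = np.random.default_rng(14)
        sig = TransientSignal(rng.poisson(1.0, 500).astype(float), 100.0,
                              start_time_s=2.5)
        path = tmp_path / "transient.tsv"
        write_transient(sig, path)
        back = read_transient(path)
        np.testing.assert_allclose(back.intensities, sig.intensities)
        assert back.dwell_us == pytest.approx(sig.dwell_us)
        assert back.start_time_s == pytest.approx(2.5)
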