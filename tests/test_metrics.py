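import numpy as np
import pytest
from hypothesis import given, strategies as st

from orexinet.metrics import (classify_periodicity, day_windows, detect_spikes,
                              quality_coefficient, synthetic_spike_train,
                              wake_intervals)

T = 24000.0
F_W = 2.0 / 3.0
GAP = 250.0


def trimmed_day_windows(n):
    """Day windows whose spiking ends one gap before the night boundary, so
    the wake tail closes exactly at the day/night split."""
    return [(a, b - GAP) for a, b in day_windows(n, T, F_W)]


def trimmed_night_windows(n):
    return [(n_ * T + F_W * T, (n_ + 1) * T - GAP) for n_ in range(n)]


class TestDetectSpikes:
    def test_subthreshold_trace_yields_nothing(self):
        V = np.full(5000, -60.0)
        assert detect_spikes(V, 0.1).size == 0

    def test_sinusoid_crossing_count(self):
        # 10 Hz sine, amplitude 40 mV about -40 mV: 10 upward 0-crossings in 1 s
        t = np.arange(0, 1000.0, 0.1)
        V = -40.0 + 40.0 * np.sin(2 * np.pi * 10 * t / 1000.0)
        sp = detect_spikes(V, 0.1, spike_threshold=0.0, refractory=2.0)
        assert sp.size == 10

    def test_refractory_merges_double_peak(self):
        V = np.full(200, -60.0)
        V[50:53] = 10.0   # first peak
        V[55:58] = 10.0   # artifact 0.5 ms later (dt = 0.1)
        sp = detect_spikes(V, 0.1, refractory=2.0)
        assert sp.size == 1

    def test_crossing_times_linearly_interpolated(self):
        V = np.array([-10.0, 10.0])
        sp = detect_spikes(V, 1.0, spike_threshold=0.0)
        assert sp[0] == pytest.approx(0.5)

    def test_refractory_must_exceed_dt(self):
        with pytest.raises(ValueError):
            detect_spikes(np.zeros(10), 0.1, refractory=0.05)


class TestWakeIntervals:
    def test_manual_union(self):
        iv = wake_intervals([0.0, 100.0, 200.0], gap=250.0)
        assert iv == [(0.0, 450.0)]
        assert sum(b - a for a, b in iv) == pytest.approx(450.0)

    def test_empty_train(self):
        assert wake_intervals([], gap=250.0) == []

    def test_isolated_spike_contributes_one_gap(self):
        iv = wake_intervals([10000.0], gap=250.0)
        assert iv == [(10000.0, 10250.0)]

    def test_unsorted_input_rejected(self):
        with pytest.raises(ValueError):
            wake_intervals([100.0, 50.0], gap=250.0)

    def test_disjoint_and_sorted(self, rng):
        t = np.sort(rng.uniform(0, 100000, 300))
        iv = wake_intervals(t, gap=250.0)
        flat = np.array(iv).ravel()
        assert np.all(np.diff(flat) >= 0)


class TestQualityCoefficient:
    def test_optimal_cycle_scores_plus_one(self):
        t = synthetic_spike_train(trimmed_day_windows(6), isi=20.0)
        rep = quality_coefficient(t, T, f_w=F_W, n_periods=6, gap=GAP)
        assert rep.Q == pytest.approx(1.0, abs=0.02)

    def test_no_spikes_scores_zero(self):
        rep = quality_coefficient([], T, f_w=F_W, n_periods=6, gap=GAP)
        assert rep.Q == 0.0

    def test_antiphase_cycle_scores_minus_one(self):
        t = synthetic_spike_train(trimmed_night_windows(6), isi=20.0)
        rep = quality_coefficient(t, T, f_w=F_W, n_periods=6, gap=GAP)
        assert rep.Q == pytest.approx(-1.0, abs=0.02)

    def test_translation_invariance_by_whole_periods(self):
        t = synthetic_spike_train(trimmed_day_windows(6), isi=35.0, jitter=5.0,
                                  seed=2)
        q0 = quality_coefficient(t, T, f_w=F_W, n_periods=6, gap=GAP).Q
        q3 = quality_coefficient(t + 3 * T, T, f_w=F_W, n_periods=9, gap=GAP,
                                 skip_periods=4).Q
        assert q3 == pytest.approx(q0, abs=1e-9)

    def test_nightly_isolated_spike_costs_one_gap_fraction(self):
        """Each isolated night spike docks Q by ≈ gap / ((1-f_w) T)."""
        base = synthetic_spike_train(trimmed_day_windows(6), isi=20.0)
        q0 = quality_coefficient(base, T, f_w=F_W, n_periods=6, gap=GAP).Q
        night = np.array([(n + F_W) * T + 4000.0 for n in range(6)])
        t = np.sort(np.concatenate([base, night]))
        q1 = quality_coefficient(t, T, f_w=F_W, n_periods=6, gap=GAP).Q
        assert q0 - q1 == pytest.approx(GAP / ((1 - F_W) * T), abs=0.01)

    @given(st.integers(0, 2 ** 31 - 1))
    def test_night_spikes_never_raise_q_when_days_are_covered(self, seed):
        rng = np.random.default_rng(seed)
        base = synthetic_spike_train(trimmed_day_windows(6), isi=20.0)
        q0 = quality_coefficient(base, T, f_w=F_W, n_periods=6, gap=GAP).Q
        extra = rng.uniform(F_W * T, T, 3) + rng.integers(0, 6, 3) * T
        t = np.sort(np.concatenate([base, extra]))
        q1 = quality_coefficient(t, T, f_w=F_W, n_periods=6, gap=GAP).Q
        assert q1 <= q0 + 1e-12

    def test_extending_day_coverage_never_lowers_q(self):
        partial = synthetic_spike_train([(n * T, n * T + 8000.0) for n in range(6)],
                                        isi=20.0)
        q0 = quality_coefficient(partial, T, f_w=F_W, n_periods=6, gap=GAP).Q
        fuller = synthetic_spike_train([(n * T, n * T + 12000.0) for n in range(6)],
                                       isi=20.0)
        q1 = quality_coefficient(fuller, T, f_w=F_W, n_periods=6, gap=GAP).Q
        assert q1 >= q0 - 1e-12

    def test_interval_rule_matches_grid_occupancy_oracle(self):
        """Q via the interval rule equals a 1-ms grid occupancy computation."""
        rng = np.random.default_rng(99)
        for _ in range(50):
            n_sp = rng.integers(0, 120)
            t = np.sort(rng.uniform(0, 5 * T, n_sp))
            rep = quality_coefficient(t, T, f_w=F_W, n_periods=5, gap=GAP,
                                      skip_periods=1)
            grid = np.arange(0.0, 5 * T, 1.0)
            awake = np.zeros(grid.size, dtype=bool)
            for k, s in enumerate(t):
                end = min(s + GAP, t[k + 1]) if k + 1 < t.size else s + GAP
                awake[(grid >= s) & (grid < end)] = True
            W_d = W_n = 0.0
            for n_ in range(1, 5):
                day = (grid >= n_ * T) & (grid < (n_ + F_W) * T)
                night = (grid >= (n_ + F_W) * T) & (grid < (n_ + 1) * T)
                W_d += awake[day].sum()
                W_n += awake[night].sum()
            q_grid = (W_d / 4) / (F_W * T) - (W_n / 4) / ((1 - F_W) * T)
            assert rep.Q == pytest.approx(q_grid, abs=0.01)

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError):
            quality_coefficient([], T=0.0, n_periods=6)
        with pytest.raises(ValueError):
            quality_coefficient([], T, f_w=1.5, n_periods=6)
        with pytest.raises(ValueError):
            quality_coefficient([], T, n_periods=1, skip_periods=1)


class TestClassifyPeriodicity:
    def test_every_day_awake_is_period1(self):
        W = np.array([14.0, 14.1, 13.9, 14.0, 14.2, 14.0]) * 1000.0
        assert classify_periodicity(W, T, F_W) == "period1"

    def test_alternation_is_period2(self):
        W = np.array([14.0, 0.3, 14.2, 0.2, 13.8, 0.4]) * 1000.0
        assert classify_periodicity(W, T, F_W) == "period2"

    def test_broken_alternation_is_irregular(self):
        W = np.array([14.0, 0.3, 0.2, 14.0, 14.0, 0.1]) * 1000.0
        assert classify_periodicity(W, T, F_W) == "irregular"

    def test_too_few_periods_rejected(self):
        with pytest.raises(ValueError):
            classify_periodicity([14000.0] * 5, T, F_W)


class TestSyntheticSpikeTrain:
    def test_zero_windows_yield_empty_train(self):
        assert synthetic_spike_train([], isi=20.0).size == 0

    def test_overlapping_windows_rejected(self):
        with pytest.raises(ValueError, match="overlapping"):
            synthetic_spike_train([(0.0, 1000.0), (500.0, 1500.0)], isi=20.0)

    def test_reproducible_per_seed(self):
        w = trimmed_day_windows(3)
        a = synthetic_spike_train(w, isi=20.0, jitter=5.0, seed=3)
        b = synthetic_spike_train(w, isi=20.0, jitter=5.0, seed=3)
        np.testing.assert_array_equal(a, b)

    def test_spikes_confined_to_windows(self):
        w = [(1000.0, 2000.0), (5000.0, 6000.0)]
        t = synthetic_spike_train(w, isi=30.0, jitter=10.0, seed=1)
        inside = ((t >= 1000.0) & (t < 2000.0)) | ((t >= 5000.0) & (t < 6000.0))
        assert inside.all()
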