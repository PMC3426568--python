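import dataclasses

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import optimize
from scipy.special import expit

from orexinet.model import (ModelParams, NetworkConfig, NetworkState,
                            derivatives, initial_silent_state, ionic_current,
                            resting_potential, sigmoid_activation)
from orexinet.experiments import default_config
from orexinet.integrator import run_simulation


# ---------------------------------------------------------------------------
# sigmoid activation
# ---------------------------------------------------------------------------

class TestSigmoidActivation:
    def test_half_value_at_half_potential(self):
        assert sigmoid_activation(-25.0, 0.25, -25.0) == pytest.approx(0.5)

    def test_saturation(self):
        assert sigmoid_activation(975.0, 0.25, -25.0) == pytest.approx(1.0, abs=1e-12)
        assert sigmoid_activation(-1025.0, 0.25, -25.0) == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_quartile(self):
        # s (V - Vh) = 0.25 · 4 ln 3 = ln 3, and 1/(1 + e^{-ln 3}) = 3/4
        V = -25.0 + 4.0 * np.log(3.0)
        assert sigmoid_activation(V, 0.25, -25.0) == pytest.approx(0.75, abs=1e-12)

    def test_rejects_non_finite_voltage(self):
        with pytest.raises(ValueError):
            sigmoid_activation(np.nan, 0.25, -25.0)
        with pytest.raises(ValueError):
            sigmoid_activation(np.inf, 0.25, -25.0)

    def test_rejects_non_positive_slope(self):
        with pytest.raises(ValueError):
            sigmoid_activation(0.0, -0.25, -25.0)

    @given(st.floats(-200, 200), st.floats(-200, 200),
           st.floats(0.01, 2.0), st.floats(-80, 0))
    def test_strictly_increasing_and_bounded(self, v1, v2, slope, vh):
        a1 = sigmoid_activation(v1, slope, vh)
        a2 = sigmoid_activation(v2, slope, vh)
        assert 0.0 <= a1 <= 1.0
        if v2 - v1 > 1e-3:  # separation large enough to resolve in float64
            assert a2 >= a1
            if 1e-9 < a1 and a2 < 1.0 - 1e-9:  # away from saturation
                assert a2 > a1


# ---------------------------------------------------------------------------
# ionic currents
# ---------------------------------------------------------------------------

class TestIonicCurrent:
    @pytest.fixture
    def p(self):
        return ModelParams()

    @pytest.mark.parametrize("kind, attr", [
        ("L", "V_L"), ("K", "V_K"), ("gl", "V_gl"), ("ox", "V_ox"), ("Na", "V_Na"),
    ])
    def test_zero_driving_force(self, p, kind, attr):
        V_eq = getattr(p, attr)
        assert ionic_current(kind, V_eq, 0.5, p) == pytest.approx(0.0)

    def test_leak_is_linear(self, p):
        assert ionic_current("L", p.V_L + 10.0, 1.0, p) == pytest.approx(p.g_L * 10.0)

    def test_sodium_half_activation_composition(self, p):
        expected = 0.5 * p.g_Na * (p.Vh_Na - p.V_Na)
        assert ionic_current("Na", p.Vh_Na, None, p) == pytest.approx(expected)

    def test_unknown_kind_rejected(self, p):
        with pytest.raises(ValueError, match="unknown current kind"):
            ionic_current("Ca", -50.0, 0.5, p)

    def test_activation_outside_unit_interval_rejected(self, p):
        with pytest.raises(ValueError):
            ionic_current("K", -50.0, 1.5, p)


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------

class TestModelParams:
    def test_defaults_satisfy_invariants(self):
        assert ModelParams().validation_errors() == []

    @pytest.mark.parametrize("kwargs", [
        dict(g_Na=-1.0), dict(g_crit=1.5), dict(tau_K=50.0),  # tau ordering
        dict(V_K=-50.0, V_L=-60.0), dict(theta_dep=100.0),    # faster than tau_ox
    ])
    def test_violations_rejected(self, kwargs):
        with pytest.raises(ValueError, match="invalid ModelParams"):
            ModelParams(**kwargs)

    def test_rescaling_scales_slow_constants_proportionally(self):
        p = ModelParams()
        q = p.rescaled(8000.0)
        f = 8000.0 / p.T_day
        assert q.theta_dep == pytest.approx(p.theta_dep * f)
        assert q.theta_rec == pytest.approx(p.theta_rec * f)
        assert q.tau_ox == pytest.approx(p.tau_ox * f)
        assert q.tau_K == p.tau_K and q.tau_gl == p.tau_gl


# ---------------------------------------------------------------------------
# state packing
# ---------------------------------------------------------------------------

class TestNetworkState:
    def test_vector_round_trip(self, rng):
        n, m = 4, 4
        s = NetworkState(rng.uniform(-80, 0, n), rng.uniform(0, 1, n),
                         rng.uniform(0, 1, n), rng.uniform(0, 1, m),
                         rng.uniform(0, 1, n), rng.uniform(0, 1, n),
                         V_B=-55.0, aK_B=0.1)
        s2 = NetworkState.from_vector(s.to_vector(), n, m)
        for f in dataclasses.fields(NetworkState):
            np.testing.assert_array_equal(getattr(s, f.name), getattr(s2, f.name))

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            NetworkState(np.zeros(3), np.zeros(2), np.zeros(3), np.zeros(3),
                         np.zeros(3), np.zeros(3), -60.0, 0.0)


class TestNetworkConfig:
    def test_zero_diversity_thresholds_equal_mean(self):
        cfg = default_config(N=5)
        assert np.all(cfg.thresholds_BA == cfg.params.theta_gl_mean)
        assert np.all(cfg.thresholds_AB == cfg.params.theta_gl_mean)

    def test_bad_source_mapping_rejected(self):
        cfg = default_config(N=3)
        with pytest.raises(ValueError):
            NetworkConfig(N=3, params=cfg.params, stimulus=cfg.stimulus,
                          thresholds_AB=np.full(3, -30.0),
                          ab_source=np.array([0, 1, 5]))


# ---------------------------------------------------------------------------
# right-hand side
# ---------------------------------------------------------------------------

def _random_homogeneous_state(config, rng):
    n, m = config.N, config.M
    V = rng.uniform(-70, -20)
    return NetworkState(np.full(n, V), np.full(n, rng.uniform(0, 1)),
                        np.full(n, rng.uniform(0, 1)),
                        np.full(m, rng.uniform(0, 1)),
                        np.full(n, rng.uniform(0, 1)),
                        np.full(n, rng.uniform(0.5, 1)),
                        V_B=rng.uniform(-70, -20), aK_B=rng.uniform(0, 1))


class TestDerivatives:
    def test_permutation_symmetry_and_exact_gap_cancellation(self, rng):
        cfg = default_config(N=7)
        s = _random_homogeneous_state(cfg, rng)
        d = derivatives(s, 500.0, cfg)
        for name in ("V_A", "aK_A", "a_glBA", "a_glAB", "a_ox", "g_ox_avail"):
            arr = getattr(d, name)
            np.testing.assert_array_equal(arr, np.full_like(arr, arr[0]))

    def test_n1_reduces_to_two_neuron_equations(self, rng):
        """N=1 network RHS equals an independently coded two-neuron RHS."""
        cfg = default_config(N=1, delta_I=1.3)
        p = cfg.params
        s = _random_homogeneous_state(cfg, rng)
        d = derivatives(s, 500.0, cfg)

        sig = lambda V, sl, vh: 1.0 / (1.0 + np.exp(-sl * (V - vh)))
        V_a, V_b = s.V_A[0], s.V_B
        I_ext = 1.3  # t=500 ms is inside the pulse window
        dV_a = (-p.g_L * (V_a - p.V_L)
                - p.g_Na * sig(V_a, p.s_Na, p.Vh_Na) * (V_a - p.V_Na)
                - p.g_K * s.aK_A[0] * (V_a - p.V_K)
                - p.g_gl * s.a_glBA[0] * (V_a - p.V_gl) + I_ext) / p.C_m
        gate = sig(s.g_ox_avail[0], p.gate_steepness, p.g_crit)
        fire = sig(V_a, p.s_ox, p.theta_ox)
        dV_b = (-p.g_L * (V_b - p.V_L)
                - p.g_Na * sig(V_b, p.s_Na, p.Vh_Na) * (V_b - p.V_Na)
                - p.g_K * s.aK_B * (V_b - p.V_K)
                - p.g_gl * s.a_glAB[0] * (V_b - p.V_gl)
                - p.g_ox * s.a_ox[0] * (V_b - p.V_ox)) / p.C_m

        assert d.V_A[0] == pytest.approx(dV_a, rel=1e-12)
        assert d.V_B == pytest.approx(dV_b, rel=1e-12)
        assert d.aK_A[0] == pytest.approx(
            (sig(V_a, p.s_K, p.Vh_K) - s.aK_A[0]) / p.tau_K, rel=1e-12)
        assert d.a_glBA[0] == pytest.approx(
            (sig(V_b, p.s_gl, p.theta_gl_mean) - s.a_glBA[0]) / p.tau_gl, rel=1e-12)
        assert d.a_glAB[0] == pytest.approx(
            (sig(V_a, p.s_gl, p.theta_gl_mean) - s.a_glAB[0]) / p.tau_gl, rel=1e-12)
        assert d.a_ox[0] == pytest.approx(
            (gate * fire - s.a_ox[0]) / p.tau_ox, rel=1e-12)
        assert d.g_ox_avail[0] == pytest.approx(
            (1 - s.g_ox_avail[0]) / p.theta_rec
            - fire * s.g_ox_avail[0] / p.theta_dep, rel=1e-12)

    def test_silent_fixed_point_has_vanishing_derivative(self):
        """An independently located rest point annihilates the full RHS.

        The slow variables' equilibria are eliminated analytically (activation
        sigmoids at the rest voltages; availability at the balance of recovery
        and depletion), leaving a 2-d current-balance root problem in the two
        membrane potentials.
        """
        cfg = default_config(N=3, delta_I=0.0)
        from dataclasses import replace
        cfg = replace(cfg, stimulus=replace(cfg.stimulus, enabled=False))
        p = cfg.params
        sig = lambda V, sl, vh: 1.0 / (1.0 + np.exp(-sl * (V - vh)))
        th = p.theta_gl_mean

        def slow_equilibria(V_a, V_b):
            fire = sig(V_a, p.s_ox, p.theta_ox)
            g = (1.0 / p.theta_rec) / (1.0 / p.theta_rec + fire / p.theta_dep)
            a_ox = sig(g, p.gate_steepness, p.g_crit) * fire
            return g, a_ox

        def balance(x):
            V_a, V_b = x
            g, a_ox = slow_equilibria(V_a, V_b)
            f_a = (-p.g_L * (V_a - p.V_L)
                   - p.g_Na * sig(V_a, p.s_Na, p.Vh_Na) * (V_a - p.V_Na)
                   - p.g_K * sig(V_a, p.s_K, p.Vh_K) * (V_a - p.V_K)
                   - p.g_gl * sig(V_b, p.s_gl, th) * (V_a - p.V_gl))
            f_b = (-p.g_L * (V_b - p.V_L)
                   - p.g_Na * sig(V_b, p.s_Na, p.Vh_Na) * (V_b - p.V_Na)
                   - p.g_K * sig(V_b, p.s_K, p.Vh_K) * (V_b - p.V_K)
                   - p.g_gl * sig(V_a, p.s_gl, th) * (V_b - p.V_gl)
                   - p.g_ox * a_ox * (V_b - p.V_ox))
            return [f_a, f_b]

        sol = optimize.root(balance, [-60.0, -60.0])
        V_a, V_b = sol.x
        assert np.linalg.norm(balance(sol.x)) < 1e-10
        g, a_ox = slow_equilibria(V_a, V_b)
        state = NetworkState(
            np.full(3, V_a), np.full(3, sig(V_a, p.s_K, p.Vh_K)),
            np.full(3, sig(V_b, p.s_gl, th)), np.full(3, sig(V_a, p.s_gl, th)),
            np.full(3, a_ox), np.full(3, g),
            V_B=V_b, aK_B=sig(V_b, p.s_K, p.Vh_K))
        residual = derivatives(state, 0.0, cfg).to_vector()
        assert np.linalg.norm(residual) < 1e-8
        # ... and it is (to availability relaxation) where the silent initial
        # state puts the network
        y0 = initial_silent_state(cfg).to_vector()
        assert abs(y0[0] - V_a) < 0.01

    def test_dimension_mismatch_rejected(self, rng):
        cfg = default_config(N=3)
        s = _random_homogeneous_state(default_config(N=4), rng)
        with pytest.raises(ValueError):
            derivatives(s, 0.0, cfg)


# ---------------------------------------------------------------------------
# silent state & excitability
# ---------------------------------------------------------------------------

class TestSilentStateAndExcitability:
    def test_initial_state_is_identical_and_recovered(self):
        cfg = default_config(N=6)
        s = initial_silent_state(cfg)
        assert np.ptp(s.V_A) == 0.0
        np.testing.assert_array_equal(s.g_ox_avail, np.ones(6))
        assert abs(s.V_A[0] - resting_potential(cfg.params)) < 1.0

    def test_no_stimulus_means_no_spikes(self, calibrated_params):
        cfg = default_config(N=1, params=calibrated_params, delta_I=0.0)
        from dataclasses import replace
        cfg = replace(cfg, stimulus=replace(cfg.stimulus, enabled=False))
        rec = run_simulation(cfg, duration=cfg.params.T_day, dt=0.1)
        assert rec.n_spikes == 0

    def test_supra_threshold_pulse_ignites_wake_outlasting_it(self, two_neuron_supra):
        rec = run_simulation(two_neuron_supra, duration=two_neuron_supra.params.T_day,
                             dt=0.1)
        last = rec.spikes_of("B")[-1]
        assert last > 5 * two_neuron_supra.stimulus.delta_T

    def test_trajectories_stay_bounded(self, two_neuron_supra):
        p = two_neuron_supra.params
        rec = run_simulation(two_neuron_supra, duration=2 * p.T_day, dt=0.1,
                             record_traces=True)
        V = np.concatenate([rec.traces["V_B"], rec.traces["V_A0"]])
        assert V.min() > p.V_K - 5.0 and V.max() < p.V_Na + 5.0
        assert np.all((rec.traces["g_avail_mean"] >= 0)
                      & (rec.traces["g_avail_mean"] <= 1))
        assert np.all((rec.traces["a_ox_mean"] >= 0)
                      & (rec.traces["a_ox_mean"] <= 1))
        f = rec.final_state
        for arr in (f.aK_A, f.a_glBA, f.a_glAB, f.a_ox, f.g_ox_avail):
            assert np.all((arr >= 0) & (arr <= 1))
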