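"""Core dynamical system: the orexin/glutamate sleep-wake network.

The model couples ``N`` orexin-producing neurons (the "A" population, all-to-all
gap-junction coupled, driven by a periodic circadian current) to a single
glutamatergic interneuron ("B").  Each neuron is a two-variable
conductance-based unit (membrane potential plus a slow potassium activation;
the sodium current activates instantaneously).  A and B excite each other
through glutamatergic synapses; in addition each A neuron excites B through an
orexinergic synapse whose efficacy is gated by a slowly depleting/recovering
orexin availability variable.  That availability variable is the homeostatic
sleep drive: it runs down during tonic firing (wakefulness) and recovers
during silence (sleep), so a sufficiently strong circadian pulse ignites a
self-sustained wake episode that terminates itself once orexin is depleted.

Units: voltages in mV, time in ms, currents in µA/cm², conductances in mS/cm²,
capacitance in µF/cm².  Time is "rescaled model time": the daily period
defaults to 24 000 ms standing in for 24 h, with the slow orexin constants
rescaled in proportion (the fast ionic time scales are physiological).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import optimize
from scipy.special import expit

from .stimulus import StimulusSpec, pulse_current

__all__ = [
    "ModelParams",
    "NetworkState",
    "NetworkConfig",
    "sigmoid_activation",
    "ionic_current",
    "derivatives",
    "initial_silent_state",
    "resting_potential",
]


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelParams:
    """All membrane, synaptic and homeostatic constants for one neuron class.

    Both neuron classes (orexin A cells and the glutamate B cell) share the
    same membrane parameters; they differ only in their synaptic inputs.  The
    defaults are a calibrated set for the rescaled day ``T_day = 24 s``: they
    give a silent resting state without input, tonic single-spike firing under
    depolarisation, and a wake episode terminated by orexin depletion.  The
    slow constants ``theta_dep``/``theta_rec`` are the natural knobs for the
    wake-fraction calibration (see :func:`orexinet.experiments.calibrate_orexin_timescales`).
    """

    # membrane
    C_m: float = 1.0          # µF/cm²
    g_L: float = 0.1          # mS/cm²
    g_Na: float = 1.5
    g_K: float = 2.0
    g_gl: float = 0.1
    g_ox: float = 0.35
    V_L: float = -60.0        # mV
    V_Na: float = 50.0
    V_K: float = -90.0
    V_gl: float = 50.0
    V_ox: float = 50.0
    # sigmoid activations
    s_Na: float = 0.25        # 1/mV
    s_K: float = 0.25
    s_gl: float = 0.25
    s_ox: float = 0.25
    Vh_Na: float = -25.0      # mV
    Vh_K: float = -25.0
    theta_gl_mean: float = -30.0
    theta_ox: float = -30.0
    # activation time constants
    tau_K: float = 2.0        # ms
    tau_gl: float = 10.0
    tau_ox: float = 500.0
    # orexin homeostat
    g_crit: float = 0.7       # availability gate centre, dimensionless
    gate_steepness: float = 10.0  # dimensionless, smooth-gate slope at g_crit
    theta_dep: float = 1600.0     # ms, depletion time constant
    theta_rec: float = 7300.0     # ms, recovery time constant
    # coupling among A neurons
    g_gap: float = 0.1        # mS/cm²
    # time scales
    T_day: float = 24000.0    # ms, rescaled daily period
    T_day_phys: float = 24.0  # h, physiological daily period

    def __post_init__(self) -> None:
        errors = self.validation_errors()
        if errors:
            raise ValueError("invalid ModelParams: " + "; ".join(errors))

    def validation_errors(self) -> list[str]:
        """Return a list of violated invariants (empty when valid)."""
        e: list[str] = []
        for name in ("C_m", "g_L", "g_Na", "g_K", "g_gl", "g_ox",
                     "tau_K", "tau_gl", "tau_ox", "theta_dep", "theta_rec",
                     "s_Na", "s_K", "s_gl", "s_ox", "T_day", "T_day_phys"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                e.append(f"{name} must be finite and > 0 (got {v})")
        if self.g_gap < 0:
            e.append(f"g_gap must be >= 0 (got {self.g_gap})")
        if not 0.0 < self.g_crit < 1.0:
            e.append(f"g_crit must lie in (0, 1) (got {self.g_crit})")
        if not (self.V_K < self.V_L < 0.0 < self.V_Na):
            e.append("equilibrium potentials must satisfy V_K < V_L < 0 < V_Na")
        if self.V_gl <= 0 or self.V_ox <= 0:
            e.append("V_gl and V_ox must be depolarising (> 0)")
        if not (self.tau_K < self.tau_gl <= self.tau_ox):
            e.append("time-scale ordering tau_K < tau_gl <= tau_ox violated")
        if not (self.tau_ox < self.theta_dep and self.tau_ox < self.theta_rec):
            e.append("orexin homeostat must be slower than tau_ox "
                     "(tau_ox < theta_dep, theta_rec)")
        if self.theta_dep > 10 * self.T_day or self.theta_rec > 10 * self.T_day:
            e.append("theta_dep/theta_rec must be of the order of T_day")
        return e

    def rescaled(self, T_day: float) -> "ModelParams":
        """Return a copy with the daily period changed to ``T_day`` and the
        slow orexin constants rescaled in proportion.

        The slow orexin constants (``tau_ox``, ``theta_dep``, ``theta_rec``)
        scale with the day; the fast ionic and synaptic time constants are
        left unchanged, which is valid as long as the rescaled constants stay
        much slower than ``tau_gl``.
        """
        f = T_day / self.T_day
        return replace(self, T_day=T_day,
                       tau_ox=self.tau_ox * f,
                       theta_dep=self.theta_dep * f,
                       theta_rec=self.theta_rec * f)


# ---------------------------------------------------------------------------
# State
# ---------------------------------------------------------------------------

@dataclass
class NetworkState:
    """Full dynamical state of the N+1-neuron network at one instant.

    Arrays of length ``N`` (or ``M`` for the A→B synapse bank, normally
    ``M == N``; it differs only in the effective two-neuron reduction where a
    single A neuron drives a mixture of A→B synapses):

    - ``V_A``: membrane potentials of the A neurons (mV)
    - ``aK_A``: potassium activations of the A neurons
    - ``a_glBA``: activations of the B→A glutamate synapses (at each A_i)
    - ``a_glAB``: activations of the A→B glutamate synapses (at B), length M
    - ``a_ox``: activations of the orexin-induced current onto B
    - ``g_ox_avail``: orexin availabilities, one homeostat per A neuron
    - ``V_B``, ``aK_B``: membrane potential and K activation of neuron B
    """

    V_A: np.ndarray
    aK_A: np.ndarray
    a_glBA: np.ndarray
    a_glAB: np.ndarray
    a_ox: np.ndarray
    g_ox_avail: np.ndarray
    V_B: float
    aK_B: float

    def __post_init__(self) -> None:
        for name in ("V_A", "aK_A", "a_glBA", "a_glAB", "a_ox", "g_ox_avail"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        n = self.n_neurons
        for name in ("aK_A", "a_glBA", "a_ox", "g_ox_avail"):
            if getattr(self, name).shape != (n,):
                raise ValueError(f"{name} must have length N={n}, "
                                 f"got {getattr(self, name).shape}")
        if self.a_glAB.ndim != 1 or self.a_glAB.size < 1:
            raise ValueError("a_glAB must be a non-empty 1-d array")

    @property
    def n_neurons(self) -> int:
        return self.V_A.size

    # flat-vector packing used by the integrator --------------------------------
    def to_vector(self) -> np.ndarray:
        return np.concatenate([
            self.V_A, self.aK_A, self.a_glBA, self.a_glAB, self.a_ox,
            self.g_ox_avail, [self.V_B, self.aK_B],
        ])

    @classmethod
    def from_vector(cls, y: np.ndarray, n: int, m: int | None = None) -> "NetworkState":
        m = n if m is None else m
        if y.size != 5 * n + m + 2:
            raise ValueError(f"state vector length {y.size} incompatible with "
                             f"N={n}, M={m}")
        o = 0
        parts = []
        for size in (n, n, n, m, n, n):
            parts.append(y[o:o + size])
            o += size
        return cls(*parts, V_B=float(y[o]), aK_B=float(y[o + 1]))

    def copy(self) -> "NetworkState":
        return NetworkState(self.V_A.copy(), self.aK_A.copy(),
                            self.a_glBA.copy(), self.a_glAB.copy(),
                            self.a_ox.copy(), self.g_ox_avail.copy(),
                            self.V_B, self.aK_B)


# ---------------------------------------------------------------------------
# Network configuration
# ---------------------------------------------------------------------------

@dataclass
class NetworkConfig:
    """Static description of one simulated network.

    ``thresholds_BA[i]`` is the half-activation threshold of the glutamate
    synapse from B onto A_i; ``thresholds_AB[j]`` that of the j-th A→B synapse
    at B.  With zero diversity both vectors are constant at
    ``params.theta_gl_mean``.  ``ab_source[j]`` names the A neuron whose
    voltage drives the j-th A→B synapse (the identity in the full model; all
    zeros in the effective two-neuron reduction).
    """

    N: int
    params: ModelParams
    stimulus: StimulusSpec
    noise: "object" = None       # NoiseSpec; late import avoided
    diversity: "object" = None   # DiversitySpec
    thresholds_BA: np.ndarray | None = None
    thresholds_AB: np.ndarray | None = None
    ab_source: np.ndarray | None = None

    def __post_init__(self) -> None:
        from .heterogeneity import DiversitySpec
        from .integrator import NoiseSpec
        if self.N < 1:
            raise ValueError(f"N must be >= 1 (got {self.N})")
        if self.noise is None:
            self.noise = NoiseSpec()
        if self.diversity is None:
            self.diversity = DiversitySpec()
        if self.thresholds_BA is None or self.thresholds_AB is None:
            from .heterogeneity import build_threshold_vectors
            th_ba, th_ab = build_threshold_vectors(
                self.N, self.params.theta_gl_mean, self.diversity)
            if self.thresholds_BA is None:
                self.thresholds_BA = th_ba
            if self.thresholds_AB is None:
                self.thresholds_AB = th_ab
        self.thresholds_BA = np.asarray(self.thresholds_BA, dtype=float)
        self.thresholds_AB = np.asarray(self.thresholds_AB, dtype=float)
        if self.thresholds_BA.shape != (self.N,):
            raise ValueError("thresholds_BA must have length N")
        if self.ab_source is None:
            if self.thresholds_AB.size != self.N:
                raise ValueError("thresholds_AB must have length N when no "
                                 "ab_source mapping is given")
            self.ab_source = np.arange(self.N)
        self.ab_source = np.asarray(self.ab_source, dtype=np.int64)
        if self.ab_source.shape != self.thresholds_AB.shape:
            raise ValueError("ab_source and thresholds_AB must align")
        if self.ab_source.min() < 0 or self.ab_source.max() >= self.N:
            raise ValueError("ab_source indices out of range")

    @property
    def M(self) -> int:
        """Number of A→B synapses (equals N except in the reduced model)."""
        return self.thresholds_AB.size

    def with_params(self, params: ModelParams) -> "NetworkConfig":
        return replace(self, params=params)


# ---------------------------------------------------------------------------
# Elementary pieces
# ---------------------------------------------------------------------------

def sigmoid_activation(V, slope: float, half_potential: float):
    """Steady-state activation ``1 / (1 + exp(-slope (V - half_potential)))``.

    Strictly increasing in ``V`` with limits 0 and 1; equals 1/2 at the
    half-activation potential.  ``V`` may be a scalar or array.
    """
    if slope <= 0:
        raise ValueError(f"slope must be > 0 (got {slope})")
    V = np.asarray(V, dtype=float)
    if not np.all(np.isfinite(V)):
        raise ValueError("non-finite membrane potential in sigmoid_activation")
    out = expit(slope * (V - half_potential))
    return float(out) if out.ndim == 0 else out


_CURRENT_KINDS = {"L", "Na", "K", "gl", "ox"}


def ionic_current(kind: str, V_post, activation, params: ModelParams):
    """Ionic or synaptic current ``g · a · (V_post − V_eq)`` in µA/cm².

    ``kind`` selects the conductance/equilibrium pair: leak ``L`` (activation
    fixed at 1), instantaneous sodium ``Na`` (activation recomputed from the
    postsynaptic voltage), potassium ``K``, glutamatergic ``gl`` and
    orexinergic ``ox``.  Positive values are outward (hyperpolarising) for
    ``V_post`` above the reversal potential.
    """
    if kind not in _CURRENT_KINDS:
        raise ValueError(f"unknown current kind {kind!r}; "
                         f"expected one of {sorted(_CURRENT_KINDS)}")
    p = params
    if kind == "L":
        return p.g_L * (np.asarray(V_post, float) - p.V_L)
    if kind == "Na":
        a = sigmoid_activation(V_post, p.s_Na, p.Vh_Na)
        return p.g_Na * a * (np.asarray(V_post, float) - p.V_Na)
    g, V_eq = {"K": (p.g_K, p.V_K), "gl": (p.g_gl, p.V_gl),
               "ox": (p.g_ox, p.V_ox)}[kind]
    a = np.asarray(activation, dtype=float)
    if np.any(a < 0) or np.any(a > 1):
        raise ValueError(f"activation for kind {kind!r} must lie in [0, 1]")
    return g * a * (np.asarray(V_post, float) - V_eq)


def availability_gate(g_avail, params: ModelParams):
    """Smooth gate ≈ 1 when orexin availability exceeds ``g_crit``, ≈ 0 below.

    A steep logistic in the availability keeps the vector field C¹; the
    Heaviside step is its infinite-steepness limit.
    """
    return expit(params.gate_steepness * (np.asarray(g_avail, float) - params.g_crit))


# ---------------------------------------------------------------------------
# Right-hand side (deterministic part)
# ---------------------------------------------------------------------------

def derivatives(state: NetworkState, t: float, config: NetworkConfig) -> NetworkState:
    """Deterministic time-derivative of the network state.

    Membrane equations (noise, when enabled, is added by the integrator):

    - each A neuron: leak + Na + K intrinsic currents, the B→A glutamate
      current, the all-to-all gap-junction current, and the circadian pulse;
    - neuron B: intrinsic currents plus the *population-averaged* glutamate
      and orexin currents from the A cells.

    Slow variables: first-order relaxation of the K and synaptic activations
    toward presynaptic-voltage sigmoids, the gated orexin activation, and the
    orexin availability homeostat (linear recovery toward 1 with time constant
    ``theta_rec``, depletion proportional to the presynaptic firing sigmoid
    with time constant ``theta_dep``).
    """
    p = config.params
    N = config.N
    if state.n_neurons != N or state.a_glAB.size != config.M:
        raise ValueError("state dimensions do not match the configuration")

    V_A, V_B = state.V_A, state.V_B

    I_L_A = ionic_current("L", V_A, 1.0, p)
    I_Na_A = ionic_current("Na", V_A, None, p)
    I_K_A = p.g_K * state.aK_A * (V_A - p.V_K)
    I_glBA = p.g_gl * state.a_glBA * (V_A - p.V_gl)
    # all-to-all gap current: sum_j g_gap (V_i - V_j); pairwise differences so
    # that identical potentials cancel exactly in floating point
    I_gap = p.g_gap * (V_A[:, None] - V_A[None, :]).sum(axis=1)
    I_ext = pulse_current(t, config.stimulus)

    dV_A = (-I_L_A - I_Na_A - I_K_A - I_glBA - I_gap + I_ext) / p.C_m
    daK_A = (sigmoid_activation(V_A, p.s_K, p.Vh_K) - state.aK_A) / p.tau_K
    # B→A glutamate synapses: driven by the presynaptic voltage V_B with
    # per-synapse thresholds
    da_glBA = (expit(p.s_gl * (V_B - config.thresholds_BA)) - state.a_glBA) / p.tau_gl
    # A→B glutamate synapses: driven by the source A neuron's voltage
    V_src = V_A[config.ab_source]
    da_glAB = (expit(p.s_gl * (V_src - config.thresholds_AB)) - state.a_glAB) / p.tau_gl
    # orexin activation: gated by availability, driven by the A firing sigmoid
    fire = sigmoid_activation(V_A, p.s_ox, p.theta_ox)
    da_ox = (availability_gate(state.g_ox_avail, p) * fire - state.a_ox) / p.tau_ox
    # availability homeostat
    dg = (1.0 - state.g_ox_avail) / p.theta_rec - fire * state.g_ox_avail / p.theta_dep

    # neuron B
    I_L_B = ionic_current("L", V_B, 1.0, p)
    I_Na_B = ionic_current("Na", V_B, None, p)
    I_K_B = p.g_K * state.aK_B * (V_B - p.V_K)
    I_gl_B = p.g_gl * float(np.mean(state.a_glAB)) * (V_B - p.V_gl)
    I_ox_B = p.g_ox * float(np.mean(state.a_ox)) * (V_B - p.V_ox)
    dV_B = (-I_L_B - I_Na_B - I_K_B - I_gl_B - I_ox_B) / p.C_m
    daK_B = (sigmoid_activation(V_B, p.s_K, p.Vh_K) - state.aK_B) / p.tau_K

    return NetworkState(dV_A, daK_A, da_glBA, da_glAB, da_ox, dg,
                        float(dV_B), float(daK_B))


# ---------------------------------------------------------------------------
# Resting / initial state
# ---------------------------------------------------------------------------

def resting_potential(params: ModelParams) -> float:
    """Resting potential of an isolated neuron (no synaptic input, no drive).

    Root of the intrinsic current balance with the K activation at its
    voltage equilibrium; bracketed between ``V_K`` and the Na half-activation
    potential, where the silent fixed point lives.
    """
    p = params

    def balance(V: float) -> float:
        aK = sigmoid_activation(V, p.s_K, p.Vh_K)
        return (p.g_L * (V - p.V_L)
                + p.g_Na * sigmoid_activation(V, p.s_Na, p.Vh_Na) * (V - p.V_Na)
                + p.g_K * aK * (V - p.V_K))

    return float(optimize.brentq(balance, p.V_K, p.Vh_Na, xtol=1e-12))


def initial_silent_state(config: NetworkConfig) -> NetworkState:
    """Silent initial condition: identical fully-recovered neurons at rest.

    All membrane potentials sit at the network's silent fixed point (located
    by root-finding on the homogeneous reduction of :func:`derivatives` with
    availability held at 1), every activation at its sigmoid equilibrium, and
    the orexin availability fully recovered (``g_ox_avail = 1``).
    """
    p = config.params
    V0 = resting_potential(p)

    def residual(x: np.ndarray) -> np.ndarray:
        V_a, V_b = x
        aK_a = sigmoid_activation(V_a, p.s_K, p.Vh_K)
        aK_b = sigmoid_activation(V_b, p.s_K, p.Vh_K)
        a_ba = float(np.mean(expit(p.s_gl * (V_b - config.thresholds_BA))))
        a_ab = float(np.mean(expit(p.s_gl * (V_a - config.thresholds_AB))))
        a_ox = availability_gate(1.0, p) * sigmoid_activation(V_a, p.s_ox, p.theta_ox)
        f_a = (-p.g_L * (V_a - p.V_L)
               - p.g_Na * sigmoid_activation(V_a, p.s_Na, p.Vh_Na) * (V_a - p.V_Na)
               - p.g_K * aK_a * (V_a - p.V_K)
               - p.g_gl * a_ba * (V_a - p.V_gl))
        f_b = (-p.g_L * (V_b - p.V_L)
               - p.g_Na * sigmoid_activation(V_b, p.s_Na, p.Vh_Na) * (V_b - p.V_Na)
               - p.g_K * aK_b * (V_b - p.V_K)
               - p.g_gl * a_ab * (V_b - p.V_gl)
               - p.g_ox * a_ox * (V_b - p.V_ox))
        return np.array([f_a, f_b])

    sol = optimize.root(residual, np.array([V0, V0]), tol=1e-13)
    V_a, V_b = (sol.x if sol.success else np.array([V0, V0]))

    N, M = config.N, config.M
    aK_a = sigmoid_activation(V_a, p.s_K, p.Vh_K)
    a_ba = expit(p.s_gl * (V_b - config.thresholds_BA))
    a_ab = expit(p.s_gl * (V_a - config.thresholds_AB))
    a_ox = np.full(N, availability_gate(1.0, p)
                   * sigmoid_activation(V_a, p.s_ox, p.theta_ox))
    return NetworkState(
        V_A=np.full(N, V_a),
        aK_A=np.full(N, aK_a),
        a_glBA=np.asarray(a_ba, float).reshape(N),
        a_glAB=np.asarray(a_ab, float).reshape(M),
        a_ox=a_ox,
        g_ox_avail=np.ones(N),
        V_B=float(V_b),
        aK_B=float(sigmoid_activation(V_b, p.s_K, p.Vh_K)),
    )
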