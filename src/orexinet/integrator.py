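"""Stochastic Heun time stepping and the simulation driver.

The Heun scheme is a predictor-corrector (deterministic order 2) that remains
consistent for SDEs with additive noise provided the *same* Wiener increment
is applied in the predictor and the corrector.  Noise enters only the
membrane-potential equations, as zero-mean Gaussian white currents with
correlation ⟨ξ(t)ξ(t′)⟩ = 2D δ(t−t′): each step adds
``sqrt(2 D dt)/C_m · N(0,1)`` to the voltage being updated.

Two code paths share the same mathematics:

- :func:`heun_step` / :func:`heun_step_network` — plain NumPy, one step at a
  time, used for validation and as the reference in equivalence tests;
- a numba-compiled chunked kernel used by :func:`run_simulation`, which also
  performs online spike detection and optional trace down-sampling.

Noise streams for the A population and for neuron B are independent children
of the master seed, so the B stream is identical regardless of how many A
neurons are simulated (this underlies the exact N-independence of the
noise-on-B experiment).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numba as nb
import numpy as np

from .model import NetworkConfig, NetworkState, derivatives

__all__ = [
    "NoiseSpec",
    "SpikeRecord",
    "heun_step",
    "heun_step_network",
    "run_simulation",
]


@dataclass(frozen=True)
class NoiseSpec:
    """Additive current-noise intensities (µA²·ms/cm⁴) and their seed.

    ``D_A`` acts on every A-neuron membrane equation (independent streams),
    ``D_B`` on neuron B.  ``seed`` is the master seed from which the per-neuron
    streams are spawned.
    """

    D_A: float = 0.0
    D_B: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.D_A < 0 or self.D_B < 0:
            raise ValueError("noise intensities must be >= 0")


@dataclass
class SpikeRecord:
    """Result of one simulation run.

    ``spike_times`` maps neuron ids (``"A0"``..``"A{N-1}"``, ``"B"``) to
    strictly increasing arrays of spike times in ms.  ``traces`` (optional)
    holds down-sampled time series: ``t``, ``V_B``, ``V_A0``, ``a_ox_mean``
    and ``g_avail_mean``.
    """

    spike_times: dict
    dt: float
    duration: float
    config_echo: dict
    traces: dict | None = None
    final_state: NetworkState | None = None

    def spikes_of(self, neuron_id: str) -> np.ndarray:
        return self.spike_times[neuron_id]

    @property
    def n_spikes(self) -> int:
        return int(sum(len(v) for v in self.spike_times.values()))

    def to_frame(self):
        """Long-format spikes table (columns: neuron_id, t_ms)."""
        import pandas as pd
        ids, times = [], []
        for k in sorted(self.spike_times):
            v = self.spike_times[k]
            ids.extend([k] * len(v))
            times.extend(v.tolist())
        return pd.DataFrame({"neuron_id": ids, "t_ms": times})


# ---------------------------------------------------------------------------
# Generic Heun step (reference path)
# ---------------------------------------------------------------------------

def heun_step(y, t: float, dt: float, rhs: Callable, noise=None):
    """One stochastic Heun step of ``dy = rhs(y, t) dt + dW``.

    ``noise`` is the *increment already scaled to state units* (for membrane
    noise: ``sqrt(2D)/C_m · dW`` with ``dW ~ N(0, dt)``); the same increment
    enters the predictor and the corrector, as required for additive noise.
    With ``noise=None`` this is the deterministic Heun / RK2 trapezoidal rule.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    y = np.asarray(y, dtype=float)
    k1 = np.asarray(rhs(y, t), dtype=float)
    y_pred = y + dt * k1
    if noise is not None:
        y_pred = y_pred + noise
    k2 = np.asarray(rhs(y_pred, t + dt), dtype=float)
    y_new = y + 0.5 * dt * (k1 + k2)
    if noise is not None:
        y_new = y_new + noise
    return y_new


def _state_var_name(idx: int, n: int, m: int) -> str:
    bounds = [(n, "V_A"), (n, "aK_A"), (n, "a_glBA"), (m, "a_glAB"),
              (n, "a_ox"), (n, "g_ox_avail")]
    o = 0
    for size, name in bounds:
        if idx < o + size:
            return f"{name}[{idx - o}]"
        o += size
    return "V_B" if idx == o else "aK_B"


def heun_step_network(state: NetworkState, t: float, dt: float,
                      config: NetworkConfig,
                      dW_A=None, dW_B: float = 0.0) -> NetworkState:
    """One Heun step of the full network (reference NumPy path).

    ``dW_A`` (length-N array) and ``dW_B`` are Wiener increments ~ N(0, dt)
    for the membrane equations; they are scaled by ``sqrt(2D)/C_m`` here.
    Orexin availabilities are clamped to [0, 1] after the step.
    """
    p = config.params
    n, m = config.N, config.M
    y = state.to_vector()

    noise = None
    if (dW_A is not None and config.noise.D_A > 0) or \
            (config.noise.D_B > 0 and dW_B != 0.0):
        noise = np.zeros_like(y)
        if dW_A is not None and config.noise.D_A > 0:
            noise[:n] = np.sqrt(2.0 * config.noise.D_A) / p.C_m * np.asarray(dW_A)
        if config.noise.D_B > 0:
            noise[5 * n + m] = np.sqrt(2.0 * config.noise.D_B) / p.C_m * dW_B

    def rhs(yv, tv):
        return derivatives(NetworkState.from_vector(yv, n, m), tv, config).to_vector()

    y_new = heun_step(y, t, dt, rhs, noise)
    if not np.all(np.isfinite(y_new)):
        bad = int(np.flatnonzero(~np.isfinite(y_new))[0])
        raise FloatingPointError(
            f"non-finite state after Heun step at t={t} ms: first offending "
            f"variable {_state_var_name(bad, n, m)}")
    g_lo, g_hi = 4 * n + m, 5 * n + m
    np.clip(y_new[g_lo:g_hi], 0.0, 1.0, out=y_new[g_lo:g_hi])
    return NetworkState.from_vector(y_new, n, m)


# ---------------------------------------------------------------------------
# Numba kernel (fast path)
# ---------------------------------------------------------------------------

# parameter-vector layout shared by _pack_params and the kernel
_P_NAMES = ("C_m", "g_L", "g_Na", "g_K", "g_gl", "g_ox",
            "V_L", "V_Na", "V_K", "V_gl", "V_ox",
            "s_Na", "s_K", "s_gl", "s_ox",
            "Vh_Na", "Vh_K", "theta_ox",
            "tau_K", "tau_gl", "tau_ox",
            "g_crit", "gate_steepness", "theta_dep", "theta_rec", "g_gap")
_IDX = {name: i for i, name in enumerate(_P_NAMES)}
_I_STIM_DI = len(_P_NAMES)
_I_STIM_DT = len(_P_NAMES) + 1
_I_STIM_PERIOD = len(_P_NAMES) + 2
_P_LEN = len(_P_NAMES) + 3


def _pack_params(config: NetworkConfig) -> np.ndarray:
    P = np.empty(_P_LEN)
    for name, i in _IDX.items():
        P[i] = getattr(config.params, name)
    s = config.stimulus
    P[_I_STIM_DI] = s.delta_I if s.enabled else 0.0
    P[_I_STIM_DT] = s.delta_T
    P[_I_STIM_PERIOD] = s.period
    return P


@nb.njit(cache=True, fastmath=False)
def _kernel_rhs(y, t, N, M, P, thBA, thAB, absrc, dy):  # pragma: no cover - jit
    C_m = P[0]
    g_L = P[1]; g_Na = P[2]; g_K = P[3]; g_gl = P[4]; g_ox = P[5]
    V_L = P[6]; V_Na = P[7]; V_K = P[8]; V_gl = P[9]; V_ox = P[10]
    s_Na = P[11]; s_K = P[12]; s_gl = P[13]; s_ox = P[14]
    Vh_Na = P[15]; Vh_K = P[16]; th_ox = P[17]
    tau_K = P[18]; tau_gl = P[19]; tau_ox = P[20]
    g_crit = P[21]; gate_s = P[22]; th_dep = P[23]; th_rec = P[24]
    g_gap = P[25]
    dI = P[26]; dT = P[27]; period = P[28]

    iVB = 5 * N + M
    V_B = y[iVB]
    aK_B = y[iVB + 1]

    I_ext = 0.0
    if dI > 0.0:
        phase = t % period
        if phase < dT:
            I_ext = dI

    # means computed as base + mean(value - base): exact when all entries are
    # bitwise identical, which keeps the homogeneous network and its
    # two-neuron reduction on the same trajectory to the last bit
    ab0 = y[3 * N]
    dev_ab = 0.0
    for j in range(M):
        i_src = absrc[j]
        eq = 1.0 / (1.0 + np.exp(-s_gl * (y[i_src] - thAB[j])))
        dy[3 * N + j] = (eq - y[3 * N + j]) / tau_gl
        dev_ab += y[3 * N + j] - ab0
    mean_ab = ab0 + dev_ab / M

    ox0 = y[3 * N + M]
    dev_ox = 0.0
    for i in range(N):
        V = y[i]
        aK = y[N + i]
        a_ba = y[2 * N + i]
        a_ox = y[3 * N + M + i]
        g_av = y[4 * N + M + i]
        dev_ox += a_ox - ox0

        aNa = 1.0 / (1.0 + np.exp(-s_Na * (V - Vh_Na)))
        gap = 0.0
        for j in range(N):
            gap += V - y[j]
        I_mem = (g_L * (V - V_L) + g_Na * aNa * (V - V_Na)
                 + g_K * aK * (V - V_K) + g_gl * a_ba * (V - V_gl)
                 + g_gap * gap)
        dy[i] = (-I_mem + I_ext) / C_m
        dy[N + i] = (1.0 / (1.0 + np.exp(-s_K * (V - Vh_K))) - aK) / tau_K
        dy[2 * N + i] = (1.0 / (1.0 + np.exp(-s_gl * (V_B - thBA[i]))) - a_ba) / tau_gl
        fire = 1.0 / (1.0 + np.exp(-s_ox * (V - th_ox)))
        gate = 1.0 / (1.0 + np.exp(-gate_s * (g_av - g_crit)))
        dy[3 * N + M + i] = (gate * fire - a_ox) / tau_ox
        dy[4 * N + M + i] = (1.0 - g_av) / th_rec - fire * g_av / th_dep
    mean_ox = ox0 + dev_ox / N

    aNaB = 1.0 / (1.0 + np.exp(-s_Na * (V_B - Vh_Na)))
    I_B = (g_L * (V_B - V_L) + g_Na * aNaB * (V_B - V_Na)
           + g_K * aK_B * (V_B - V_K)
           + g_gl * mean_ab * (V_B - V_gl)
           + g_ox * mean_ox * (V_B - V_ox))
    dy[iVB] = -I_B / C_m
    dy[iVB + 1] = (1.0 / (1.0 + np.exp(-s_K * (V_B - Vh_K))) - aK_B) / tau_K


@nb.njit(cache=True, fastmath=False)
def _heun_chunk(y, t0, dt, nsteps, N, M, P, thBA, thAB, absrc,
                xiA, ampA, xiB, ampB, v_rec):  # pragma: no cover - jit
    """Advance ``nsteps`` Heun steps in place; record observables per step.

    ``v_rec`` has shape (nsteps, N+3): columns 0..N-1 hold V_A, column N holds
    V_B, column N+1 the mean orexin availability, column N+2 the mean orexin
    activation.  Returns -1 on success, otherwise the index of the first
    unstable step (|V| > 500 mV or non-finite).
    """
    L = y.size
    k1 = np.empty(L)
    k2 = np.empty(L)
    yp = np.empty(L)
    iVB = 5 * N + M
    for k in range(nsteps):
        t = t0 + k * dt
        _kernel_rhs(y, t, N, M, P, thBA, thAB, absrc, k1)
        for i in range(L):
            yp[i] = y[i] + dt * k1[i]
        if ampA > 0.0:
            for i in range(N):
                yp[i] += ampA * xiA[k, i]
        if ampB > 0.0:
            yp[iVB] += ampB * xiB[k]
        _kernel_rhs(yp, t + dt, N, M, P, thBA, thAB, absrc, k2)
        for i in range(L):
            y[i] = y[i] + 0.5 * dt * (k1[i] + k2[i])
        if ampA > 0.0:
            for i in range(N):
                y[i] += ampA * xiA[k, i]
        if ampB > 0.0:
            y[iVB] += ampB * xiB[k]
        # clamp orexin availability to [0, 1]
        for i in range(4 * N + M, 5 * N + M):
            if y[i] < 0.0:
                y[i] = 0.0
            elif y[i] > 1.0:
                y[i] = 1.0
        ok = True
        for i in range(N):
            v_rec[k, i] = y[i]
            if not (-500.0 < y[i] < 500.0):
                ok = False
        v_rec[k, N] = y[iVB]
        if not (-500.0 < y[iVB] < 500.0):
            ok = False
        sg = 0.0
        sox = 0.0
        for i in range(N):
            sg += y[4 * N + M + i]
            sox += y[3 * N + M + i]
        v_rec[k, N + 1] = sg / N
        v_rec[k, N + 2] = sox / N
        if not ok:
            return k
    return -1


# ---------------------------------------------------------------------------
# Spike detection on sampled voltages (shared with spike_metrics)
# ---------------------------------------------------------------------------

def _crossings(prev_v, v_col, t0, dt, threshold, refractory, last_spike):
    """Upward threshold crossings in one chunk of a voltage trace.

    ``prev_v`` is the sample preceding the chunk (voltage at ``t0 - dt``...
    actually at ``t0``); samples ``v_col[k]`` are at times ``t0 + (k+1) dt``.
    Crossing times are linearly interpolated; crossings within ``refractory``
    of the previous accepted spike are suppressed.  Returns (times, new_last).
    """
    out = []
    v = np.concatenate(([prev_v], v_col))
    below = v[:-1] < threshold
    above = v[1:] >= threshold
    idx = np.flatnonzero(below & above)
    for k in idx:
        frac = (threshold - v[k]) / (v[k + 1] - v[k])
        t_sp = t0 + (k + frac) * dt
        if t_sp - last_spike >= refractory:
            out.append(t_sp)
            last_spike = t_sp
    return out, last_spike


# ---------------------------------------------------------------------------
# Driver
# ---------------------------------------------------------------------------

def _config_echo(config: NetworkConfig, duration, dt, seed) -> dict:
    from dataclasses import asdict
    return {
        "N": int(config.N),
        "params": asdict(config.params),
        "stimulus": asdict(config.stimulus),
        "noise": asdict(config.noise),
        "diversity": asdict(config.diversity),
        "thresholds_BA": np.asarray(config.thresholds_BA).tolist(),
        "thresholds_AB": np.asarray(config.thresholds_AB).tolist(),
        "ab_source": np.asarray(config.ab_source).tolist(),
        "duration_ms": float(duration),
        "dt_ms": float(dt),
        "seed": None if seed is None else int(seed),
    }


def run_simulation(config: NetworkConfig, duration: float, dt: float = 0.1,
                   seed: int | None = None, *,
                   initial_state: NetworkState | None = None,
                   spike_threshold: float = 0.0, refractory: float = 2.0,
                   record_traces: bool = False, trace_every: float = 1.0,
                   chunk_steps: int = 40000) -> SpikeRecord:
    """Integrate the network from the silent state and return its spikes.

    Noise streams are derived from ``seed`` (ignored in the noiseless case so
    noiseless runs are seed-independent).  Spikes are detected online as
    upward crossings of ``spike_threshold`` with a ``refractory`` dead time;
    optional traces are down-sampled every ``trace_every`` ms.

    Raises ``FloatingPointError`` when the integration becomes unstable
    (|V| > 500 mV or non-finite state).
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if dt > config.params.tau_K / 10.0:
        raise ValueError(f"dt={dt} too coarse: need dt <= tau_K/10 "
                         f"= {config.params.tau_K / 10.0} ms")
    if duration <= 0:
        raise ValueError("duration must be > 0")

    from .model import initial_silent_state

    N, M = config.N, config.M
    state0 = initial_state if initial_state is not None else initial_silent_state(config)
    y = state0.to_vector().copy()
    P = _pack_params(config)
    thBA = np.ascontiguousarray(config.thresholds_BA, dtype=float)
    thAB = np.ascontiguousarray(config.thresholds_AB, dtype=float)
    absrc = np.ascontiguousarray(config.ab_source, dtype=np.int64)

    D_A, D_B = config.noise.D_A, config.noise.D_B
    ampA = np.sqrt(2.0 * D_A * dt) / config.params.C_m
    ampB = np.sqrt(2.0 * D_B * dt) / config.params.C_m
    master = config.noise.seed if seed is None else seed
    rng_A = np.random.default_rng(np.random.SeedSequence([int(master), 11]))
    rng_B = np.random.default_rng(np.random.SeedSequence([int(master), 13]))

    n_steps = int(round(duration / dt))
    stride = max(1, int(round(trace_every / dt)))

    spike_lists: dict[str, list] = {f"A{i}": [] for i in range(N)}
    spike_lists["B"] = []
    last_spike = {k: -np.inf for k in spike_lists}
    prev_v = np.empty(N + 1)
    prev_v[:N] = y[:N]
    prev_v[N] = y[5 * N + M]

    tr_t, tr_vb, tr_va0, tr_g, tr_ox = [], [], [], [], []
    if record_traces:
        tr_t.append(0.0)
        tr_vb.append(y[5 * N + M])
        tr_va0.append(y[0])
        tr_g.append(float(np.mean(y[4 * N + M:5 * N + M])))
        tr_ox.append(float(np.mean(y[3 * N + M:4 * N + M])))

    empty = np.zeros((0, 0))
    done = 0
    while done < n_steps:
        n = min(chunk_steps, n_steps - done)
        xiA = rng_A.standard_normal((n, N)) if ampA > 0 else empty
        xiB = rng_B.standard_normal(n) if ampB > 0 else np.zeros(0)
        v_rec = np.empty((n, N + 3))
        status = _heun_chunk(y, done * dt, dt, n, N, M, P, thBA, thAB, absrc,
                             xiA, ampA, xiB, ampB, v_rec)
        if status >= 0:
            t_bad = (done + status + 1) * dt
            raise FloatingPointError(
                f"integration unstable at t={t_bad:.3f} ms "
                f"(|V| > 500 mV or non-finite); check parameters/noise level")
        t0 = done * dt
        for i in range(N + 1):
            key = "B" if i == N else f"A{i}"
            times, last_spike[key] = _crossings(
                prev_v[i], v_rec[:, i], t0, dt, spike_threshold,
                refractory, last_spike[key])
            spike_lists[key].extend(times)
        prev_v[:] = v_rec[-1, :N + 1]
        if record_traces:
            # sample global step indices s = done+k+1 with s % stride == 0
            first_k = (-done - 1) % stride
            for k in range(first_k, n, stride):
                tr_t.append((done + k + 1) * dt)
                tr_vb.append(v_rec[k, N])
                tr_va0.append(v_rec[k, 0])
                tr_g.append(v_rec[k, N + 1])
                tr_ox.append(v_rec[k, N + 2])
        done += n

    traces = None
    if record_traces:
        traces = {"t": np.asarray(tr_t), "V_B": np.asarray(tr_vb),
                  "V_A0": np.asarray(tr_va0),
                  "g_avail_mean": np.asarray(tr_g),
                  "a_ox_mean": np.asarray(tr_ox)}
    return SpikeRecord(
        spike_times={k: np.asarray(v) for k, v in spike_lists.items()},
        dt=dt, duration=duration,
        config_echo=_config_echo(config, duration, dt, master),
        traces=traces,
        final_state=NetworkState.from_vector(y, N, M),
    )
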