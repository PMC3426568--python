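"""Wake/sleep scoring of spike trains and the sleep-wake quality coefficient.

The wake state is identified with the spiking regime, sleep with silence.
Each spike extends the wake state for at most ``gap`` ms (default 250 ms) or
until the next spike, whichever comes first, so tonic firing (inter-spike
intervals well below ``gap``) produces contiguous wake episodes while an
isolated spike contributes a short awakening of length ``gap``.

Each daily period of length ``T`` splits into a "day" window covering the
first fraction ``f_w`` of the period (default 2/3 — 16 h of a 24-h day) and
the complementary "night" window.  With ``W_d(n)``/``W_n(n)`` the wake time
during day/night of period ``n``, the quality coefficient is the linear score

    Q = ⟨W_d⟩ / (f_w T) − ⟨W_n⟩ / ((1 − f_w) T)   ∈ [−1, 1],

maximal (+1) for wake all day and sleep all night, reduced by sleep during
the day or wakefulness at night.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "QReport",
    "detect_spikes",
    "wake_intervals",
    "wake_time_in_window",
    "quality_coefficient",
    "classify_periodicity",
    "synthetic_spike_train",
    "day_windows",
]

DEFAULT_GAP = 250.0       # ms a single spike keeps the system "awake"
DEFAULT_WAKE_FRACTION = 2.0 / 3.0


@dataclass
class QReport:
    """Per-period wake times and the quality coefficient of one spike train."""

    W_day: np.ndarray        # ms of wake in each retained day window
    W_night: np.ndarray      # ms of wake in each retained night window
    wake_fraction: float     # f_w
    period: float            # T, ms
    n_periods: int           # M, number of retained periods
    Q: float

    def to_frame(self):
        """Per-period table (columns: period_index, W_day_ms, W_night_ms)."""
        import pandas as pd
        return pd.DataFrame({
            "period_index": np.arange(self.W_day.size),
            "W_day_ms": self.W_day,
            "W_night_ms": self.W_night,
        })


def detect_spikes(V_trace, dt: float, spike_threshold: float = 0.0,
                  refractory: float = 2.0) -> np.ndarray:
    """Spike times (ms) from a regularly sampled voltage trace.

    Upward crossings of ``spike_threshold``, linearly interpolated between
    samples; crossings within ``refractory`` ms of the previous accepted spike
    are suppressed (double-peaked artifacts count once).
    """
    if refractory <= dt:
        raise ValueError("refractory must exceed the sampling step dt")
    V = np.asarray(V_trace, dtype=float)
    if V.size < 2:
        return np.empty(0)
    below = V[:-1] < spike_threshold
    above = V[1:] >= spike_threshold
    idx = np.flatnonzero(below & above)
    out = []
    last = -np.inf
    for k in idx:
        frac = (spike_threshold - V[k]) / (V[k + 1] - V[k])
        t = (k + frac) * dt
        if t - last >= refractory:
            out.append(t)
            last = t
    return np.asarray(out)


def wake_intervals(spike_times, gap: float = DEFAULT_GAP) -> list[tuple[float, float]]:
    """Disjoint wake intervals induced by a sorted spike train.

    Union over spikes ``k`` of ``[t_k, min(t_{k+1}, t_k + gap)]``, merged into
    maximal disjoint intervals.
    """
    t = np.asarray(spike_times, dtype=float)
    if t.size == 0:
        return []
    if np.any(np.diff(t) < 0):
        raise ValueError("spike times must be sorted")
    if gap <= 0:
        raise ValueError("gap must be > 0")
    ends = np.minimum(t + gap, np.append(t[1:], np.inf))
    merged: list[list[float]] = [[t[0], ends[0]]]
    for s, e in zip(t[1:], ends[1:]):
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(a, b) for a, b in merged]


def wake_time_in_window(intervals, lo: float, hi: float) -> float:
    """Total wake time (ms) that a set of intervals spends inside [lo, hi)."""
    total = 0.0
    for a, b in intervals:
        total += max(0.0, min(b, hi) - max(a, lo))
    return total


def quality_coefficient(spike_times, T: float,
                        f_w: float = DEFAULT_WAKE_FRACTION,
                        n_periods: int | None = None,
                        gap: float = DEFAULT_GAP,
                        skip_periods: int = 1) -> QReport:
    """Score a spike train's sleep-wake cycle on [−1, 1].

    Periods ``n = skip_periods .. n_periods − 1`` are retained (the default
    discards one initial transient period).  ``n_periods`` defaults to the
    number of whole periods spanned by the train.
    """
    if T <= 0:
        raise ValueError("period T must be > 0")
    if not 0.0 < f_w < 1.0:
        raise ValueError("wake fraction f_w must lie in (0, 1)")
    t = np.asarray(spike_times, dtype=float)
    if n_periods is None:
        n_periods = max(int(np.ceil(t.max() / T)) if t.size else 1, skip_periods + 1)
    if n_periods < skip_periods + 1:
        raise ValueError("need at least skip_periods + 1 periods")

    intervals = wake_intervals(t, gap) if t.size else []
    W_d, W_n = [], []
    for n in range(skip_periods, n_periods):
        lo, split, hi = n * T, (n + f_w) * T, (n + 1) * T
        W_d.append(wake_time_in_window(intervals, lo, split))
        W_n.append(wake_time_in_window(intervals, split, hi))
    W_d = np.asarray(W_d)
    W_n = np.asarray(W_n)
    Q = float(W_d.mean() / (f_w * T) - W_n.mean() / ((1.0 - f_w) * T))
    return QReport(W_day=W_d, W_night=W_n, wake_fraction=f_w, period=T,
                   n_periods=len(W_d), Q=Q)


def classify_periodicity(day_wake_times, T: float,
                         f_w: float = DEFAULT_WAKE_FRACTION) -> str:
    """Label a sequence of per-period day-wake times.

    A period counts as a "wake day" when its day-wake time reaches a quarter
    of the day window.  ``"period1"``: every period is a wake day;
    ``"period2"``: wake days strictly alternate (a prolonged wake episode only
    every other day); anything else is ``"irregular"``.
    """
    W = np.asarray(day_wake_times, dtype=float)
    if W.size < 6:
        raise ValueError("periodicity classification needs at least 6 periods")
    wake_day = W >= 0.25 * f_w * T
    if wake_day.all():
        return "period1"
    alternating = np.all(wake_day[1:] != wake_day[:-1])
    if alternating:
        return "period2"
    return "irregular"


def day_windows(n_periods: int, T: float,
                f_w: float = DEFAULT_WAKE_FRACTION) -> list[tuple[float, float]]:
    """Convenience: the day window of each of ``n_periods`` periods."""
    return [(n * T, (n + f_w) * T) for n in range(n_periods)]


def synthetic_spike_train(windows, isi: float, jitter: float = 0.0,
                          seed: int | None = 0) -> np.ndarray:
    """Tonic-firing fixture: spikes at ``isi`` spacing inside each window.

    ``windows`` is a sequence of non-overlapping ``(start, end)`` intervals in
    ms.  Successive inter-spike intervals are ``isi ± U(−jitter, jitter)``;
    the train is reproducible for a fixed seed.  Used to exercise the quality
    metric independently of the simulator.
    """
    if isi <= 0:
        raise ValueError("isi must be > 0")
    if jitter < 0 or jitter >= isi:
        raise ValueError("jitter must satisfy 0 <= jitter < isi")
    wins = sorted((float(a), float(b)) for a, b in windows)
    for (a1, b1), (a2, _) in zip(wins[:-1], wins[1:]):
        if a2 < b1:
            raise ValueError(f"overlapping wake windows: [{a1}, {b1}) and "
                             f"[{a2}, ...)")
    rng = np.random.default_rng(seed)
    spikes: list[float] = []
    for a, b in wins:
        t = a
        while t < b:
            spikes.append(t)
            step = isi + (rng.uniform(-jitter, jitter) if jitter > 0 else 0.0)
            t += step
    return np.asarray(spikes)
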