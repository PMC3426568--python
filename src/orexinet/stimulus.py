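"""Circadian drive: a periodic train of rectangular current pulses.

The circadian input is idealised as a depolarising current pulse of height
``delta_I`` and length ``delta_T`` delivered at the start of every daily
period — an "alarm clock" arriving once per (rescaled) day, acting identically
on every orexin neuron.  The interface admits named alternative waveforms, but
only the rectangular train is implemented.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = ["StimulusSpec", "pulse_current"]

_WAVEFORMS = {"rectangular"}


@dataclass(frozen=True)
class StimulusSpec:
    """Periodic rectangular pulse train.

    ``delta_I``: pulse height (µA/cm², positive = depolarising);
    ``delta_T``: pulse length (ms); ``period``: daily period (ms).
    Pulses occupy the half-open windows ``[k·period, k·period + delta_T)``.
    """

    delta_I: float = 1.0
    delta_T: float = 1000.0
    period: float = 24000.0
    enabled: bool = True
    waveform: str = "rectangular"

    def __post_init__(self) -> None:
        if self.waveform not in _WAVEFORMS:
            raise NotImplementedError(
                f"waveform {self.waveform!r} not available; "
                f"implemented: {sorted(_WAVEFORMS)}")
        if not (0 < self.delta_T < self.period):
            raise ValueError("pulse length must satisfy 0 < delta_T < period")
        if self.delta_I < 0:
            raise ValueError("pulse height delta_I must be >= 0")

    def with_height(self, delta_I: float) -> "StimulusSpec":
        return replace(self, delta_I=delta_I)


def pulse_current(t, spec: StimulusSpec):
    """External current at time ``t`` (ms); scalar or array.

    Returns ``delta_I`` inside the pulse window of each period and 0 outside;
    exactly periodic: the value depends on ``t`` only through ``t mod period``.
    """
    if not spec.enabled or spec.delta_I == 0.0:
        return np.zeros_like(np.asarray(t, dtype=float)) if np.ndim(t) else 0.0
    phase = np.mod(t, spec.period)
    out = np.where(phase < spec.delta_T, spec.delta_I, 0.0)
    return float(out) if np.ndim(out) == 0 else out
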