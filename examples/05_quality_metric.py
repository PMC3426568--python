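"""The sleep-wake quality coefficient Q on synthetic spike trains.

Q = <W_day>/(f_w T) - <W_night>/((1-f_w) T) scores a spike train on [-1, 1]:
+1 for tonic firing through every 16-h day and silence every night, 0 for no
activity at all, -1 for the anti-phase cycle.  Synthetic trains make the
metric testable without the simulator.
"""

import numpy as np

from orexinet import quality_coefficient, synthetic_spike_train, day_windows

T, F_W, GAP = 24000.0, 2.0 / 3.0, 250.0

days = [(a, b - GAP) for a, b in day_windows(6, T, F_W)]
optimal = synthetic_spike_train(days, isi=20.0)
print(f"optimal day/night train:  Q = "
      f"{quality_coefficient(optimal, T, n_periods=6).Q:+.3f}")

print(f"no spikes at all:         Q = "
      f"{quality_coefficient([], T, n_periods=6).Q:+.3f}")

nights = [(n * T + F_W * T, (n + 1) * T - GAP) for n in range(6)]
antiphase = synthetic_spike_train(nights, isi=20.0)
print(f"anti-phase (night) train: Q = "
      f"{quality_coefficient(antiphase, T, n_periods=6).Q:+.3f}")

night_spikes = np.array([(n + F_W) * T + 4000.0 for n in range(6)])
disturbed = np.sort(np.concatenate([optimal, night_spikes]))
q = quality_coefficient(disturbed, T, n_periods=6).Q
print(f"one isolated night spike per period: Q = {q:+.3f} "
      f"(each awakening costs gap/((1-f_w)T) = {GAP / ((1 - F_W) * T):.4f})")
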