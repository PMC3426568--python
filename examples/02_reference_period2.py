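"""The marginal period-2 reference state every disorder experiment starts from.

Bisects the critical circadian pulse height (ignition from the fully
recovered orexin availability), then sets the pulse just above it: day one
ignites a prolonged wake episode, the partially recovered next morning cannot,
and the prolonged wake recurs only every other day.
"""

import numpy as np

from orexinet import ModelParams, classify_periodicity
from orexinet.experiments import (default_config, find_pulse_threshold,
                                  make_reference_config, simulate_and_score)

params = ModelParams(theta_dep=1590.0)
network = default_config(N=20, params=params)

I_c = find_pulse_threshold(network)
print(f"critical pulse height (day-1 ignition): {I_c:.4f} µA/cm²")

reference = make_reference_config(network)
print(f"reference pulse height: {reference.stimulus.delta_I:.4f} µA/cm² "
      f"({reference.stimulus.delta_I / I_c:.4f} x critical)")

_, report = simulate_and_score(reference, n_periods=10, skip_periods=1)
print("per-period day-wake times (s):", np.round(report.W_day / 1000.0, 1))
print("classification:", classify_periodicity(report.W_day, 24000.0))
print(f"Q = {report.Q:.3f} — the non-optimal cycle that noise or diversity "
      f"can repair")
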