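"""Diversity at the A→B synapses reduces exactly to a two-neuron model.

When only the thresholds of the A→B glutamate synapses (located at neuron B)
are diversified, all orexin neurons follow the same trajectory and neuron B
sees their averaged drive — a single effective synapse whose activation curve
is the diversity-averaged sigmoid with a reduced effective steepness.
"""

import numpy as np

from orexinet import (DiversitySpec, ModelParams, NetworkConfig, StimulusSpec,
                      effective_two_neuron_config, fit_effective_slope,
                      run_simulation)

params = ModelParams(theta_dep=1590.0)
full = NetworkConfig(N=20, params=params,
                     stimulus=StimulusSpec(delta_I=1.1736, period=params.T_day),
                     diversity=DiversitySpec(site="AB", width=3.0, seed=7))
reduced = effective_two_neuron_config(full)

a = run_simulation(full, duration=2 * params.T_day, dt=0.1, record_traces=True)
b = run_simulation(reduced, duration=2 * params.T_day, dt=0.1, record_traces=True)
gap = np.max(np.abs(a.traces["V_B"] - b.traces["V_B"]))
print(f"max |V_B(full 21-neuron model) - V_B(two-neuron reduction)| = {gap:.2e} mV")
print("the reduction is exact: the averaged synaptic activations obey the "
      "same linear relaxation as each synapse individually")

print("\neffective steepness of the averaged synaptic activation "
      "(bare slope 0.25 /mV):")
for w in (0.0, 2.0, 4.0, 8.0, 16.0):
    print(f"  width {w:4.1f} mV -> s_eff = {fit_effective_slope(w, 0.25):.4f} /mV")
print("diversity flattens the population's activation curve — the mechanism "
      "that lets part of the population respond early")
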