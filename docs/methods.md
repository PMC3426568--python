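# Methods

## The model

Two neuron classes share one membrane template — a conductance-based excitable
unit with an instantaneous sodium current, a relaxing potassium current and a
leak:

```
C dV/dt  = −I_L − I_Na − I_K − I_syn + I_ext(t) + ξ(t)
I_L      = g_L (V − V_L)
I_Na     = g_Na σ(s_Na (V − V_h,Na)) (V − V_Na)
I_K      = g_K a_K (V − V_K),   τ_K da_K/dt = σ(s_K (V − V_h,K)) − a_K
```

with σ(x) = 1/(1+e^(−x)). Without input the unit rests near −60 mV; above
≈1.2 µA/cm² of depolarising current it fires tonically (single spikes at
30–70 Hz in model time). This is the regime the sleep-wake machinery needs:
silence ↔ sleep, tonic firing ↔ wake.

The network couples N orexin neurons A₁…A_N and one glutamate interneuron B:

- **B → A** (glutamate): each A_i carries a synapse with activation
  `τ_gl da_i/dt = σ(s_gl (V_B − θ_i^{BA})) − a_i` and current
  `g_gl a_i (V_{A,i} − V_gl)`.
- **A → B** (glutamate): the mirror synapses live at B; B receives the
  *population mean* `g_gl · mean_i(a_i^{AB}) · (V_B − V_gl)`.
- **A → B** (orexin): activations
  `τ_ox da_{ox,i}/dt = H(g_i) σ(s_ox (V_{A,i} − θ_ox)) − a_{ox,i}`, B receives
  their mean. `H(g) = σ(k (g − g_crit))` is a smooth availability gate: the
  orexin synapse only works while enough orexin is available.
- **A ↔ A**: all-to-all gap junctions, `g_gap Σ_j (V_{A,i} − V_{A,j})`,
  strong enough to keep the homogeneous population in pace.
- **Availability** (one homeostat per orexin neuron):
  `dg_i/dt = (1 − g_i)/θ_rec − σ(s_ox (V_{A,i} − θ_ox)) g_i/θ_dep`.
- **Circadian input**: a rectangular pulse of height ΔI and length ΔT at the
  start of each period T, applied to every A neuron.
- **Noise**: additive white Gaussian currents on the membrane equations with
  ⟨ξ(t)ξ(t′)⟩ = 2D δ(t−t′) (the factor-2 convention; an Ornstein-Uhlenbeck
  test in the suite pins the stationary variance to D·τ under it).

A wake episode works as a loop: the pulse fires the A population; A's
glutamate plus orexin drive fires B; B's glutamate back-excitation keeps A
firing after the pulse ends. The glutamate loop alone is deliberately below
self-sustaining strength, so the wake state *requires* the orexin current:
when availability has depleted to the gate's shoulder, B's drive sags, the
loop unlatches, and both populations fall silent. Overnight, availability
recovers and the next pulse can ignite again.

## Time rescaling

Simulations run on a rescaled clock: the daily period is T = 24 000 ms
("24 s for 24 h"), and only the slow orexin constants (τ_ox, θ_dep, θ_rec)
carry the rescaling; the fast ionic and synaptic time constants keep
physiological values. This preserves the scale separation (fast spiking ≪
synaptic ≪ homeostatic ≈ daily) that the mechanism relies on.
`ModelParams.rescaled(T)` produces further-rescaled parameter sets with the
same logic.

## Parameters

Units: mV, ms, mS/cm², µA/cm², µF/cm². All defaults live in `ModelParams`.

| group | values | why |
|---|---|---|
| membrane | C=1; g_L=0.1, V_L=−60; g_Na=1.5, V_Na=50; g_K=2.0, V_K=−90; s_Na=s_K=0.25, V_h=−25; τ_K=2 | silent rest near −60 mV, tonic firing above ≈1.2 µA/cm², spike peaks ≈+4 mV |
| glutamate | g_gl=0.10, V_gl=50, s_gl=0.25, θ̄=−30, τ_gl=10 | below the ≈0.17 boundary at which the reciprocal glutamate loop would self-sustain without orexin — wake must be orexin-limited |
| orexin | g_ox=0.35, V_ox=50, s_ox=0.25, θ_ox=−30, τ_ox=500 | carries the latch; sized so the loop unlatches when the gate has dropped to ≈½ |
| gate | g_crit=0.7, k=10 | places the gate's sensitive range inside the availabilities actually visited (≈0.7–1.0), so the homeostat modulates both wake termination *and* morning ignition; a Heaviside step is the k→∞ limit |
| homeostat | θ_dep=1600 (calibration lands ≈1590), θ_rec=7300 | see calibration below |
| coupling | g_gap=0.1 | homogeneous population responds in pace |
| stimulus | ΔT=1000, T=24 000 | short "alarm clock" pulse at the start of each day |
| metric | f_w=2/3, gap=250, spike threshold 0 mV, refractory 2 ms, skip 1 period | 16-h day of a 24-h cycle; see metric below |

## Calibration protocol

`find_pulse_threshold` bisects the pulse height at which the *first* day
(fully recovered availability, g=1) ignites a sustained wake episode
(day-wake ≥ half the day window); with the defaults the critical height is
≈1.118 µA/cm².

`calibrate_orexin_timescales` then tunes θ_dep by bisection at supra-threshold
drive (1.05× critical) until the mean wake time per period equals
f_w·T = 16 s. Wake duration is monotone in θ_dep in the depletion-limited
regime (slower depletion → longer wake); the calibration operates inside that
regime — above it (θ_dep ≳ 1650 at the defaults) the cycle period-doubles
into an overlong-wake alternation, which the post-calibration period-1 check
guards against. If the calibrated cycle were not single-periodic the recovery
constant θ_rec is *reduced* (faster overnight recovery stabilises the daily
fixed point).

## The period-2 reference state

All four disorder experiments start from a marginal, double-periodic cycle.
Because the bisected critical height is measured on day one — the system's
most excitable morning — a pulse *below* it ignites nothing on any day.
The double-periodic band instead sits marginally **above** the critical
height: day one ignites and depletes orexin; after one night of partial
recovery the same pulse cannot re-ignite; after a further silent day it can.
`make_reference_config` therefore sets the pulse to ≈1.005× the critical
height (scanning 1.002–1.012 and verifying period-2 by simulation). With the
defaults the band is ≈[1.000, 1.008]× and 1.05× is safely single-periodic.
The reference cycle has Q ≈ 0.25 against Q ≈ 0.93 for the healthy cycle.

## Quality metric

The wake state is identified with spiking: each spike extends wakefulness by
at most `gap` = 250 ms or until the next spike. Tonic firing (inter-spike
intervals ≈ 15–30 ms) therefore yields contiguous wake, while an isolated
spike contributes a 250-ms awakening. Q is the mean day-wake fraction minus
the mean night-wake fraction; the normalisation puts the optimal cycle at +1,
total silence at 0 and the anti-phase cycle at −1. Penalties: an isolated
night spike costs gap/((1−f_w)T) ≈ 0.031; a skipped wake day costs a full
day-wake share. The interval rule is cross-checked in the suite against a
brute-force 1-ms occupancy grid. The canonical metric fixtures end their
spiking one `gap` before the day/night boundary so the wake tail closes with
the window.

Periodicity labels: a period is a "wake day" if its day-wake time reaches a
quarter of the day window; all wake days → period1, strict alternation →
period2, anything else → irregular.

## Quenched diversity

Thresholds are drawn once per realisation from the logistic bell
p(θ) = e^(−(θ−θ̄)/w) / (w(1+e^(−(θ−θ̄)/w))²) with standard deviation
(π/√3)·w; the width w is the sweep variable. This density's CDF is itself a
sigmoid, so the population-averaged synaptic activation keeps the form of a
single synapse with a reduced effective steepness — exactly σ with the bare
slope as w→0 and exactly the threshold CDF (slope 1/w in the standardised
variable) as w→∞, with a monotone interpolation in between
(`fit_effective_slope`). The averaged-activation integral is evaluated by
adaptive quadrature in the standardised variable u = (θ−θ̄)/w, which is
well-conditioned for any width.

When only the A→B thresholds are diversified the network reduces *exactly* to
a two-neuron model in which B is driven by the finite mixture
(1/N)Σσ(s(V_A−θᵢ)): each activation ODE is linear with the common τ_gl.
`effective_two_neuron_config` constructs that reduction, and the integrator
computes population means as base-plus-deviations so the reduction (and the
homogeneous permutation symmetry, and the N-independence of noise-on-B runs)
hold to the last bit, not merely to tolerance.

## Integration

Stochastic Heun (deterministic order 2; the same Wiener increment in
predictor and corrector, as required for additive noise), default dt = 0.1 ms
(20 steps per τ_K). Availabilities are clamped to [0,1] after each step as a
safety net (inactive in practice). A numba-compiled chunked kernel is the
production path; a step-by-step NumPy path implements the identical update
and the suite pins the two to ≤1e−9 over noisy trajectories. Noise streams
for the A population and for B are independent children of the master seed,
so B's stream does not depend on N. Spikes are detected online as upward
0-mV crossings (linear interpolation, 2-ms refractory). Runs abort with a
diagnostic if |V| exceeds 500 mV.

## Experiment design and problem sizes

The study network is N = 20 orexin neurons + 1 glutamate neuron. Sweeps run
10 scored periods after one discarded transient period, with 3 independent
seeds per value (quenched threshold draws for the diversity kinds, noise
streams for the noise kinds); default grids are 8 log-spaced noise
intensities per site and 8 linear widths 0–7 mV. Calibration and threshold
bisection exploit the exact N-independence of homogeneous noiseless dynamics
and run the two-neuron system. At dt = 0.1 ms a 10-period N=20 run takes a
few seconds on one CPU core, so the full acceptance protocol (calibration +
sweeps) completes in minutes.

## What the synthetic spike trains do and do not show

`synthetic_spike_train` emits tonically spaced (optionally jittered) spikes
inside prescribed wake windows. It emulates exactly the feature the quality
metric reads — spiking versus silence in day and night windows — and nothing
else: no membrane dynamics, no realistic inter-spike-interval statistics, no
graded episode onsets/offsets. Metric tests on these fixtures validate the
scoring rule, not the biology; the simulator-level tests and experiments
carry the dynamical claims.

## Known limitations

- All numeric parameter values are the package's own calibrated set for the
  stated qualitative regimes; other values satisfying the same constraints
  would shift quantitative results (e.g. the location of the diversity
  optimum) without changing the phenomena.
- The period-2 reference is deliberately marginal (≈0.5 % above ignition
  threshold), so even very small noise on B repairs the cycle; the stochastic
  "resonance" appears as a broad plateau with a steep low-noise flank rather
  than a gradual rise.
- Single generic non-REM sleep state; one orexin transmitter type; complete
  gap-junction topology; diversity only in glutamate-synapse thresholds;
  noise and diversity are studied separately, not combined.
- The rectangular pulse is the only implemented circadian waveform (the
  stimulus interface accepts named alternatives).
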