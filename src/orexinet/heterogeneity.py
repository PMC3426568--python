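"""Quenched synaptic diversity: threshold sampling and effective reductions.

Diversity enters the network as per-synapse half-activation thresholds of the
glutamatergic currents, drawn once ("quenched") from a bell-shaped density
centred on the homogeneous value.  We use the logistic density

    p(θ) = e^{−(θ−θ̄)/w} / ( w (1 + e^{−(θ−θ̄)/w})² ),

whose standard deviation is σ = (π/√3)·w.  Its CDF is itself a sigmoid, so
the population-averaged synaptic activation keeps the same analytical form as
a single synapse with a reduced effective steepness — exactly in the
small-width and large-width limits, and to good approximation in between.
The width ``w`` (not σ) is the sweep variable used as the measure of
diversity.

When only the A→B synapses are diversified, all A neurons remain identical
(their own equations are untouched), so the full N+1 network reduces exactly
to a two-neuron model in which neuron B is driven by the finite mixture
(1/N)·Σ_i σ(s(V_A − θ_i)); :func:`effective_two_neuron_config` builds that
reduced configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

import numpy as np
from scipy import integrate, optimize, stats
from scipy.special import expit

__all__ = [
    "DiversitySpec",
    "threshold_density",
    "threshold_cdf",
    "sample_thresholds",
    "effective_equilibrium",
    "fit_effective_slope",
    "effective_two_neuron_config",
    "build_threshold_vectors",
]

WIDTH_TO_STD = np.pi / np.sqrt(3.0)


@dataclass(frozen=True)
class DiversitySpec:
    """Where quenched disorder lives and how wide it is.

    ``site``: which glutamate synapse family carries diversified thresholds —
    ``"none"`` (homogeneous), ``"BA"`` (B→A synapses, at the A neurons) or
    ``"AB"`` (A→B synapses, at neuron B).  ``mean`` of ``None`` means "use the
    homogeneous threshold of the model parameters".  ``width`` is the logistic
    dispersion parameter w (mV); ``seed`` makes the quenched draw reproducible.
    """

    site: Literal["none", "BA", "AB"] = "none"
    mean: float | None = None
    width: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.site not in ("none", "BA", "AB"):
            raise ValueError(f"unknown diversity site {self.site!r}")
        if self.width < 0:
            raise ValueError("diversity width must be >= 0")
        if self.site == "none" and self.width != 0:
            raise ValueError("site='none' requires width 0")


def threshold_density(theta, mean: float, width: float):
    """Bell-shaped probability density of the synaptic thresholds (1/mV).

    Symmetric about ``mean``, unimodal, unit mass; standard deviation
    ``(π/√3)·width``.
    """
    if width <= 0:
        raise ValueError("threshold_density requires width > 0; "
                         "width 0 is a point mass handled by the sampler")
    out = stats.logistic.pdf(np.asarray(theta, float), loc=mean, scale=width)
    return float(out) if np.ndim(out) == 0 else out


def threshold_cdf(theta, mean: float, width: float):
    """Cumulative distribution of the threshold density (a sigmoid in θ)."""
    if width <= 0:
        raise ValueError("threshold_cdf requires width > 0")
    out = stats.logistic.cdf(np.asarray(theta, float), loc=mean, scale=width)
    return float(out) if np.ndim(out) == 0 else out


def sample_thresholds(N: int, mean: float, width: float, seed) -> np.ndarray:
    """Draw ``N`` i.i.d. thresholds from the bell density (quenched draw).

    ``width = 0`` returns ``N`` copies of ``mean``.  The same seed always
    reproduces the same vector.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    if width < 0:
        raise ValueError("width must be >= 0")
    if width == 0:
        return np.full(N, float(mean))
    rng = np.random.default_rng(seed)
    return rng.logistic(loc=mean, scale=width, size=N)


def effective_equilibrium(V, mean: float, width: float, slope: float):
    """Population-averaged synaptic equilibrium ∫ p(θ) σ(slope·(V−θ)) dθ.

    The equilibrium activation a diversified synapse bank presents to neuron B
    when every presynaptic neuron sits at voltage ``V``.  Monotone increasing
    in ``V``, in [0, 1], and equal to 1/2 at ``V = mean`` for every width.
    ``width = 0`` returns the plain sigmoid.
    """
    if width < 0:
        raise ValueError("width must be >= 0")
    if slope <= 0:
        raise ValueError("slope must be > 0")
    Varr = np.atleast_1d(np.asarray(V, dtype=float))
    if width == 0.0:
        out = expit(slope * (Varr - mean))
        return float(out[0]) if np.ndim(V) == 0 else out

    # substitute u = (θ - mean)/width: the density becomes the standard
    # logistic, well-conditioned for any width (including widths far below
    # the sigmoid scale 1/slope)
    half = 40.0  # the standardised density is negligible beyond ±40
    out = np.empty_like(Varr)
    for k, v in enumerate(Varr):
        u_star = (v - mean) / width  # location of the sigmoid transition
        pts = [0.0, u_star] if abs(u_star) < half else [0.0]
        val, err = integrate.quad(
            lambda u: stats.logistic.pdf(u) * expit(slope * (v - mean - width * u)),
            -half, half, epsabs=1e-10, epsrel=1e-10, limit=400, points=pts)
        if not np.isfinite(val) or err > 1e-6:
            raise RuntimeError(
                f"effective-equilibrium quadrature did not converge at V={v}")
        out[k] = min(max(val, 0.0), 1.0)
    return float(out[0]) if np.ndim(V) == 0 else out


def fit_effective_slope(width: float, slope: float, mean: float = 0.0) -> float:
    """Least-squares effective steepness of the averaged synaptic sigmoid.

    Fits a single sigmoid ``σ(s_eff (V − mean))`` to the population-averaged
    equilibrium over ``V ∈ mean ± (20 + 5·width)`` mV and returns the fitted
    steepness.  Decreases monotonically with the diversity width: for w → 0 it
    equals ``slope``; for w ≫ 1/slope it approaches ``1/w`` (the CDF limit).
    """
    if width < 0:
        raise ValueError("width must be >= 0")
    if width == 0:
        return float(slope)
    half = 20.0 + 5.0 * width
    V = np.linspace(mean - half, mean + half, 201)
    target = effective_equilibrium(V, mean, width, slope)

    def model(v, s_eff):
        return expit(s_eff * (v - mean))

    try:
        popt, _ = optimize.curve_fit(model, V, target, p0=[slope],
                                     bounds=(1e-8, np.inf), maxfev=10000)
    except RuntimeError as exc:  # pragma: no cover - curve_fit failure
        raise RuntimeError(f"effective-slope fit failed: {exc}") from exc
    return float(popt[0])


def build_threshold_vectors(N: int, theta_mean: float, spec: DiversitySpec):
    """Materialise (thresholds_BA, thresholds_AB) for a network of size N.

    The family named by ``spec.site`` gets a quenched draw from the bell
    density; the other family stays homogeneous at ``theta_mean``.
    """
    mean = theta_mean if spec.mean is None else spec.mean
    homog = np.full(N, float(mean))
    if spec.site == "none" or spec.width == 0:
        return homog.copy(), homog.copy()
    drawn = sample_thresholds(N, mean, spec.width, spec.seed)
    if spec.site == "BA":
        return drawn, homog.copy()
    return homog.copy(), drawn


def effective_two_neuron_config(config):
    """Exact two-neuron reduction for diversity at the A→B synapses.

    Requires diversity only at the A→B site, zero noise on the A neurons and
    homogeneous B→A thresholds: then every A neuron follows the same
    trajectory, and neuron B sees the finite mixture
    (1/N)·Σ_i σ(s_gl (V_A − θ_i)).  The returned configuration keeps a single
    A neuron but the full bank of A→B synaptic thresholds, all driven by that
    neuron (``ab_source = 0``), which reproduces the mixture exactly because
    each activation ODE is linear with the common time constant τ_gl.
    """
    from .model import NetworkConfig

    if np.ptp(config.thresholds_BA) != 0:
        raise ValueError("reduction requires homogeneous B→A thresholds")
    if config.noise.D_A != 0:
        raise ValueError("reduction requires zero noise on the A neurons")
    if config.diversity.site == "BA" and config.diversity.width != 0:
        raise ValueError("reduction is only valid for diversity at the A→B site")
    return NetworkConfig(
        N=1,
        params=config.params,
        stimulus=config.stimulus,
        noise=config.noise,
        diversity=replace(config.diversity, site="none", width=0.0),
        thresholds_BA=config.thresholds_BA[:1].copy(),
        thresholds_AB=config.thresholds_AB.copy(),
        ab_source=np.zeros(config.thresholds_AB.size, dtype=np.int64),
    )
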