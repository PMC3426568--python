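"""Run-configuration loading/validation and tabular output writers.

Configurations are human-editable YAML with the sections ``network``,
``stimulus``, ``noise``, ``diversity``, ``integration``, ``metric`` and
``output``; every omitted field takes the documented default, unknown keys
are rejected, and all invariant violations are reported together.  A JSON
echo of the fully resolved configuration is written next to every output set
so a run can be replayed exactly.
"""

from __future__ import annotations

import dataclasses
import json
import platform
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .heterogeneity import DiversitySpec
from .integrator import NoiseSpec, SpikeRecord
from .metrics import DEFAULT_GAP, DEFAULT_WAKE_FRACTION, QReport
from .model import ModelParams, NetworkConfig
from .stimulus import StimulusSpec

__all__ = ["RunConfig", "load_config", "write_outputs"]

_SECTIONS = ("network", "stimulus", "noise", "diversity", "integration",
             "metric", "output")


@dataclass
class RunConfig:
    """Fully resolved configuration of one simulation run."""

    network: NetworkConfig
    dt: float = 0.1
    n_periods: int = 10
    seed: int = 0
    f_w: float = DEFAULT_WAKE_FRACTION
    gap: float = DEFAULT_GAP
    skip_periods: int = 1
    outdir: str = "results"

    @property
    def duration(self) -> float:
        return self.n_periods * self.network.stimulus.period

    def to_dict(self) -> dict:
        net = self.network
        return {
            "network": {"N": int(net.N),
                        "params": dataclasses.asdict(net.params)},
            "stimulus": dataclasses.asdict(net.stimulus),
            "noise": dataclasses.asdict(net.noise),
            "diversity": dataclasses.asdict(net.diversity),
            "integration": {"dt": self.dt, "n_periods": self.n_periods,
                            "seed": self.seed},
            "metric": {"f_w": self.f_w, "gap": self.gap,
                       "skip_periods": self.skip_periods},
            "output": {"dir": self.outdir},
        }


def _take(section: dict, name: str, errors: list, known: dict) -> dict:
    got = section.get(name) or {}
    if not isinstance(got, dict):
        errors.append(f"section {name!r} must be a mapping")
        return {}
    unknown = set(got) - set(known)
    for k in sorted(unknown):
        errors.append(f"unknown key {name}.{k}")
    return {k: v for k, v in got.items() if k in known}


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration.

    An empty file yields the complete default configuration (N=20,
    T_day=24 000 ms, f_w=2/3).  Raises ``ValueError`` listing *every*
    offending field on unknown keys or invariant violations.
    """
    text = Path(path).read_text()
    raw = yaml.safe_load(text)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError("configuration root must be a mapping")
    errors: list[str] = []
    for k in sorted(set(raw) - set(_SECTIONS)):
        errors.append(f"unknown section {k!r}")

    param_fields = {f.name: f for f in dataclasses.fields(ModelParams)}
    net_sec = _take(raw, "network", errors, {"N": None, "params": None})
    params_raw = net_sec.get("params") or {}
    if not isinstance(params_raw, dict):
        errors.append("network.params must be a mapping")
        params_raw = {}
    for k in sorted(set(params_raw) - set(param_fields)):
        errors.append(f"unknown key network.params.{k}")
    params_kw = {k: v for k, v in params_raw.items() if k in param_fields}

    try:
        params = ModelParams(**params_kw)
    except (ValueError, TypeError) as exc:
        errors.append(str(exc))
        params = None

    stim_kw = _take(raw, "stimulus", errors,
                    {"delta_I": None, "delta_T": None, "period": None,
                     "enabled": None, "waveform": None})
    noise_kw = _take(raw, "noise", errors, {"D_A": None, "D_B": None, "seed": None})
    div_kw = _take(raw, "diversity", errors,
                   {"site": None, "mean": None, "width": None, "seed": None})
    integ = _take(raw, "integration", errors,
                  {"dt": None, "n_periods": None, "seed": None})
    metric = _take(raw, "metric", errors,
                   {"f_w": None, "gap": None, "skip_periods": None})
    out = _take(raw, "output", errors, {"dir": None})

    network = None
    if params is not None:
        stim_kw.setdefault("period", params.T_day)
        try:
            stimulus = StimulusSpec(**stim_kw)
            noise = NoiseSpec(**noise_kw)
            diversity = DiversitySpec(**div_kw)
            network = NetworkConfig(N=int(net_sec.get("N", 20)), params=params,
                                    stimulus=stimulus, noise=noise,
                                    diversity=diversity)
        except (ValueError, TypeError, NotImplementedError) as exc:
            errors.append(str(exc))

    dt = float(integ.get("dt", 0.1))
    n_periods = int(integ.get("n_periods", 10))
    f_w = float(metric.get("f_w", DEFAULT_WAKE_FRACTION))
    if dt <= 0:
        errors.append("integration.dt must be > 0")
    if n_periods < 1:
        errors.append("integration.n_periods must be >= 1")
    if not 0 < f_w < 1:
        errors.append("metric.f_w must lie in (0, 1)")
    if errors:
        raise ValueError("invalid configuration:\n  - " + "\n  - ".join(errors))

    return RunConfig(
        network=network, dt=dt, n_periods=n_periods,
        seed=int(integ.get("seed", 0)),
        f_w=f_w, gap=float(metric.get("gap", DEFAULT_GAP)),
        skip_periods=int(metric.get("skip_periods", 1)),
        outdir=str(out.get("dir", "results")),
    )


def write_outputs(record: SpikeRecord, report: QReport | None, outdir,
                  plot: bool = False) -> dict:
    """Write the standard output file set of one run.

    ``spikes.csv`` (neuron_id, t_ms), ``qreport.csv`` (per-period wake times)
    with a one-row ``qsummary.csv`` (Q, f_w, T, M), a JSON configuration echo
    and a run log with the master seed.  With ``plot=True`` a raster and a
    trace figure are also produced (requires matplotlib; figures are for
    inspection only).  Returns the mapping of logical names to paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    spikes = record.to_frame()
    paths["spikes"] = outdir / "spikes.csv"
    spikes.to_csv(paths["spikes"], index=False)

    if report is not None:
        import pandas as pd
        paths["qreport"] = outdir / "qreport.csv"
        report.to_frame().to_csv(paths["qreport"], index=False)
        paths["qsummary"] = outdir / "qsummary.csv"
        pd.DataFrame([{"Q": report.Q, "f_w": report.wake_fraction,
                       "T_ms": report.period,
                       "n_periods": report.n_periods}]).to_csv(
            paths["qsummary"], index=False)

    paths["config"] = outdir / "config_echo.json"
    paths["config"].write_text(json.dumps(record.config_echo, indent=2))

    from . import __version__
    paths["log"] = outdir / "run_log.txt"
    paths["log"].write_text(
        f"orexinet {__version__} (python {platform.python_version()}, "
        f"numpy {np.__version__})\n"
        f"seed: {record.config_echo.get('seed')}\n"
        f"duration_ms: {record.duration}\ndt_ms: {record.dt}\n"
        f"n_spikes: {record.n_spikes}\n")

    if plot:
        paths.update(_write_figures(record, outdir))
    return paths


def _write_figures(record: SpikeRecord, outdir: Path) -> dict:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    paths = {}
    fig, ax = plt.subplots(figsize=(9, 3))
    ids = sorted(record.spike_times, key=lambda k: (k != "B", k))
    for row, key in enumerate(ids):
        t = record.spike_times[key]
        ax.vlines(t / 1000.0, row + 0.1, row + 0.9, lw=0.4)
    ax.set_yticks(np.arange(len(ids)) + 0.5, ids)
    ax.set_xlabel("time (s, rescaled)")
    fig.tight_layout()
    paths["raster"] = outdir / "raster.png"
    fig.savefig(paths["raster"], dpi=120)
    plt.close(fig)

    if record.traces is not None:
        tr = record.traces
        fig, axes = plt.subplots(3, 1, sharex=True, figsize=(9, 5))
        axes[0].plot(tr["t"] / 1000.0, tr["V_B"], lw=0.4)
        axes[0].set_ylabel("V_B (mV)")
        axes[1].plot(tr["t"] / 1000.0, tr["a_ox_mean"], lw=0.8)
        axes[1].set_ylabel("mean a_ox")
        axes[2].plot(tr["t"] / 1000.0, tr["g_avail_mean"], lw=0.8)
        axes[2].set_ylabel("mean g avail")
        axes[2].set_xlabel("time (s, rescaled)")
        fig.tight_layout()
        paths["trace"] = outdir / "trace.png"
        fig.savefig(paths["trace"], dpi=120)
        plt.close(fig)
    return paths
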