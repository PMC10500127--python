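"""Config-driven simulation experiments.

Each named experiment regenerates one simulated scenario end to end —
point-process timing train, optional waveform convolution, optional
background noise, Welch spectrum, peak/slope diagnostics — from a YAML
config shipped with the package.  Experiments are seed-deterministic: the
default seed is derived from the experiment name, and every stochastic
component inside an experiment draws from an independently derived
sub-stream.

Scenario catalogue (see ``lfpshot/configs/``):

========  ==========================================================
name      scenario
========  ==========================================================
fig1a-d   40 Hz point processes: super-Poissonian, Poisson,
          sub-Poissonian, perfectly periodic (timing spectra)
fig2b-d   Poisson 40 Hz train convolved with alpha / spike-Morlet /
          spindle-Morlet waveforms
fig3a-c   RC-filtered background noise, 75 Hz Poisson spike train,
          and their sum
s1        increasingly regular gamma processes (a = 1 ... 1000) and
          the periodic limit
s2        compound mixture train and its three components
s3        periodic 40 Hz train convolved with the fig2 waveforms
s4        moderately regular train with Hann pulses of growing width
s5        quasi-periodic theta, theta-modulated gamma, and their sum
========  ==========================================================
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from . import io as _io
from .point_process import (
    EventTrain,
    GammaIntervalSpec,
    compound_train,
    events_to_pulse,
    interval_histogram,
    modulated_train,
    periodic_train,
    sample_gamma_train,
    train_statistics,
)
from .spectral import (
    PowerSpectrum,
    argmax_frequency,
    find_spectral_peaks,
    fit_loglog_slope,
    welch_psd,
)
from .synthesis import Signal, convolve_train, rc_background_noise, sum_signals
from .waveforms import (
    alpha_waveform,
    hann_waveform,
    morlet_waveform,
    rc_impulse,
)

__all__ = ["ExperimentResult", "run_experiment", "experiment_names", "default_seed"]


@dataclass
class ExperimentResult:
    """Outcome of one experiment run."""

    name: str
    seed: int
    summary: dict
    artifacts: list = field(default_factory=list)
    spectra: dict = field(default_factory=dict)
    trains: dict = field(default_factory=dict)


def experiment_names() -> list[str]:
    """Valid experiment identifiers, in catalogue order."""
    files = resources.files("lfpshot.configs")
    names = [p.name[:-5] for p in files.iterdir() if p.name.endswith(".yaml")]
    order = {"f": 0, "s": 1}
    return sorted(names, key=lambda n: (order.get(n[0], 2), n))


def default_seed(name: str) -> int:
    """Stable per-experiment seed derived from the name."""
    return zlib.crc32(name.encode()) & 0x7FFFFFFF


def _load_config(name: str) -> dict:
    path = resources.files("lfpshot.configs") / f"{name}.yaml"
    if not path.is_file():
        raise ValueError(
            f"unknown experiment {name!r}; valid names: {', '.join(experiment_names())}"
        )
    return yaml.safe_load(path.read_text())


def _sub_seed(*parts: int) -> int:
    return int(np.random.SeedSequence(list(parts)).generate_state(1)[0] % (2**31))


def _build_waveform(cfg: dict, fs: float):
    family = cfg["family"]
    if family == "alpha":
        return alpha_waveform(cfg["tau_s"], sampling_rate=fs)
    if family == "morlet":
        return morlet_waveform(
            cfg["sigma_s"], cfg.get("t0_s", 0.0), cfg["p_s"],
            cfg.get("mu_s", 0.0), sampling_rate=fs,
        )
    if family == "hann":
        return hann_waveform(
            cfg["p_s"], inverted=cfg.get("inverted", False),
            scale=cfg.get("scale", 1.0), sampling_rate=fs,
        )
    if family == "rc":
        return rc_impulse(cfg["tau_s"], sampling_rate=fs)
    raise ValueError(f"unknown waveform family {family!r}")


def _build_train(cfg: dict, duration: float, seed: int) -> EventTrain:
    kind = cfg["kind"]
    if kind == "gamma":
        return sample_gamma_train(
            GammaIntervalSpec(cfg["shape"], cfg["rate_hz"]), duration, seed
        )
    if kind == "periodic":
        return periodic_train(cfg["rate_hz"], duration, cfg.get("phase_offset_s", 0.0))
    if kind == "compound":
        comps = [GammaIntervalSpec(c["shape"], c["rate_hz"]) for c in cfg["components"]]
        return compound_train(comps, duration, seed, cfg.get("weights"))
    if kind == "modulated":
        mod_cfg = cfg["modulator"]
        modulator = sample_gamma_train(
            GammaIntervalSpec(mod_cfg["shape"], mod_cfg["rate_hz"]),
            duration,
            _sub_seed(seed, 1),
        )
        carrier = GammaIntervalSpec(cfg["carrier"]["shape"], cfg["carrier"]["rate_hz"])
        keep = tuple(cfg.get("keep_fraction_of_cycle", [0.0, 0.5]))
        return modulated_train(
            carrier, modulator, cfg["modulator_period_s"], keep,
            duration, _sub_seed(seed, 0),
        )
    raise ValueError(f"unknown process kind {kind!r}")


def _build_component(cfg: dict, duration: float, fs: float, seed: int):
    """Return (signal, train-or-None) for one scenario component."""
    kind = cfg["kind"]
    if kind == "rc_noise":
        sig = rc_background_noise(
            cfg.get("tau_s", 0.035), duration, fs, seed,
            amplitude=cfg.get("amplitude", 1.0),
        )
        return sig, None
    train = _build_train(cfg["process"], duration, seed)
    pulse = events_to_pulse(train, fs)
    if kind == "pulse":
        sig = Signal(pulse.values, fs, provenance=[dict(pulse.provenance)])
        return sig, train
    if kind == "shot":
        w = _build_waveform(cfg["waveform"], fs)
        return convolve_train(pulse, w), train
    raise ValueError(f"unknown component kind {kind!r}")


def _analyze(
    sig: Signal,
    train: EventTrain | None,
    analysis: dict,
) -> tuple[dict, PowerSpectrum]:
    ps = welch_psd(sig)
    f_hi = min(500.0, float(ps.frequencies[-1]))
    peak_range = tuple(analysis.get("peak_range_hz", (2.0 + 1e-9, f_hi)))
    peaks = find_spectral_peaks(
        ps, analysis.get("min_prominence_ratio", 1.5), peak_range
    )
    stats: dict = {
        "argmax_hz": argmax_frequency(ps, peak_range),
        "peaks_hz": [f for f, _ in peaks[:12]],
        "n_samples": sig.values.size,
    }
    if "slope_range_hz" in analysis:
        stats["slope_loglog"] = fit_loglog_slope(
            ps, tuple(analysis["slope_range_hz"])
        )
        stats["slope_range_hz"] = list(analysis["slope_range_hz"])
    if train is not None and train.n_events >= 2:
        ts = train_statistics(train, analysis.get("count_window_s", 1.0))
        stats.update(
            rate_hz=ts["rate_hz"],
            interval_cv=ts["interval_cv"],
            fano_factor=ts["fano_factor"],
            n_events=ts["n_events"],
        )
    return stats, ps


def run_experiment(
    name: str,
    overrides: dict | None = None,
    seed: int | None = None,
    outdir: str | Path | None = None,
) -> ExperimentResult:
    """Run one named experiment and return its summary.

    Parameters
    ----------
    name
        Experiment identifier (see :func:`experiment_names`).
    overrides
        Shallow config overrides, e.g. ``{"duration_s": 100.0}``.
    seed
        Base seed; defaults to a stable hash of the name.
    outdir
        If given, spectra (CSV), interval histograms (CSV), event times
        (text) and a manifest JSON are written there.
    """
    cfg = _load_config(name)
    if overrides:
        cfg = {**cfg, **overrides}
    if seed is None:
        seed = default_seed(name)
    duration = float(cfg.get("duration_s", 1000.0))
    fs = float(cfg.get("sampling_rate_hz", 1000.0))

    summary: dict = {}
    spectra: dict = {}
    trains: dict = {}
    artifacts: list = []
    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)

    for vi, variant in enumerate(cfg["variants"]):
        label = variant["label"]
        parts = []
        first_train: EventTrain | None = None
        for ci, comp in enumerate(variant["components"]):
            sig, train = _build_component(comp, duration, fs, _sub_seed(seed, vi, ci))
            parts.append(sig)
            if first_train is None and train is not None:
                first_train = train
        sig = parts[0] if len(parts) == 1 else sum_signals(parts)
        analysis = {**cfg.get("analysis", {}), **variant.get("analysis", {})}
        stats, ps = _analyze(sig, first_train, analysis)
        summary[label] = stats
        spectra[label] = ps
        if first_train is not None:
            trains[label] = first_train

        if outdir is not None:
            spec_path = outdir / f"{name}_{label}_spectrum.csv"
            _io.spectrum_to_csv(ps, spec_path)
            artifacts.append(str(spec_path))
            if first_train is not None and first_train.n_events >= 2:
                hist = interval_histogram(
                    first_train,
                    analysis.get("hist_bin_s", 0.002),
                    analysis.get("hist_max_s", 0.25),
                )
                hist_path = outdir / f"{name}_{label}_intervals.csv"
                np.savetxt(
                    hist_path,
                    np.column_stack([hist.bin_centers, hist.density]),
                    delimiter=",",
                    header="interval_s,density_per_s",
                    comments="",
                )
                artifacts.append(str(hist_path))
                ev_path = outdir / f"{name}_{label}_events.txt"
                _io.write_event_times(first_train, ev_path)
                artifacts.append(str(ev_path))

    if outdir is not None:
        manifest = {
            "name": name,
            "seed": seed,
            "duration_s": duration,
            "sampling_rate_hz": fs,
            "summary": summary,
            "artifacts": artifacts,
        }
        mpath = outdir / f"{name}_manifest.json"
        mpath.write_text(json.dumps(manifest, indent=2, default=float))
        artifacts.append(str(mpath))

    return ExperimentResult(name, seed, summary, artifacts, spectra, trains)
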