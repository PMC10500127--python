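"""Plain-text input/output: event timestamps, spectra and signals."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .point_process import EventTrain
from .spectral import PowerSpectrum, SurrogateBand
from .synthesis import Signal


def read_event_times(path: str | Path, duration: float | None = None) -> EventTrain:
    """Read an event train from text: one time in seconds per line.

    Blank lines and lines starting with ``#`` are ignored.  If ``duration``
    is not given it is taken as the last event time rounded up to the next
    whole second.
    """
    times = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        times.append(float(line))
    arr = np.sort(np.asarray(times, dtype=float))
    if duration is None:
        if arr.size == 0:
            raise ValueError(f"no event times found in {path}")
        duration = float(np.ceil(arr[-1] + 1e-9))
    arr = arr[arr < duration]
    return EventTrain(arr, duration, provenance={"source": str(path)})


def write_event_times(train: EventTrain, path: str | Path) -> None:
    """Write event times as plain text, one time in seconds per line."""
    lines = [f"# duration_s {train.duration:.9g}"]
    lines += [f"{t:.9f}" for t in train.times]
    Path(path).write_text("\n".join(lines) + "\n")


def spectrum_to_csv(
    s: PowerSpectrum, path: str | Path, band: SurrogateBand | None = None
) -> None:
    """Write a spectrum (and optional surrogate band) as CSV + JSON sidecar."""
    path = Path(path)
    cols = {"frequency_hz": s.frequencies, "power": s.power}
    if band is not None:
        cols["lower"] = band.lower
        cols["upper"] = band.upper
    pd.DataFrame(cols).to_csv(path, index=False)
    meta = {k: v for k, v in s.meta.items()}
    if band is not None:
        meta["surrogate_band"] = {
            "n_surrogates": band.n_surrogates,
            "alpha": band.alpha,
        }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(meta, indent=2, default=str)
    )


def read_spectrum_csv(path: str | Path) -> PowerSpectrum:
    """Read a spectrum written by :func:`spectrum_to_csv`."""
    path = Path(path)
    df = pd.read_csv(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return PowerSpectrum(df["frequency_hz"].to_numpy(), df["power"].to_numpy(), meta)


def save_signal(sig: Signal, path: str | Path, fmt: str = "text") -> None:
    """Write a signal as two-column text or raw float64 + JSON sidecar."""
    path = Path(path)
    if fmt == "text":
        t = np.arange(sig.values.size) / sig.sampling_rate
        np.savetxt(path, np.column_stack([t, sig.values]), fmt="%.9g",
                   header="time_s value")
    elif fmt == "binary":
        sig.values.astype("<f8").tofile(path)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    sidecar = {
        "sampling_rate_hz": sig.sampling_rate,
        "duration_s": sig.duration,
        "format": fmt,
        "provenance": sig.provenance,
    }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=2, default=str)
    )


def load_signal(path: str | Path) -> Signal:
    """Read a signal written by :func:`save_signal`."""
    path = Path(path)
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    if sidecar.get("format") == "binary":
        values = np.fromfile(path, dtype="<f8")
    else:
        values = np.loadtxt(path)[:, 1]
    return Signal(values, sidecar["sampling_rate_hz"])
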