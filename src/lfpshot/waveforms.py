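"""Single-event impulse-response waveforms and their spectra.

Four waveform families cover the neural events simulated by the package:

* ``alpha`` — the alpha synaptic response ``A(t) = H(t) * t * exp(-t/tau)``
  (causal; peaks at ``t = tau``);
* ``morlet`` — a real Gabor atom, a sinusoid under a Gaussian envelope,
  shaped as a spike or a spindle depending on its width;
* ``hann`` — a single raised-cosine cycle of period ``p``, optionally
  inverted and scaled (models one cycle of a quasi-periodic rhythm such as
  hippocampal theta);
* ``rc`` — the impulse response of a passive RC membrane,
  ``F(t) = (1/tau) * exp(-t/tau)`` (unit area before truncation).

All waveforms are hard-truncated to a fixed trace length (500 ms by
default).  The event-time origin differs per family and is carried on the
waveform: alpha, RC and Hann traces are causal (origin at sample 0) while
the Morlet envelope is centered mid-trace, so convolution aligns the
envelope peak with the event time.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal as _sps

from .spectral import PowerSpectrum

DEFAULT_SAMPLING_RATE = 1000.0
DEFAULT_LENGTH = 0.5


@dataclass
class Waveform:
    """Finite sampled impulse response of a single neural event."""

    values: np.ndarray
    sampling_rate: float
    family: str
    params: dict = field(default_factory=dict)
    origin_index: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("waveform values must be finite")
        if not 0 <= self.origin_index < max(self.values.size, 1):
            raise ValueError("origin_index outside the trace")

    @property
    def length(self) -> float:
        """Trace duration in seconds."""
        return self.values.size / self.sampling_rate

    def times(self) -> np.ndarray:
        """Time axis relative to the event origin (s)."""
        return (np.arange(self.values.size) - self.origin_index) / self.sampling_rate

    def scaled(self, c: float) -> "Waveform":
        return Waveform(
            c * self.values,
            self.sampling_rate,
            self.family,
            dict(self.params, scale=c * self.params.get("scale", 1.0)),
            self.origin_index,
        )


def _n_samples(length: float, sampling_rate: float) -> int:
    n = int(round(length * sampling_rate))
    if n < 2:
        raise ValueError("trace length too short for the sampling rate")
    return n


def alpha_waveform(
    tau: float = 0.0056,
    sampling_rate: float = DEFAULT_SAMPLING_RATE,
    length: float = DEFAULT_LENGTH,
) -> Waveform:
    """Alpha synaptic response ``t * exp(-t/tau)`` for t >= 0.

    ``tau`` (seconds) sets the time-to-peak; the default 5.6 ms is typical of
    a fast excitatory synaptic potential.  No amplitude normalization is
    applied beyond the formula.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    n = _n_samples(length, sampling_rate)
    t = np.arange(n) / sampling_rate
    return Waveform(
        t * np.exp(-t / tau),
        sampling_rate,
        "alpha",
        {"tau_s": tau},
        origin_index=0,
    )


def morlet_waveform(
    sigma: float,
    t0: float = 0.0,
    p: float = 0.02,
    mu: float = 0.0,
    sampling_rate: float = DEFAULT_SAMPLING_RATE,
    length: float = DEFAULT_LENGTH,
) -> Waveform:
    """Real Morlet (Gabor) atom: a sinusoid under a Gaussian envelope.

    ``values = exp(-(t - mu)**2 / (2 * sigma**2)) * sin((t - t0) * 2*pi/p)``
    on a time axis centered mid-trace (so the default ``mu = 0`` puts the
    envelope peak at the trace center).  ``sigma`` is the envelope width,
    ``p`` the carrier period, ``t0`` a carrier phase offset that moves
    spectral phase only.  Narrow sigma gives a spike-like transient; sigma
    comparable to p gives a spindle-like oscillation burst.  The power
    spectrum is centered near ``1/p`` with bandwidth inversely proportional
    to sigma.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if p <= 0:
        raise ValueError("period p must be positive")
    n = _n_samples(length, sampling_rate)
    center = n // 2
    t = (np.arange(n) - center) / sampling_rate
    values = np.exp(-((t - mu) ** 2) / (2.0 * sigma**2)) * np.sin(
        (t - t0) * 2.0 * np.pi / p
    )
    return Waveform(
        values,
        sampling_rate,
        "morlet",
        {"sigma_s": sigma, "t0_s": t0, "p_s": p, "mu_s": mu},
        origin_index=center,
    )


def hann_waveform(
    p: float,
    inverted: bool = False,
    scale: float = 1.0,
    sampling_rate: float = DEFAULT_SAMPLING_RATE,
    length: float = DEFAULT_LENGTH,
) -> Waveform:
    """One raised-cosine cycle of period ``p`` at the start of the trace.

    ``0.5 * (1 - cos(2*pi*t/p))`` for ``0 <= t <= p``, zero elsewhere;
    multiplied by -1 when ``inverted`` (a trough-first deflection, as used
    for theta-like rhythms) and by ``scale``.  ``p`` is quantized to the
    sample grid.
    """
    if p > length:
        raise ValueError("cycle period p exceeds the trace length")
    if p <= 0:
        raise ValueError("period p must be positive")
    n = _n_samples(length, sampling_rate)
    m = int(round(p * sampling_rate))
    if m < 2:
        raise ValueError("period p too short for the sampling rate")
    values = np.zeros(n)
    k = np.arange(m + 1)
    cycle = 0.5 * (1.0 - np.cos(2.0 * np.pi * k / m))
    values[: m + 1] = cycle[: min(m + 1, n)]
    sign = -1.0 if inverted else 1.0
    return Waveform(
        sign * scale * values,
        sampling_rate,
        "hann",
        {"p_s": p, "inverted": inverted, "scale": scale},
        origin_index=0,
    )


def rc_impulse(
    tau: float = 0.035,
    sampling_rate: float = DEFAULT_SAMPLING_RATE,
    length: float = DEFAULT_LENGTH,
) -> Waveform:
    """Impulse response of a passive RC membrane: ``(1/tau) * exp(-t/tau)``.

    Causal decaying exponential with unit area (up to truncation at the
    trace length).  Filtering white noise with it produces the 1/f^2
    high-frequency spectrum characteristic of background synaptic activity.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    n = _n_samples(length, sampling_rate)
    t = np.arange(n) / sampling_rate
    return Waveform(
        (1.0 / tau) * np.exp(-t / tau),
        sampling_rate,
        "rc",
        {"tau_s": tau},
        origin_index=0,
    )


def waveform_spectrum(w: Waveform) -> PowerSpectrum:
    """Single-segment power spectrum of the full waveform trace.

    The trace is tapered with a Hann window and the squared amplitude of its
    Fourier transform taken (one segment, no averaging, no detrending —
    waveforms carry genuine low-frequency content).  Frequency resolution is
    ``1/length`` (2 Hz for the default 500 ms trace).
    """
    freqs, power = _sps.welch(
        w.values,
        fs=w.sampling_rate,
        window="hann",
        nperseg=w.values.size,
        noverlap=0,
        detrend=False,
        scaling="density",
        return_onesided=True,
    )
    meta = {
        "segment_length_s": w.length,
        "taper": "hann",
        "n_segments": 1,
        "source": f"waveform:{w.family}",
        "params": dict(w.params),
    }
    return PowerSpectrum(freqs[1:], power[1:], meta)


def save_waveform(w: Waveform, path: str | Path) -> None:
    """Write a waveform as two-column text (time_s, value) + JSON sidecar."""
    path = Path(path)
    data = np.column_stack([w.times(), w.values])
    np.savetxt(path, data, fmt="%.9g", header="time_s value")
    sidecar = {
        "family": w.family,
        "params": w.params,
        "sampling_rate_hz": w.sampling_rate,
        "origin_index": w.origin_index,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def load_waveform(path: str | Path) -> Waveform:
    """Read a waveform written by :func:`save_waveform`."""
    path = Path(path)
    data = np.loadtxt(path)
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return Waveform(
        data[:, 1],
        sidecar["sampling_rate_hz"],
        sidecar["family"],
        sidecar.get("params", {}),
        sidecar.get("origin_index", 0),
    )
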