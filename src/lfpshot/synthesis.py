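"""Assemble voltage-like signals from timing trains and waveforms.

A recurring neural event contributes one copy of its waveform at every event
time; the recorded trace is the convolution of the timing pulse train with
the waveform (generalized shot noise).  Independent processes superpose
linearly in the field, so signals simply sum.  Background synaptic activity
is modeled as white noise filtered by the RC membrane impulse response.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve

from .point_process import PulseTrain
from .waveforms import Waveform, rc_impulse

__all__ = ["Signal", "convolve_train", "sum_signals", "rc_background_noise"]


@dataclass
class Signal:
    """Uniformly sampled real-valued series (a synthetic LFP trace)."""

    values: np.ndarray
    sampling_rate: float
    provenance: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("signal values must be finite")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def duration(self) -> float:
        return self.values.size / self.sampling_rate


def convolve_train(pulse: PulseTrain, w: Waveform) -> Signal:
    """Convolve a timing pulse train with a single-event waveform.

    Linear convolution truncated to the pulse train's length: each event
    contributes one waveform copy aligned on the family's time origin
    (causal for alpha/RC/Hann, envelope-centered for Morlet), and the tail
    extending past the recording end is discarded — the output covers
    exactly the input duration, with no wrap-around.
    """
    if not np.isclose(pulse.sampling_rate, w.sampling_rate):
        raise ValueError(
            f"sampling rates differ: pulse {pulse.sampling_rate} Hz, "
            f"waveform {w.sampling_rate} Hz"
        )
    n = pulse.values.size
    full = fftconvolve(np.asarray(pulse.values, dtype=float), w.values)
    start = w.origin_index
    out = full[start : start + n]
    return Signal(
        out,
        pulse.sampling_rate,
        provenance=[{"op": "convolve", "waveform": w.family,
                     "params": dict(w.params), "train": dict(pulse.provenance)}],
    )


def sum_signals(parts: list[Signal]) -> Signal:
    """Element-wise sum of signals sharing grid and duration."""
    if not parts:
        raise ValueError("need at least one signal")
    first = parts[0]
    for s in parts[1:]:
        if not np.isclose(s.sampling_rate, first.sampling_rate):
            raise ValueError("sampling rates differ")
        if s.values.size != first.values.size:
            raise ValueError("durations differ")
    total = np.sum([s.values for s in parts], axis=0)
    provenance: list = []
    for s in parts:
        provenance.extend(s.provenance)
    return Signal(total, first.sampling_rate, provenance)


def rc_background_noise(
    tau: float = 0.035,
    duration: float = 1000.0,
    sampling_rate: float = 1000.0,
    seed: int | None = None,
    kernel_length: float = 0.5,
    amplitude: float = 1.0,
) -> Signal:
    """Background synaptic noise: RC-filtered Gaussian white noise.

    Unit-variance white noise (scaled by ``amplitude``) is convolved with
    the causal RC impulse response of time constant ``tau``.  Above the RC
    corner frequency ``1/(2*pi*tau)`` the resulting spectrum falls as
    1/f^2.  Seed-deterministic.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed)
    n = int(round(duration * sampling_rate))
    noise = amplitude * rng.standard_normal(n)
    kernel = rc_impulse(tau, sampling_rate, kernel_length)
    out = fftconvolve(noise, kernel.values)[:n]
    return Signal(
        out,
        sampling_rate,
        provenance=[{"op": "rc_background_noise", "tau_s": tau,
                     "seed": seed, "amplitude": amplitude}],
    )
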