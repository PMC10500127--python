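"""Power-spectrum estimation and diagnostics.

All spectra in the package go through :func:`welch_psd`: a one-sided average
periodogram over non-overlapping Hann-tapered segments (default 500 ms, so the
frequency resolution is 2 Hz at a 1 kHz sampling rate).  Power is reported in
density units (``x**2 / Hz``, scipy's ``scaling="density"`` convention with
window-energy compensation); every diagnostic built on top of it — peak
detection, log-log slope fits, surrogate bands — is invariant to that global
normalization constant.

The 0 Hz bin is dropped from every spectrum.  For point-process inputs the
mean level is an arbitrary function of the discretization, and segment means
are removed before tapering anyway, so the DC bin carries no information.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal as _sps


@dataclass
class PowerSpectrum:
    """One-sided power spectrum on a uniform frequency grid.

    ``frequencies`` runs from the estimator resolution (one bin) up to the
    Nyquist frequency; the DC bin is excluded by construction.  ``meta``
    records how the estimate was obtained (segment length, taper, number of
    segments averaged, source description).
    """

    frequencies: np.ndarray
    power: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.frequencies.shape != self.power.shape:
            raise ValueError("frequency and power grids differ in length")
        if self.frequencies.size and self.frequencies[0] <= 0:
            raise ValueError("spectrum must not include the DC bin")
        if np.any(self.power < 0):
            raise ValueError("power must be nonnegative")

    @property
    def resolution(self) -> float:
        """Frequency grid spacing in Hz."""
        return float(self.frequencies[0]) if self.frequencies.size else np.nan

    def band(self, f_lo: float, f_hi: float) -> "PowerSpectrum":
        """Restrict to frequencies in ``[f_lo, f_hi]`` (inclusive)."""
        m = (self.frequencies >= f_lo) & (self.frequencies <= f_hi)
        return PowerSpectrum(self.frequencies[m], self.power[m], dict(self.meta))

    def normalized(self, f_lo: float = 100.0, f_hi: float = 500.0) -> "PowerSpectrum":
        """Divide power by its mean over ``[f_lo, f_hi]`` (shape comparison)."""
        m = (self.frequencies >= f_lo) & (self.frequencies <= f_hi)
        ref = float(np.mean(self.power[m]))
        if ref <= 0:
            raise ValueError("cannot normalize: zero mean power in reference band")
        meta = dict(self.meta)
        meta["normalized_band_hz"] = (f_lo, f_hi)
        return PowerSpectrum(self.frequencies, self.power / ref, meta)


@dataclass
class SurrogateBand:
    """Pointwise quantile envelope of surrogate spectra.

    ``lower`` and ``upper`` are the per-bin empirical ``alpha/2`` and
    ``1 - alpha/2`` quantiles over ``n_surrogates`` matched-Poisson spectra.
    """

    frequencies: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    n_surrogates: int
    alpha: float

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.lower = np.asarray(self.lower, dtype=float)
        self.upper = np.asarray(self.upper, dtype=float)
        if not (self.frequencies.shape == self.lower.shape == self.upper.shape):
            raise ValueError("band grids differ in length")
        if np.any(self.lower > self.upper):
            raise ValueError("lower quantile exceeds upper quantile")


def welch_psd(
    x,
    segment_length: float = 0.5,
    taper: str = "hann",
    detrend: str | bool = "constant",
) -> PowerSpectrum:
    """Welch power spectral density of a sampled series.

    Parameters
    ----------
    x
        Any object with ``values`` (1-d samples) and ``sampling_rate`` (Hz)
        attributes — a ``Signal``, a ``PulseTrain`` or a ``Waveform``.
    segment_length
        Segment duration in seconds.  Segments do not overlap; the input is
        cut into ``floor(duration / segment_length)`` of them.
    taper
        Window name passed to scipy (default Hann).
    detrend
        Per-segment detrending; the constant (mean) is removed by default so
        the DC level of pulse trains does not leak into the first bins.  Pass
        ``False`` to taper-and-square the raw segments.

    Returns
    -------
    PowerSpectrum
        One-sided density spectrum; DC bin dropped.
    """
    values = np.asarray(x.values, dtype=float)
    fs = float(x.sampling_rate)
    nperseg = int(round(segment_length * fs))
    if nperseg < 2:
        raise ValueError("segment_length too short for the sampling rate")
    if values.size < nperseg:
        raise ValueError(
            f"input duration {values.size / fs:.3f} s shorter than "
            f"segment length {segment_length:g} s"
        )
    freqs, power = _sps.welch(
        values,
        fs=fs,
        window=taper,
        nperseg=nperseg,
        noverlap=0,
        detrend=detrend,
        scaling="density",
        return_onesided=True,
    )
    meta = {
        "segment_length_s": nperseg / fs,
        "taper": taper,
        "n_segments": values.size // nperseg,
        "detrend": detrend,
        "source": getattr(x, "provenance", None) or type(x).__name__,
    }
    return PowerSpectrum(freqs[1:], power[1:], meta)


def find_spectral_peaks(
    s: PowerSpectrum,
    min_prominence_ratio: float = 1.5,
    f_range: tuple[float, float] | None = None,
    neighborhood_bins: int = 10,
    min_power_ratio: float = 1e-9,
) -> list[tuple[float, float]]:
    """Local spectral maxima standing out from the local background.

    A bin is a peak when it is a strict local maximum and its power is at
    least ``min_prominence_ratio`` times the median power in a
    ``±neighborhood_bins`` window around it (a peak over a zero background
    always qualifies).  Bins below ``min_power_ratio`` times the strongest
    bin in range are ignored: they are numerical residue, not structure
    (line spectra have background bins at machine precision).  Peaks are
    returned sorted by frequency; adjacent equal-power plateaus keep the
    higher-power representative.
    """
    if f_range is None:
        f_range = (float(s.frequencies[0]), float(s.frequencies[-1]))
    lo, hi = f_range
    mask = (s.frequencies >= lo) & (s.frequencies <= hi)
    if not np.any(mask):
        raise ValueError("empty frequency range")
    f = s.frequencies[mask]
    p = s.power[mask]
    floor = min_power_ratio * float(p.max(initial=0.0))
    peaks: list[tuple[float, float]] = []
    for i in range(p.size):
        left = p[i - 1] if i > 0 else -np.inf
        right = p[i + 1] if i < p.size - 1 else -np.inf
        if not (p[i] > left and p[i] >= right and p[i] > floor):
            continue
        if p[i] == right:  # plateau: keep its first sample unless it rises after
            j = i + 1
            while j < p.size and p[j] == p[i]:
                j += 1
            if j < p.size and p[j] > p[i]:
                continue
        sl = slice(max(0, i - neighborhood_bins), min(p.size, i + neighborhood_bins + 1))
        local_median = float(np.median(p[sl]))
        if local_median > 0 and p[i] < min_prominence_ratio * local_median:
            continue
        peaks.append((float(f[i]), float(p[i])))
    return peaks


def fit_loglog_slope(s: PowerSpectrum, f_range: tuple[float, float]) -> float:
    """Least-squares slope of log10(power) against log10(frequency).

    Quantifies power-law behaviour (0 for a flat spectrum, -2 for the RC
    filtered-noise background).  Requires at least 5 strictly positive bins
    in the range.
    """
    lo, hi = f_range
    mask = (s.frequencies >= lo) & (s.frequencies <= hi)
    if np.count_nonzero(mask) < 5:
        raise ValueError("need at least 5 frequency bins in range")
    p = s.power[mask]
    if np.any(p <= 0):
        raise ValueError("zero or negative power in fit range")
    slope, _ = np.polyfit(np.log10(s.frequencies[mask]), np.log10(p), 1)
    return float(slope)


def poisson_surrogate_band(
    train,
    n_surrogates: int = 1000,
    alpha: float = 0.05,
    seed: int | None = None,
    segment_length: float = 0.5,
    sampling_rate: float = 1000.0,
) -> SurrogateBand:
    """Confidence band from count-matched Poisson randomizations.

    Each surrogate redraws the observed number of events uniformly over the
    recording (a binomial point process — the count-conditioned version of a
    homogeneous Poisson process), discretizes it on the same grid as the
    input and estimates its Welch spectrum identically.  The band is the
    per-bin (alpha/2, 1 - alpha/2) empirical quantile envelope.
    """
    from .point_process import EventTrain, events_to_pulse  # cycle: pp imports spectral

    if n_surrogates < 100:
        raise ValueError("n_surrogates must be at least 100")
    if train.n_events == 0:
        raise ValueError("cannot build surrogates for an empty train")
    rng = np.random.default_rng(seed)
    n_events = train.n_events
    duration = train.duration
    spectra = None
    freqs = None
    for i in range(n_surrogates):
        times = np.sort(rng.uniform(0.0, duration, size=n_events))
        surrogate = EventTrain(times, duration, provenance={"surrogate": i})
        pulse = events_to_pulse(surrogate, sampling_rate)
        ps = welch_psd(pulse, segment_length=segment_length)
        if spectra is None:
            freqs = ps.frequencies
            spectra = np.empty((n_surrogates, freqs.size))
        spectra[i] = ps.power
    lower = np.quantile(spectra, alpha / 2.0, axis=0)
    upper = np.quantile(spectra, 1.0 - alpha / 2.0, axis=0)
    return SurrogateBand(freqs, lower, upper, n_surrogates, alpha)


def band_exceedance(
    s: PowerSpectrum, band: SurrogateBand
) -> list[tuple[float, int]]:
    """Bins where a spectrum leaves the surrogate band.

    Returns ``(frequency, direction)`` pairs with direction ``+1`` for power
    above the upper quantile and ``-1`` for power below the lower one.
    """
    if s.frequencies.shape != band.frequencies.shape or not np.allclose(
        s.frequencies, band.frequencies
    ):
        raise ValueError("spectrum and band are on different frequency grids")
    out: list[tuple[float, int]] = []
    for f, p, lo, hi in zip(s.frequencies, s.power, band.lower, band.upper):
        if p > hi:
            out.append((float(f), +1))
        elif p < lo:
            out.append((float(f), -1))
    return out


def argmax_frequency(s: PowerSpectrum, f_range: tuple[float, float] | None = None) -> float:
    """Frequency of the highest-power bin, optionally within a range."""
    if f_range is not None:
        s = s.band(*f_range)
    if s.power.size == 0:
        raise ValueError("empty spectrum")
    return float(s.frequencies[int(np.argmax(s.power))])


def refine_peak_frequency(
    s: PowerSpectrum,
    around: float | None = None,
    half_width: float = 10.0,
) -> float:
    """Sub-bin peak location by a log-quadratic fit around a maximum.

    Broad spectral peaks (e.g. a bell inherited from a wide-band waveform)
    have an argmax bin that wanders with estimation noise; fitting a
    parabola to ``log(power)`` over ``±half_width`` Hz around the maximum
    localizes the peak well below the bin resolution.  Falls back to the
    raw argmax when the fit is not concave or the window is too small.
    """
    if around is None:
        around = argmax_frequency(s)
    m = np.abs(s.frequencies - around) <= half_width
    if np.count_nonzero(m) < 5 or np.any(s.power[m] <= 0):
        return float(around)
    a, b, _ = np.polyfit(s.frequencies[m], np.log(s.power[m]), 2)
    if a >= 0:
        return float(around)
    vertex = -b / (2.0 * a)
    lo, hi = around - half_width, around + half_width
    return float(min(max(vertex, lo), hi))
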