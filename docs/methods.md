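# Methods

## Model

`lfpshot` treats a neural recording as a superposition of *generalized shot
noise* processes: each recurring neural event (a synaptic activation, a
spike, a synaptic barrage) occurs at the times of a point process and
contributes a fixed voltage waveform to the recorded trace,

    x(t) = sum_k w(t - t_k) ,

i.e. the convolution of the event-timing pulse train with the single-event
impulse response `w`.  Because convolution multiplies spectra and
superposition adds them, the power spectrum of a simulated local field
potential decomposes into (timing spectrum) × (waveform spectrum), summed
over processes.  The package simulates each ingredient, assembles signals,
and estimates spectra the way practitioners do on real data, so that the
spectral consequences of timing statistics, waveform shape and summation
can be studied in isolation.

### Timing: gamma renewal processes

Inter-event intervals are i.i.d. gamma with shape `a` and scale
`b = 1/(a f)`, which pins the mean interval to `1/f` for every shape and
gives interval CV `1/sqrt(a)`:

* `a = 1` — Poisson: flat timing spectrum at level `f`.
* `a > 1` — regular / sub-Poissonian (count Fano factor < 1): spectral peak
  near `f`; harmonics emerge as `a` grows; the periodic train is the limit.
* `a < 1` — bursty / super-Poissonian (Fano > 1): monotonically decaying
  timing spectrum.

The closed-form check is the renewal (Bartlett) spectrum
`S(f) = rate * Re[(1 + phi)/(1 - phi)]` with
`phi(f) = (1 - i 2 pi f b)^(-a)` the interval characteristic function;
`analytic_renewal_psd` implements it and the test suite compares it
against the Welch estimate of simulated trains.

Renewal sampling starts at t = 0 with the first event at the first sampled
interval; no stationary-renewal (equilibrium) correction is applied.  The
transient is one interval out of tens of thousands at the default 1000 s
duration.  Very bursty trains (`a = 0.1`) produce intervals below the
floating-point spacing of the time axis; ties in the event times are kept
(they collapse into one sample at discretization, where the collision is
counted) rather than perturbed, so interval statistics stay unbiased.

Mixture ("compound") trains draw each interval from a weighted mixture of
gamma densities (equal weights by default).  Phase-modulated trains gate a
gamma carrier on the phase of a slower modulator train: an event survives
only if its latency from the most recent modulator event, as a fraction of
the modulator period, falls in the keep window.  The default keep window is
the first half-cycle `[0, 0.5)` — with an inverted (trough-first) Hann
waveform for the modulating rhythm, the second half-cycle is the rising
("upward") phase, so dropping it reproduces gamma activity riding the
falling phase of theta.  This half-cycle convention is a documented choice;
the boundary between "upward" and "downward" is not otherwise pinned down.

### Waveforms

Four parametric families, all hard-truncated to a 500 ms trace at 1 kHz:

| family  | formula | default | alignment |
|---------|---------|---------|-----------|
| alpha   | `t exp(-t/tau)`, t ≥ 0 | tau = 5.6 ms | causal (origin at 0) |
| morlet  | `exp(-(t-mu)^2/2sigma^2) sin((t-t0) 2 pi / p)` | mu = 0 | envelope centered mid-trace |
| hann    | one raised-cosine cycle of period `p`, optional inversion/scale | — | causal |
| rc      | `(1/tau) exp(-t/tau)` | tau = 35 ms | causal |

The Morlet (Gabor) spectrum is centered near `1/p` with bandwidth
`~1/(2 pi sigma)`; narrow sigma gives spike-like transients, sigma ≈ p
gives spindles.  The Hann cycle is nonnegative, so its spectrum is a
DC-centered low-pass lobe with cutoff ≈ `2/p` (not a band-pass lobe at
`1/p`); its band-pass character in the simulations comes from the timing
train it is convolved with.  Hann periods are quantized to the sample grid
(e.g. 12.5 ms → 12 samples at 1 kHz), which shifts the nominal cycle
frequency by < 5% — negligible at 2 Hz spectral resolution.  No amplitude
normalization is applied beyond the formulas; every acceptance-level check
(peak positions, slopes, normalized shapes) is scale-free.

### Signals

Convolution is linear, FFT-based, truncated to the recording length (the
tail past the end is discarded; no wrap-around).  Each family's origin
determines alignment: causal families start at the event sample, the
Morlet envelope peaks on it.  Background synaptic activity is unit-variance
Gaussian white noise convolved with the RC impulse response; above the RC
corner `1/(2 pi tau)` ≈ 4.5 Hz its spectrum falls as `1/f^2`.

## Spectral estimation

`welch_psd` averages one-sided periodograms over non-overlapping Hann-
tapered segments (default 500 ms → 2 Hz resolution, 2000 segments at
1000 s).  Conventions, fixed package-wide:

* scipy `density` scaling with window-energy compensation; the absolute
  constant is irrelevant to every diagnostic built on top.
* per-segment mean removal (`detrend="constant"`), so the DC level of pulse
  trains does not leak into the lowest bins; the 0 Hz bin is dropped from
  all spectra.  Waveform spectra (`waveform_spectrum`) are single-segment
  and *not* detrended, since a waveform's low-frequency content is real.
* pulse trains are binary by default ("1 at event samples"); a counting
  mode is available and is what the analytic-spectrum cross-checks use,
  because binary clipping thins very bursty trains (at `a = 0.1`, 40 Hz,
  about half the events share a 1 ms bin with a neighbour).

Peak detection reports strict local maxima exceeding 1.5× the local median
(±10 bins), ignoring bins below 1e-9 of the range maximum (line spectra
have background bins at machine precision, which are residue, not
structure).  For broad peaks the argmax bin is a high-variance estimator;
`refine_peak_frequency` fits a parabola to log-power around the maximum
(default ±10 Hz, ±30 Hz for the ~50 Hz-wide spike-train bell) and returns
the vertex.  Power-law slopes are least-squares fits of log10 power against
log10 frequency; the default 20–200 Hz range for the RC background sits
above the RC corner and below the Nyquist roll-off.

Surrogate testing redraws the observed number of events uniformly over the
recording (count-matched Poisson / binomial process), discretizes and
Welch-estimates each surrogate identically to the input, and forms per-bin
empirical quantile envelopes.  For a Poisson input the fraction of bins
leaving the band calibrates to alpha; regular trains exceed the band at
their rate and fall below it at low frequencies.

## Synthetic-data conditions

Default grid: 1 kHz sampling, 1000 s duration.  The experiment catalogue
(`lfpshot/configs/*.yaml`) fixes the simulated scenarios: 40 Hz processes
with `a ∈ {0.1, 1, 10^1.2, 10^1.5, 10, 100, 1000}` and the periodic limit;
alpha (5.6 ms), spike Morlet (sigma 1.7 ms, t0 3.7 ms, p 6.7 ms), spindle
Morlet (sigma 66.7 ms, p 66.7 ms), unit-spike Morlet (sigma 3.3 ms,
t0 7.3 ms, p 13.3 ms, 75 Hz Poisson timing); RC background (tau 35 ms);
a 50/80/20 Hz mixture train; theta as a 7 Hz `a = 10^1.5` train with an
inverted 142.9 ms Hann cycle; theta-nested gamma as an 80 Hz `a = 10^1.5`
carrier gated to the theta falling half-cycle with an inverted 12.5 ms
Hann cycle scaled 1/8.

What the generator emulates: event-timing statistics, waveform shape, and
linear superposition.  What it does not: amplitude/shape variability across
events, phase-locked cancellation between processes, spatial/conductivity
effects of the extracellular medium, and any fitting to recorded data.
Passing tests therefore validate the spectral *mechanics* (how timing,
waveform and summation shape a spectrum), not the biological realism of
any particular waveform.

## Numerical choices and degenerate inputs

* Event discretization rounds times to the nearest sample; an event
  rounding to the sample past the grid end is clipped to the last sample.
  Collisions are counted and clipped to 1 in binary mode.
* `a = 1` makes the renewal characteristic-function ratio `(1+phi)/(1-phi)`
  finite at all f > 0; f = 0 is rejected (the mean atom is excluded).
* Zero-amplitude inputs propagate to zero spectra; empty trains are valid
  pulse trains but invalid inputs for histograms, statistics and surrogate
  bands (errors, not NaNs).
* Experiment seeds derive from a stable hash of the experiment name;
  every stochastic component inside an experiment draws from an
  independently spawned `SeedSequence` stream, so component realizations
  are independent and reruns are bit-reproducible.
* Test-suite problem sizes: unit and property tests simulate 5–300 s;
  the end-to-end suite and the acceptance script use the full 1000 s
  conditions (a 1000 s Welch estimate takes well under a second).

## Known limitations

* The quantile band assumes exchangeable bins under the null; it tests
  against count-matched uniform timing only, not against rate
  nonstationarity.
* The analytic renewal spectrum describes the continuous-time counting
  measure; the discretized comparison holds on interior bins (the first
  bin is biased by per-segment mean removal, the Nyquist bin by one-sided
  folding) and in counting mode.
* Slope estimates weight bins uniformly on the linear frequency grid, so
  they emphasize the top of the fitted range (a property shared by common
  aperiodic-slope fitters on linearly gridded spectra).
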