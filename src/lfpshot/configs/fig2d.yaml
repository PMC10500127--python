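description: Poisson 40 Hz train convolved with a spindle-shaped Morlet wavelet.
duration_s: 1000.0
sampling_rate_hz: 1000.0
variants:
  - label: spindle
    components:
      - kind: shot
        process: {kind: gamma, shape: 1.0, rate_hz: 40.0}
        waveform: {family: morlet, sigma_s: 0.0667, t0_s: 0.0, p_s: 0.0667}
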