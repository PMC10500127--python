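description: 75 Hz Poisson spike train (Morlet spike waveform); bell-shaped spectrum peaking at 75 Hz.
duration_s: 1000.0
sampling_rate_hz: 1000.0
variants:
  - label: poisson_spikes
    components:
      - kind: shot
        process: {kind: gamma, shape: 1.0, rate_hz: 75.0}
        waveform: {family: morlet, sigma_s: 0.0033, t0_s: 0.0073, p_s: 0.0133}
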