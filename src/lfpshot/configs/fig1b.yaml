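description: Poisson 40 Hz process; flat timing spectrum.
duration_s: 1000.0
sampling_rate_hz: 1000.0
variants:
  - label: poisson
    components:
      - kind: pulse
        process: {kind: gamma, shape: 1.0, rate_hz: 40.0}
    analysis: {slope_range_hz: [4.0, 500.0]}
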