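description: Perfectly periodic 40 Hz train; power concentrated at the rate and its harmonics.
duration_s: 1000.0
sampling_rate_hz: 1000.0
variants:
  - label: periodic
    components:
      - kind: pulse
        process: {kind: periodic, rate_hz: 40.0}
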