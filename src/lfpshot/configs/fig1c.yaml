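description: Sub-Poissonian (regular) 40 Hz gamma process (a = 10^1.5); spectral peak near the rate.
duration_s: 1000.0
sampling_rate_hz: 1000.0
variants:
  - label: sub_poissonian
    components:
      - kind: pulse
        process: {kind: gamma, shape: 31.6227766017, rate_hz: 40.0}
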