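description: Quasi-periodic theta (7 Hz), theta-modulated gamma (80 Hz carrier), and their sum.
duration_s: 1000.0
sampling_rate_hz: 1000.0
variants:
  - label: theta
    components:
      - kind: shot
        process: {kind: gamma, shape: 31.6227766017, rate_hz: 7.0}
        waveform: {family: hann, p_s: 0.1429, inverted: true}
  - label: modulated_gamma
    components:
      - kind: shot
        process:
          kind: modulated
          carrier: {shape: 31.6227766017, rate_hz: 80.0}
          modulator: {shape: 31.6227766017, rate_hz: 7.0}
          modulator_period_s: 0.142857143
          keep_fraction_of_cycle: [0.0, 0.5]
        waveform: {family: hann, p_s: 0.0125, inverted: true, scale: 0.125}
  - label: sum
    components:
      - kind: shot
        process: {kind: gamma, shape: 31.6227766017, rate_hz: 7.0}
        waveform: {family: hann, p_s: 0.1429, inverted: true}
      - kind: shot
        process:
          kind: modulated
          carrier: {shape: 31.6227766017, rate_hz: 80.0}
          modulator: {shape: 31.6227766017, rate_hz: 7.0}
          modulator_period_s: 0.142857143
          keep_fraction_of_cycle: [0.0, 0.5]
        waveform: {family: hann, p_s: 0.0125, inverted: true, scale: 0.125}
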