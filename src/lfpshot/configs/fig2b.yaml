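description: Poisson 40 Hz train convolved with the alpha synaptic waveform (tau = 5.6 ms).
duration_s: 1000.0
sampling_rate_hz: 1000.0
variants:
  - label: alpha
    components:
      - kind: shot
        process: {kind: gamma, shape: 1.0, rate_hz: 40.0}
        waveform: {family: alpha, tau_s: 0.0056}
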