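description: Background synaptic noise, RC-filtered white noise (tau = 35 ms); 1/f^2 spectrum.
duration_s: 1000.0
sampling_rate_hz: 1000.0
variants:
  - label: rc_background
    components:
      - kind: rc_noise
        tau_s: 0.035
    analysis: {slope_range_hz: [20.0, 200.0]}
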