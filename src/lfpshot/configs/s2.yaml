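description: Compound mixture train (Poisson 50 Hz + gamma a=20 f=80 + gamma a=40 f=20) and its components.
duration_s: 1000.0
sampling_rate_hz: 1000.0
variants:
  - label: poisson_50
    components:
      - {kind: pulse, process: {kind: gamma, shape: 1.0, rate_hz: 50.0}}
  - label: gamma_80
    components:
      - {kind: pulse, process: {kind: gamma, shape: 20.0, rate_hz: 80.0}}
  - label: gamma_20
    components:
      - {kind: pulse, process: {kind: gamma, shape: 40.0, rate_hz: 20.0}}
  - label: compound
    components:
      - kind: pulse
        process:
          kind: compound
          components:
            - {shape: 1.0, rate_hz: 50.0}
            - {shape: 20.0, rate_hz: 80.0}
            - {shape: 40.0, rate_hz: 20.0}
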