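description: Gamma processes of increasing regularity (a = 1 ... 1000) and the periodic limit; harmonics emerge.
duration_s: 1000.0
sampling_rate_hz: 1000.0
variants:
  - label: a1
    components:
      - {kind: pulse, process: {kind: gamma, shape: 1.0, rate_hz: 40.0}}
  - label: a10
    components:
      - {kind: pulse, process: {kind: gamma, shape: 10.0, rate_hz: 40.0}}
  - label: a100
    components:
      - {kind: pulse, process: {kind: gamma, shape: 100.0, rate_hz: 40.0}}
  - label: a1000
    components:
      - {kind: pulse, process: {kind: gamma, shape: 1000.0, rate_hz: 40.0}}
  - label: periodic
    components:
      - {kind: pulse, process: {kind: periodic, rate_hz: 40.0}}
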