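description: Moderately regular train (a = 10^1.2, 40 Hz) with Hann pulses of increasing width.
duration_s: 1000.0
sampling_rate_hz: 1000.0
variants:
  - label: timing
    components:
      - {kind: pulse, process: {kind: gamma, shape: 15.8489319246, rate_hz: 40.0}}
  - label: hann_5ms
    components:
      - kind: shot
        process: {kind: gamma, shape: 15.8489319246, rate_hz: 40.0}
        waveform: {family: hann, p_s: 0.005}
  - label: hann_25ms
    components:
      - kind: shot
        process: {kind: gamma, shape: 15.8489319246, rate_hz: 40.0}
        waveform: {family: hann, p_s: 0.025}
  - label: hann_125ms
    components:
      - kind: shot
        process: {kind: gamma, shape: 15.8489319246, rate_hz: 40.0}
        waveform: {family: hann, p_s: 0.125}
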