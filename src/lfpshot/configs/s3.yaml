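description: Periodic 40 Hz train convolved with alpha, spike-Morlet and spindle-Morlet waveforms.
duration_s: 1000.0
sampling_rate_hz: 1000.0
variants:
  - label: timing
    components:
      - {kind: pulse, process: {kind: periodic, rate_hz: 40.0}}
  - label: alpha
    components:
      - kind: shot
        process: {kind: periodic, rate_hz: 40.0}
        waveform: {family: alpha, tau_s: 0.0056}
  - label: spike
    components:
      - kind: shot
        process: {kind: periodic, rate_hz: 40.0}
        waveform: {family: morlet, sigma_s: 0.0017, t0_s: 0.0037, p_s: 0.0067}
  - label: spindle
    components:
      - kind: shot
        process: {kind: periodic, rate_hz: 40.0}
        waveform: {family: morlet, sigma_s: 0.0667, t0_s: 0.0, p_s: 0.0667}
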