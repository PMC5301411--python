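seed: 7
output_dir: example_out
phantom:
  nx: 64
  ny: 64
  pixel_mm: [1.2, 1.2]
  vessel_radius_mm: 7.5
  Nc: 8
  noise_sd: 0.05
  VENC: 100.0
  waveform: {kind: I, period_s: 2.0, peak_cm_s: 60.0, baseline_cm_s: 10.0}
acquisition: {Nv: 2, TR_ms: 5.0, duration_s: 10.0}
recon: {L: 20, mode: joint}
analysis: {assumed_period_s: 2.0, compare_truth: true}
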