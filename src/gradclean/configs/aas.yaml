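# Averaged artifact subtraction (AAS): block-wise template averaging with a
# 0.975 correlation gate, 100-slice blocks, 10x interpolation, 70 Hz
# post low-pass and adaptive noise cancellation.
trigger_label: slice
correction:
  sequence: [cut, upsample, align_slices, template, downsample, paste,
             lowpass, anc]
  upsample_factor: 10
  avg_matrix: {scheme: allen, block: 100, corr_threshold: 0.975}
  lp_cutoff_hz: 70.0
  dont_touch_non_artifact: true
  volume_gap_fill: linear
  rng_seed: 0
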