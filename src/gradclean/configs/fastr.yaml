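# FASTR-style correction: 1 Hz Gaussian high-pass prefilter, 10x
# interpolation with sub-sample epoch alignment, sliding-window template
# over every second slice of a 30-slice window, OBS-PCA residual removal
# as a separate subtraction step, 70 Hz post low-pass and adaptive noise
# cancellation.
trigger_label: slice
prefilter:
  kind: gauss
  hp_hz: 1.0
correction:
  sequence: [cut, upsample, align_slices, align_subsample,
             remove_volume_artifact, template, obs,
             downsample, paste, lowpass, anc]
  upsample_factor: 10
  avg_window: 30
  avg_matrix: {scheme: fastr_slice}
  obs_num_pcs: 3
  lp_cutoff_hz: 70.0
  dont_touch_non_artifact: true
  volume_gap_fill: linear
  rng_seed: 0
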