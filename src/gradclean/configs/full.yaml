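# Full correction sequence: 1 Hz Gaussian high-pass prefilter, 10x
# interpolation with integer and sub-sample epoch alignment, volume-artifact
# handling, block-wise (Allen) template averaging with the 0.975 correlation
# gate, OBS-PCA residual removal, 70 Hz post low-pass and adaptive noise
# cancellation.  This is the configuration used for the synthetic
# end-to-end validation.
trigger_label: slice
prefilter:
  kind: gauss
  hp_hz: 1.0
correction:
  sequence: [cut, upsample, align_slices, align_subsample,
             remove_volume_artifact, template, obs,
             downsample, paste, lowpass, anc]
  upsample_factor: 10
  avg_matrix: {scheme: allen, block: 100, corr_threshold: 0.975}
  obs_num_pcs: 3
  lp_cutoff_hz: 70.0
  dont_touch_non_artifact: true
  volume_gap_fill: linear
  rng_seed: 0
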