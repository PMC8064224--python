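# Example pipeline configuration. Flags override these values.
simulate:
  group: WT
  eye: OD
  age_months: 2
  n_eyes: 4
  sim:
    noise_sd_um: 2.0
    nasal_temporal_slope_um: 1.0
    disc_distance_slope_um: -2.0
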