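# Desk-scale demo screen: one 8x4 plate region, 5 focal planes per well.
seed: 1
outdir: scratch/demo_run
plate_name: P1
screen:
  plate_shape: [4, 8]
  n_planes: 5
  image_size: [256, 256]
  cysts_per_well: [10, 14]
  base_radius_px: 10.0
  noise_sd: 40.0
  replicates: 4
  doses_um: [0.1, 1.0]
  n_unstim_controls: 4
  n_stim_controls: 4
compounds:
  - {name: active, ec50_um: 0.01, hill_slope: 2.0, max_inhibition: 1.0}
  - {name: inert, max_inhibition: 0.0}
  - {name: toxicant, ec50_um: 0.02, hill_slope: 2.0, toxic: true}
segmentation:
  smoothing_sigma: 0.8
  min_area_px: 30
nuclei: {}
normalization:
  scale_policy: mad
  size_feature: area_px_median
  hit_threshold: 0.0
profiling:
  zprime_cutoff: -1.0
  mahalanobis_radius: 3.5
  nuclei_fraction_cutoff: 0.5
stages: [simulate, segment, featurize, normalize, qc, hits, profile]
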