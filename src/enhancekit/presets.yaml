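# Synthetic cohort presets (SyntheticSpec fields).
# cnp-like: imbalanced 4-class cohort, edge-like Gaussian features;
# separation pre-calibrated so the logistic-regression nested-CV baseline
# sits near 50% (chance = 47.76%).
cnp-like:
  class_sizes: [117, 46, 44, 38]
  n_features: 2000
  separation: 3.0
  covariance: isotropic
  connectome_mode: false
  within_sd: 0.1
  edge_mean: 0.25
  edge_sd: 0.25
  seed: 0

cnp-like-small:
  class_sizes: [40, 16, 15, 13]
  n_features: 300
  separation: 3.0
  covariance: isotropic
  connectome_mode: false
  within_sd: 0.1
  edge_mean: 0.25
  edge_sd: 0.25
  seed: 0

connectome-small:
  class_sizes: [20, 10, 10]
  n_features: 45
  separation: 2.0
  connectome_mode: true
  n_nodes: 10
  n_timepoints: 120
  seed: 0
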