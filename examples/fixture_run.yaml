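# Small fixture configuration for a complete, fast pipeline run.
# Reduced permutation counts keep it quick; production runs use the
# 50,000 / 10,000 defaults.
synthetic:
  n_rois: 20
  block_sizes: [10, 10]
  n_timepoints: 80
  rho_in_control: 0.5
  rho_out: 0.1
  delta_rho_in: -0.15
  n_per_group: 10
  seed: 42
thresholds: [0.3, 0.5]
n_permutations_global: 200
n_permutations_nodal: 200
cv_schemes: [loo]
classifiers: [lda, knn]
seed: 42
out_dir: fixture_out
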