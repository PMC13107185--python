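# Default end-to-end pipeline configuration on a synthetic cohort.
# The simulated cohort follows the study conditions: 20 Healthy donors,
# 124 patients with paired NAT/Tumor samples, mode effect 1.0 log2 units,
# within-group noise sd 0.5.
seed: 1
outdir: escctraj_out
simulate:
  n_proteins: 2000
de:
  alpha: 0.01
  fc_min: 1.5
  require_fc: false
subtype:
  feature_fraction: 0.25
  k_range: [2, 6]
  n_resamples: 100
  n_init: 5
survival:
  endpoint: OS
  nfolds: 5
  lambda_grid: [1.0, 10.0, 100.0, 1000.0]
  mode_models: [US, All]
  t_eval_years: [3, 5]
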