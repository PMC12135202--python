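seed: 1
out_dir: scratch/demo
control: control
alpha: 0.05
n_comparisons: null
n_boot_viability: 20000
n_boot_ci: 1000
n_viability_embryos: 200
cat1_threshold: 0.9
cat3_threshold: 0.6
plots: false
scenarios:
- label: control
  K: 1.0
  beta_over_gamma: 1.2
  n: inf
  noise_cv: 0.1
  n_embryos: 50
  hatch_prob: 0.97
- label: no_feedback
  K: inf
  beta_over_gamma: 0.71
  n: inf
  noise_cv: 0.1
  n_embryos: 50
  hatch_prob: 0.5
- label: cat2_mutant
  K: 1.0
  beta_over_gamma: 0.8
  n: inf
  noise_cv: 0.1
  n_embryos: 50
  hatch_prob: 0.9
- label: cat3_mutant
  K: 2.0
  beta_over_gamma: 0.7
  n: inf
  noise_cv: 0.1
  n_embryos: 50
  hatch_prob: 0.7
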