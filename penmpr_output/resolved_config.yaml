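data:
  categorical: {}
  missing: null
  path: missing.csv
  scale_covariates: []
  sep: null
  shape_covariates: []
  status: status
  time: time
output_dir: penmpr_output
penalty:
  adaptive_weights: null
  epsilon: 0.0001
  family: lasso
  scad_a: 3.7
  structure: single
  weight_cap: 1000000.0
  zero_threshold: 0.001
seed: 0
simulation: null
tuning:
  bounds: null
  de:
    cache_decimals: 4
    exploration_tol: 1.0e-05
    maxiter: 100
    mutation: 0.8
    popsize: null
    recombination: 0.9
    stall_generations: 10
    stall_tol: 0.0001
  grid: null
verbosity: info
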