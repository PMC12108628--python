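# Desk-scale smoke preset: two metaheuristics x one classifier x both
# objectives, 2 repetitions on a small synthetic table.
grid:
  metaheuristics: [pso, gwo, psa]
  classifiers: [knn]
  objectives: [OF1, OF2]
  repetitions: 2
  base_seed: 0
synthetic:
  n_samples: 400
  minority_fraction: 0.2889
  n_informative: 4
  n_noise: 8
  n_categorical: 0
  categorical_cardinalities: []
  effect_size: 1.0
  seed: 11
objective:
  k_folds: 3
metaheuristic:
  population_size: 6
  max_iter: 8
binarization:
  transfer: v1
  rule: standard
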