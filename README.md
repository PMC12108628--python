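# metafs

Binary-metaheuristic wrapper feature selection for imbalanced clinical
classification.

## The problem

Predicting intradialytic hypotension (IDH) — a drop in systolic blood
pressure of at least 20 mmHg during a hemodialysis session — from
session-start clinical and laboratory variables is a heavily imbalanced
classification problem (roughly 29% of sessions are hypotensive) over many
partially redundant features. `metafs` selects a compact, predictive
feature subset by *wrapper* search: candidate feature masks are scored by
actually training a classifier under a protocol designed for imbalance,
and a binarized population metaheuristic searches over masks.

The objective minimized over masks `S` is the weighted multi-objective

```
fitness(S) = α · (1 − recall) + (1 − α) · NSF / TNF,        α = 0.99
```

with `recall` either the macro recall (OF1) or the minority-class recall
(OF2), `NSF = |S|` the selected-feature count and `TNF` the total feature
count. Each evaluation runs shuffled 5-fold cross-validation; within each
fold the training part is balanced by random undersampling of the
majority class, min–max normalized (scaler fitted on the balanced
training fold only), used to train a classifier with its library-default
hyperparameters (KNN / random forest / XGBoost), and scored on the
untouched test fold; the nine metrics (macro, minority and majority
recall/precision/F-score) are averaged across folds.

Four metaheuristics are provided — particle swarm optimization (PSO),
grey wolf optimizer (GWO), pendulum search algorithm (PSA) and whale
optimization algorithm (WOA) — binarized by the two-step technique: a
transfer function `T: R → [0,1]` (S1–S4 sigmoidal, V1–V4 symmetric)
followed by a binarization rule (standard, complement,
static-probability, elitist). Competing configurations are compared over
repeated seeded runs with a gated nonparametric battery: Friedman omnibus
test, Nemenyi post hoc on significant omnibus, and one-sided Wilcoxon
signed-rank tests for directionality, plus win-count summaries.

Because the motivating clinical dataset is not public, the package ships
a synthetic generator that emulates its structure: feature tables with a
planted informative subset at configurable imbalance, raw hourly SBP
session records labeled by the 20 mmHg rule, and irregular laboratory
panels joined to sessions by a nearest-prior-date merge. Ground-truth
informative indices are returned so recovery can be measured.

## Worked example

Generate a synthetic dataset with 4 informative features among 12 noise
and two 3-level categorical columns (22 expanded features, minority
fraction 0.2889), then run a PSO + KNN + OF1 search:

```
$ metafs synth --n-samples 800 --n-informative 4 --n-noise 12 \
      --cardinalities 3,3 --effect-size 1.0 --seed 3 --out-dir demo
wrote demo/features.csv (800 rows, 22 features)

$ metafs search --data demo/features.csv --classifier knn --mh pso \
      --pop 10 --iters 20 --seed 1 --transfer v1 --out demo/pso_knn.json
best fitness 0.184350, TFS 9/22; wrote demo/pso_knn.json
```

The best mask `1111001100010110000000` keeps 9 of 22 features and —
reading `demo/pso_knn.json` — starts with `1111`: all four planted
informative columns were recovered. Its cross-validated metrics are
macro recall 0.818 (so the fitness is 0.99·(1−0.818) + 0.01·9/22 ≈
0.184), minority recall 0.838, minority precision 0.623 and macro
F-score 0.795: the balanced training protocol trades majority precision
for the minority-class detection that matters clinically.

A full comparison experiment (the 4 metaheuristics × 3 classifiers × 2
objectives grid, 31 seeded repetitions each) is driven by a config file:

```
$ metafs run --config run.yaml --out-dir runs/
$ metafs stats --results runs/results_long.csv --out-dir runs/stats
```

`run` is resumable (finished cells are skipped via per-cell manifests)
and writes a long-format results CSV, aggregate best/average/std tables
and one boxplot per metric; `stats` writes the Friedman summary, Nemenyi
p-value matrix, directed pairwise conclusions ("X is better than Y") and
win counts per objective.

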