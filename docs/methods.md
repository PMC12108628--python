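# Methods

## Problem and model

`metafs` implements wrapper feature selection for imbalanced binary
classification, motivated by predicting intradialytic hypotension (IDH) —
a systolic blood-pressure (SBP) drop during a hemodialysis session — from
session-start clinical and laboratory variables. A solution is a bit mask
over the feature set; the search minimizes the weighted multi-objective

    fitness(mask) = α · (1 − recall) + (1 − α) · NSF / TNF

where `recall` is either the macro recall (objective OF1) or the
minority-class recall (objective OF2), `NSF` the number of selected
features, `TNF` the total number of features, and `α = 0.99` by default so
that classification quality dominates and the feature-ratio term acts as a
tie-breaker toward smaller subsets. The empty mask is assigned fitness 1.0
(the maximum) without any classifier call; this keeps the search space
total and maximally penalizes the degenerate solution.

Evaluating a mask trains a real classifier: shuffled k-fold
cross-validation (k = 5), random undersampling of the **training fold
only** to a minority/majority ratio of 1.0, per-fold min–max normalization
fitted on the balanced training fold (test values may fall outside [0, 1];
constant training columns map to 0 everywhere), training with the
classifier's library-default hyperparameters (KNN and random forest from
scikit-learn, gradient-boosted trees from xgboost; `random_state` pinned
for reproducibility, exact parameters recorded by
`objective.classifier_manifest`), and arithmetic averaging of the nine
metrics across folds. Metrics are computed per fold and then averaged
(rather than pooling confusion counts first); the macro F-score is the
harmonic mean of macro precision and macro recall (the other convention,
the mean of per-class F-scores, is available as `macro_f1_classwise`).
Zero-denominator metrics return 0 with a degeneracy flag so fold averages
stay defined.

## Binarized metaheuristics

Four population metaheuristics search over masks: PSO (inertia decreasing
linearly 0.9 → 0.2, c1 = c2 = 2, symmetric velocity clamp at 5000 —
effectively inactive at this scale but kept for completeness), the grey
wolf optimizer (three leaders, exploration coefficient a: 2 → 0), the
pendulum search algorithm (parameter-free harmonic displacement
`2 e^{−t/t_max} cos(2πr)` toward the best), and the whale optimization
algorithm (even coin between a logarithmic spiral around the best, b = 1,
and an encircling/search move gated by |A|). Continuous positions are
mapped to bits by the two-step technique: a transfer function (four
S-shaped logistic curves with slopes 2, 1, 1/2, 1/3; four V-shaped
symmetric curves based on erf, tanh, x/√(1+x²) and arctan) followed by a
binarization rule (standard, complement, static-probability with its own
band parameter α_s ∈ (0, 0.5), default 1/3; elitist). The
roulette-elitist rule found in the same rule family is not implemented:
its published form depends on group-fitness quantities that are undefined
for a per-solution update. The study configuration is (S4, standard).

Two design choices deserve explanation:

**Positions persist; bits are samples.** Pseudocode of the form
"binarize population X" is ambiguous about whether the next iteration's
continuous update operates on the sampled bits or on the continuous
positions. We keep continuous positions across iterations and treat the
binary population as per-iteration samples (attractors — personal/global
bests, leaders — are the binary masks of the best evaluations). The
alternative, feeding bits back as positions, destroys all magnitude
information each iteration: an S-shaped transfer maps position 0 to
T(0) = 1/2, so every zero bit is re-randomized as a fair coin forever and
the population cannot hold a converged mask (measured on a 15-bit
hidden-mask surrogate, exact recovery drops from 20/20 to ≤ 11/20 for PSO
and to ≤ 3/20 for the other three algorithms).

**Benchmark transfer.** For the same reason, exact-recovery benchmarks use
the V1 transfer: V-shaped functions map position 0 to bit 0
deterministically, so a converged coordinate stays converged, while
S-shaped functions keep resampling the zero bits of any binary attractor
at probability 1/2 — making exact recovery of a known mask structurally
impossible regardless of the algorithm. The study default (S4, standard)
is unchanged for everything else; under it the algorithms still improve
monotonically over the random baseline, which is tested separately.

Per-iteration draw granularity: PSO draws r1, r2 per agent-dimension; GWO
draws its r1, r2 per agent and leader (scalar); PSA draws its phase per
agent-dimension; WOA draws p, l, r1, r2 and the random-agent index per
agent (scalars). Iterations are indexed t = 1..max_iter, so the
time-dependent coefficients reach their terminal values (w = w_min, a = 0)
exactly at the last iteration. Fitness ties keep the incumbent best
(strict improvement), and GWO leader ranking breaks fitness ties by agent
index, making runs bitwise reproducible from one master seed
(substreams derive from it for initialization, per-iteration draws, and
per-fold undersampling).

A known limitation, confirmed by instrumented runs: WOA lacks a
per-coordinate escape mechanism. Its search branch requires |A| ≥ 1
(inactive once a < 0.5, i.e. the last quarter of the run) and both
exploitation moves preserve a coordinate at exactly 0 when the incumbent
best is 0 there; with a V-shaped transfer such a coordinate can never be
resampled to 1. On the 15-bit surrogate this caps WOA's exact-recovery
rate near 87% (35/40 seeds; every failure sits at Hamming distance 1 with
one lost 1-bit), while PSO/GWO/PSA reach 97–100%.

Population size and iteration count are not prescribed by the
experimental protocol this package follows; defaults are 20 agents × 100
iterations (desk scale, configurable).

## Synthetic data

The clinical dataset (68,574 sessions, 71.11%/28.89% class split, 87
features after one-hot expansion of 3 categorical variables from 71) is
not public, so `metafs.synthetic` generates structural stand-ins:

- `generate_feature_table` plants `n_informative` unit-variance Gaussian
  columns whose class means differ by `effect_size` among
  class-independent noise and one-hot categorical columns, with an exactly
  controlled minority count `round(n · minority_fraction)`. Defaults echo
  the clinical table: minority fraction 0.2889, 68 numeric columns and 3
  categoricals of cardinalities (7, 6, 6) → 87 expanded columns. The real
  cardinalities are unpublished; these are a documented choice and nothing
  asserts against the resulting 87.
- `label_hypotension` encodes the clinical rule: IDH is present iff
  min(SBP hours 2–4) ≤ max(SBP hours 0–1) − 20 mmHg (inclusive), and the
  drop magnitude HYM is that maximal difference — defined so HYM ≥ 20
  exactly when the label fires. Hours 0–4 carry the rule; sessions with a
  missing hour are labeled missing and excluded.
- `generate_sessions` draws patient covariates (age, diabetic and
  hypertensive flags, baseline SBP) and a logistic drop-propensity on
  standardized covariates whose intercept is calibrated by bisection to a
  target prevalence (default 0.289). Trajectories are constructed so the
  drop indicator and the labeling rule coincide exactly: non-drop sessions
  never fall more than 15 mmHg below their early maximum; drop sessions
  reach exactly 20 + Exp(8) mmHg below it. Labels are always recomputed
  through `label_hypotension`, never stored independently.
- `join_nearest_prior` attaches each session's most recent same-patient
  lab with draw date ≤ session date (pandas backward as-of merge);
  duplicate same-day labs resolve to the latest by stable input order.

What this emulates — and does not: the generators reproduce the dataset's
*shape* (imbalance, planted relevant subset, expansion, irregular lab
cadence), not hemodynamics. SBP trajectories are noisy level curves, all
informative features are Gaussian with equal effect, and feature
correlations are absent. Passing tests therefore demonstrate that the
pipeline recovers planted structure under controlled conditions, not
clinical performance.

## Statistical comparison

Configurations (classifier × metaheuristic × objective, labeled
`XGB_PSO` etc.) are compared over repeated seeded runs with a three-stage
gated battery at significance 0.05 throughout: (1) tie-corrected Friedman
omnibus test on within-run mid-ranks (scipy); (2) Nemenyi post hoc from
the studentized-range distribution on mean-rank differences, computed only
after an omnibus rejection — requesting it otherwise raises `GateError`;
(3) one-sided Wilcoxon signed-rank tests ("A stochastically less than B",
i.e. A better under minimization) on Nemenyi-significant pairs only, zeros
dropped before ranking, exact null for ≤ 25 nonzero pairs and the
tie-corrected normal approximation above, with all-zero differences
reported as no-decision. Win counts summarize directed significant pairs
per configuration. No multiplicity correction is applied beyond Nemenyi.
Under a fully null simulation (31 runs × 12 identical configurations, 500
replicates) the stage-1 rejection rate is within 3 points of 5%.

## Problem sizes used in tests and the acceptance script

Wrapper evaluations dominate runtime (a single 5-fold random-forest
evaluation costs roughly 1–2 s per mask at n in the low thousands), so the
shipped checks run at desk scale, chosen once:

- surrogate search benchmark: 15 bits, population 20, 100 iterations,
  20 seeded runs per algorithm;
- planted-feature recovery: n = 600 samples, 30 features (5 informative,
  effect size 1.0, minority fraction 0.29), PSO + random forest + OF1,
  population 8, 15 iterations, 5 seeded runs, with mask-level memoization
  of objective evaluations;
- null calibration: 500 Friedman replicates on 31 × 12 matrices;
- session generator check: 500 patients × 20 sessions.

The full protocol (24 configurations × 31 repetitions on the complete
dataset) is what `metafs run` orchestrates; it is resumable cell by cell
and each cell is reproducible in isolation from its seed and manifest.

## Numerical conventions

- Transfer functions evaluate erf/tanh/expit in double precision; all
  forms are bounded, so no clipping is applied.
- The static-probability rule's middle band is `α_s < T < (1+α_s)/2`
  (keep the current bit); the boundary `T = (1+α_s)/2` maps to 1.
- One uniform draw is consumed per (agent, dimension) in row-major order
  during binarization regardless of the rule, so the draw stream is
  rule-independent and order-deterministic.
- `random_undersample` keeps all minority indices and draws
  `round(n_min/ratio)` majority indices without replacement; a request
  less balanced than the data is a warned no-op.
- Sample standard deviations use n − 1; single-run cells report std 0 and
  are flagged.
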