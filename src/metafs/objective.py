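"""Wrapper objective: balanced, normalized, cross-validated mask evaluation.

A candidate feature mask is scored by actually training a classifier on the
masked dataset: stratified-free shuffled k-fold split, random undersampling
of the *training* fold only (the test fold is never resampled), per-fold
min-max normalization fitted on the balanced training fold, training with
the classifier's library-default hyperparameters, and arithmetic averaging
of the nine metrics across folds.  The scalar fitness is the weighted
multi-objective

    fitness = alpha * (1 - recall) + (1 - alpha) * NSF / TNF

minimized over masks, where recall is the macro recall (OF1) or the
minority-class recall (OF2), NSF the number of selected features and TNF
the total number of features.  With the default alpha = 0.99 classification
quality dominates and the feature-count term breaks ties toward smaller
subsets.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field

import numpy as np

from .metrics import METRIC_NAMES, ConfusionCounts, metric_bundle, tfs


class ObjectiveId(str, enum.Enum):
    OF1 = "OF1"  # macro recall
    OF2 = "OF2"  # minority recall


class ClassifierId(str, enum.Enum):
    KNN = "knn"
    RANDOM_FOREST = "random_forest"
    XGBOOST = "gradient_boosted_trees"


@dataclass(frozen=True)
class ObjectiveConfig:
    objective_id: ObjectiveId = ObjectiveId.OF1
    alpha: float = 0.99
    k_folds: int = 5
    sampling_ratio: float = 1.0  # minority/majority after undersampling
    classifier_id: ClassifierId = ClassifierId.RANDOM_FOREST
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError("alpha must lie in [0, 1]")
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")
        if not (0.0 < self.sampling_ratio <= 1.0):
            raise ValueError("sampling_ratio must lie in (0, 1]")


@dataclass(frozen=True)
class FitnessRecord:
    """Fitness plus the metric suite for one evaluated mask.

    ``metrics`` is None for infeasible (empty) masks, which receive the
    worst fitness 1.0 without any classifier call.
    """

    fitness: float
    tfs: int
    metrics: dict | None = None
    objective_id: ObjectiveId = ObjectiveId.OF1
    alpha: float = 0.99
    tnf: int = 0

    @property
    def feasible(self) -> bool:
        return self.tfs > 0

    def to_dict(self) -> dict:
        return {
            "fitness": self.fitness,
            "tfs": self.tfs,
            "metrics": self.metrics,
            "objective_id": str(self.objective_id.value),
            "alpha": self.alpha,
            "tnf": self.tnf,
        }


def weighted_fitness(
    objective_id: ObjectiveId, alpha: float, recall_value: float,
    nsf: int, tnf: int,
) -> float:
    """alpha * (1 - recall) + (1 - alpha) * nsf / tnf."""
    ObjectiveId(objective_id)  # validate
    if not (0.0 <= recall_value <= 1.0):
        raise ValueError("recall must lie in [0, 1]")
    if not (1 <= nsf <= tnf):
        raise ValueError("need 1 <= nsf <= tnf (empty masks are infeasible)")
    return alpha * (1.0 - recall_value) + (1.0 - alpha) * nsf / tnf


def kfold_indices(n: int, k: int, seed: int) -> list[np.ndarray]:
    """Shuffled partition of range(n) into k test-index folds.

    Fold sizes differ by at most one; the union is the full index set.
    """
    if k < 2 or n < k:
        raise ValueError("need n >= k >= 2")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return [np.sort(part) for part in np.array_split(perm, k)]


def random_undersample(labels, ratio: float, seed: int) -> np.ndarray:
    """Undersample the majority class to a minority/majority ratio.

    All minority indices are kept; ``round(n_min / ratio)`` majority indices
    are drawn uniformly without replacement.  The output is sorted, so it is
    stable under the input ordering.  If the data is already at least that
    balanced the call is a no-op (with a warning).
    """
    labels = np.asarray(labels)
    if not (0.0 < ratio <= 1.0):
        raise ValueError("ratio must lie in (0, 1]")
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) != 2:
        raise ValueError("labels must contain exactly two classes")
    order = np.argsort(counts, kind="stable")
    minority, majority = classes[order[0]], classes[order[1]]
    n_min = int(counts[order[0]])
    n_maj = int(counts[order[1]])
    target_maj = int(round(n_min / ratio))
    if target_maj >= n_maj:
        if n_min / n_maj > ratio + 1e-12:
            warnings.warn(
                "requested ratio is below the current class ratio; "
                "undersampling the majority class cannot unbalance the data "
                "— keeping all samples", stacklevel=2)
        return np.arange(len(labels))
    rng = np.random.default_rng(seed)
    maj_idx = np.flatnonzero(labels == majority)
    kept_maj = rng.choice(maj_idx, size=target_maj, replace=False)
    kept = np.concatenate([np.flatnonzero(labels == minority), kept_maj])
    return np.sort(kept)


def minmax_fit_transform(train: np.ndarray, test: np.ndarray):
    """Per-column min-max scaling fitted on the training matrix.

    Test values outside the training range map outside [0, 1] (no
    clipping).  A constant training column maps to 0 everywhere, in both
    matrices.
    """
    train = np.asarray(train, dtype=float)
    test = np.asarray(test, dtype=float)
    if train.size == 0 or train.shape[0] == 0:
        raise ValueError("empty training matrix")
    if train.shape[1] != test.shape[1]:
        raise ValueError("train and test must share column count")
    lo = train.min(axis=0)
    span = train.max(axis=0) - lo
    constant = span == 0.0
    span = np.where(constant, 1.0, span)
    train_s = (train - lo) / span
    test_s = (test - lo) / span
    train_s[:, constant] = 0.0
    test_s[:, constant] = 0.0
    return train_s, test_s


_CLASSIFIER_BUILDERS = {}


def _build_knn(seed: int):
    from sklearn.neighbors import KNeighborsClassifier

    return KNeighborsClassifier()


def _build_rf(seed: int):
    from sklearn.ensemble import RandomForestClassifier

    # library defaults; random_state pinned for the determinism contract
    return RandomForestClassifier(random_state=seed)


def _build_xgb(seed: int):
    from xgboost import XGBClassifier

    return XGBClassifier(random_state=seed, n_jobs=1)


_CLASSIFIER_BUILDERS = {
    ClassifierId.KNN: _build_knn,
    ClassifierId.RANDOM_FOREST: _build_rf,
    ClassifierId.XGBOOST: _build_xgb,
}


def make_classifier(classifier_id: ClassifierId, seed: int = 0):
    """Instantiate a classifier with its library-default hyperparameters."""
    return _CLASSIFIER_BUILDERS[ClassifierId(classifier_id)](seed)


def classifier_manifest(classifier_id: ClassifierId, seed: int = 0) -> dict:
    """The exact hyperparameters an evaluation will use (audit record)."""
    clf = make_classifier(classifier_id, seed)
    return {k: repr(v) for k, v in sorted(clf.get_params().items())}


class EvaluationError(RuntimeError):
    """Classifier or fold failure during objective evaluation."""

    def __init__(self, message: str, fold: int | None = None):
        super().__init__(message if fold is None else f"fold {fold}: {message}")
        self.fold = fold


def evaluate_subset(
    mask,
    X,
    y,
    cfg: ObjectiveConfig,
) -> FitnessRecord:
    """Score one feature mask by balanced cross-validated training.

    ``X`` is a samples x features array (or DataFrame), ``y`` a binary
    label vector with the minority class coded 1.  Deterministic for a
    fixed ``cfg.seed``: the fold split derives from the master seed and
    each fold's undersampling from (master seed, fold index).
    """
    mask = np.asarray(mask).astype(int)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    if mask.shape != (X.shape[1],):
        raise ValueError("mask length must equal the feature count")
    n_selected = tfs(mask)
    tnf = mask.size
    if n_selected == 0:
        return FitnessRecord(fitness=1.0, tfs=0, metrics=None,
                             objective_id=cfg.objective_id, alpha=cfg.alpha,
                             tnf=tnf)

    Xm = X[:, mask == 1]
    ss = np.random.SeedSequence(cfg.seed)
    fold_seed, us_seed = (int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2))
    folds = kfold_indices(len(y), cfg.k_folds, fold_seed)
    all_idx = np.arange(len(y))

    fold_metrics: list[dict] = []
    for fold_i, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(all_idx, test_idx, assume_unique=False)
        y_train = y[train_idx]
        if len(np.unique(y_train)) < 2:
            raise EvaluationError("single-class training fold", fold_i)
        kept = random_undersample(
            y_train, cfg.sampling_ratio, seed=us_seed + fold_i)
        bal_idx = train_idx[kept]
        y_bal = y[bal_idx]
        if len(np.unique(y_bal)) < 2:
            raise EvaluationError(
                "single-class training fold after undersampling", fold_i)
        X_tr, X_te = minmax_fit_transform(Xm[bal_idx], Xm[test_idx])
        try:
            clf = make_classifier(cfg.classifier_id, cfg.seed)
            clf.fit(X_tr, y_bal)
            y_pred = np.asarray(clf.predict(X_te)).astype(int)
        except Exception as exc:  # noqa: BLE001 - carries fold context
            raise EvaluationError(str(exc), fold_i) from exc
        counts = ConfusionCounts.from_labels(y[test_idx], y_pred, positive=1)
        fold_metrics.append(metric_bundle(counts))

    avg = {name: float(np.mean([m[name] for m in fold_metrics]))
           for name in METRIC_NAMES}
    recall = avg["r_m"] if cfg.objective_id is ObjectiveId.OF1 else avg["r_min"]
    fit = weighted_fitness(cfg.objective_id, cfg.alpha, recall,
                           n_selected, tnf)
    return FitnessRecord(fitness=fit, tfs=n_selected, metrics=avg,
                         objective_id=cfg.objective_id, alpha=cfg.alpha,
                         tnf=tnf)


class SubsetObjective:
    """Callable mask -> FitnessRecord with mask-level memoization.

    Wrapper evaluation is by far the dominant cost of a search run, and
    population algorithms revisit masks often once they start converging,
    so identical masks are looked up instead of re-trained.
    """

    def __init__(self, X, y, cfg: ObjectiveConfig):
        self.X = np.asarray(X, dtype=float)
        self.y = np.asarray(y).astype(int)
        if len(np.unique(self.y)) < 2:
            raise ValueError("both classes must be present")
        if self.X.shape[1] < 2:
            raise ValueError("need at least 2 features")
        self.cfg = cfg
        self._cache: dict[bytes, FitnessRecord] = {}
        self.n_evaluations = 0  # classifier-backed (non-cached) evaluations

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def __call__(self, mask) -> FitnessRecord:
        key = np.asarray(mask).astype(np.int8).tobytes()
        rec = self._cache.get(key)
        if rec is None:
            rec = evaluate_subset(mask, self.X, self.y, self.cfg)
            self._cache[key] = rec
            self.n_evaluations += 1
        return rec
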