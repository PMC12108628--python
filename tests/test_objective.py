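"""Wrapper objective: fitness formula, folds, balancing, scaling, evaluation."""

import numpy as np
import pytest

import metafs.objective as obj_mod
from metafs.objective import (
    ClassifierId,
    ObjectiveConfig,
    ObjectiveId,
    SubsetObjective,
    evaluate_subset,
    kfold_indices,
    minmax_fit_transform,
    random_undersample,
    weighted_fitness,
)


@pytest.mark.parametrize("oid,alpha,recall,nsf,tnf,expected", [
    (ObjectiveId.OF1, 0.99, 1.0, 87, 87, 0.01),
    (ObjectiveId.OF2, 0.99, 0.0, 87, 87, 1.0),
    (ObjectiveId.OF1, 0.99, 0.755, 44, 87, 0.247607),
])
def test_weighted_fitness_arithmetic(oid, alpha, recall, nsf, tnf, expected):
    assert weighted_fitness(oid, alpha, recall, nsf, tnf) == pytest.approx(
        expected, abs=1e-6)


def test_weighted_fitness_identity_on_random_triples():
    rng = np.random.default_rng(17)
    for _ in range(1000):
        alpha = rng.random()
        recall = rng.random()
        tnf = int(rng.integers(1, 200))
        nsf = int(rng.integers(1, tnf + 1))
        oid = ObjectiveId.OF1 if rng.random() < 0.5 else ObjectiveId.OF2
        got = weighted_fitness(oid, alpha, recall, nsf, tnf)
        assert got == pytest.approx(
            alpha * (1 - recall) + (1 - alpha) * nsf / tnf, abs=1e-12)


def test_weighted_fitness_rejects_empty_mask():
    with pytest.raises(ValueError):
        weighted_fitness(ObjectiveId.OF1, 0.99, 0.5, 0, 87)


def test_kfold_partition_properties():
    folds = kfold_indices(10, 5, seed=3)
    assert sorted(len(f) for f in folds) == [2] * 5
    folds = kfold_indices(11, 5, seed=3)
    assert sorted(len(f) for f in folds) == [2, 2, 2, 2, 3]
    flat = np.concatenate(folds)
    assert len(flat) == len(set(flat.tolist())) == 11
    assert set(flat.tolist()) == set(range(11))
    with pytest.raises(ValueError):
        kfold_indices(4, 5, seed=0)


def test_random_undersample_counting():
    labels = np.r_[np.zeros(10, dtype=int), np.ones(4, dtype=int)]
    kept = random_undersample(labels, 1.0, seed=0)
    assert len(kept) == 8
    assert (labels[kept] == 1).sum() == 4
    kept = random_undersample(labels, 0.5, seed=0)
    assert len(kept) == 12
    assert (labels[kept] == 0).sum() == 8


def test_random_undersample_minority_always_kept():
    rng = np.random.default_rng(5)
    for _ in range(20):
        labels = (rng.random(60) < 0.3).astype(int)
        if labels.sum() in (0, 60):
            continue
        minority = 1 if labels.sum() <= 30 else 0
        kept = random_undersample(labels, 1.0, seed=11)
        assert set(np.flatnonzero(labels == minority)) <= set(kept.tolist())
        assert np.array_equal(kept, np.sort(kept))


def test_random_undersample_noop_when_already_balanced():
    labels = np.r_[np.zeros(5, dtype=int), np.ones(4, dtype=int)]
    with pytest.warns(UserWarning):
        kept = random_undersample(labels, 0.5, seed=0)
    assert np.array_equal(kept, np.arange(9))


def test_minmax_scaling_conventions():
    train = np.array([[2.0, 5.0], [4.0, 5.0], [6.0, 5.0]])
    test = np.array([[8.0, 7.0]])
    tr, te = minmax_fit_transform(train, test)
    assert tr[:, 0].tolist() == [0.0, 0.5, 1.0]
    assert te[0, 0] == pytest.approx(1.5)  # outside train range, no clipping
    assert not tr[:, 1].any() and not te[:, 1].any()  # constant column -> 0
    with pytest.raises(ValueError):
        minmax_fit_transform(np.empty((0, 2)), test)


def test_empty_mask_is_infeasible(separable_dataset, knn_objective_cfg):
    X, y = separable_dataset
    rec = evaluate_subset(np.zeros(X.shape[1], dtype=int), X, y,
                          knn_objective_cfg)
    assert rec.fitness == 1.0
    assert rec.metrics is None
    assert not rec.feasible


def test_separable_dataset_reaches_full_recall(separable_dataset,
                                               knn_objective_cfg):
    X, y = separable_dataset
    rec = evaluate_subset(np.ones(X.shape[1], dtype=int), X, y,
                          knn_objective_cfg)
    assert rec.metrics["r_m"] > 0.99
    # full mask: feature-count term contributes exactly 1 - alpha
    assert rec.fitness == pytest.approx(
        0.99 * (1 - rec.metrics["r_m"]) + 0.01, abs=1e-12)
    assert rec.fitness < 0.02


def test_record_fitness_reproducible_from_fields(separable_dataset):
    X, y = separable_dataset
    for oid, key in ((ObjectiveId.OF1, "r_m"), (ObjectiveId.OF2, "r_min")):
        cfg = ObjectiveConfig(objective_id=oid,
                              classifier_id=ClassifierId.KNN, seed=3)
        rec = evaluate_subset(np.array([1, 0, 1]), X, y, cfg)
        expected = (rec.alpha * (1 - rec.metrics[key])
                    + (1 - rec.alpha) * rec.tfs / rec.tnf)
        assert rec.fitness == pytest.approx(expected, abs=1e-12)


def test_evaluation_deterministic(separable_dataset, knn_objective_cfg):
    X, y = separable_dataset
    mask = np.array([1, 1, 0])
    a = evaluate_subset(mask, X, y, knn_objective_cfg)
    b = evaluate_subset(mask, X, y, knn_objective_cfg)
    assert a.fitness == b.fitness
    assert a.metrics == b.metrics


def test_objectives_coincide_on_perfect_recall(separable_dataset):
    X, y = separable_dataset
    mask = np.ones(X.shape[1], dtype=int)
    recs = [evaluate_subset(mask, X, y, ObjectiveConfig(
        objective_id=oid, classifier_id=ClassifierId.KNN, seed=5))
        for oid in (ObjectiveId.OF1, ObjectiveId.OF2)]
    # symmetric errors: both recalls 1, so OF1 and OF2 agree exactly
    assert recs[0].metrics["r_m"] == recs[1].metrics["r_min"] == 1.0
    assert recs[0].fitness == recs[1].fitness


def test_test_folds_never_resampled_or_fit(separable_dataset,
                                           knn_objective_cfg, monkeypatch):
    """Instrumented fold accounting: undersampling sees only training folds
    and the scaler is fitted on the balanced training fold only."""
    X, y = separable_dataset
    n = len(y)
    k = knn_objective_cfg.k_folds
    undersample_sizes = []
    scaler_calls = []

    orig_us = obj_mod.random_undersample
    orig_mm = obj_mod.minmax_fit_transform

    def spy_us(labels, ratio, seed):
        undersample_sizes.append(len(labels))
        return orig_us(labels, ratio, seed)

    def spy_mm(train, test):
        scaler_calls.append((len(train), len(test)))
        return orig_mm(train, test)

    monkeypatch.setattr(obj_mod, "random_undersample", spy_us)
    monkeypatch.setattr(obj_mod, "minmax_fit_transform", spy_mm)
    evaluate_subset(np.ones(X.shape[1], dtype=int), X, y, knn_objective_cfg)

    assert len(undersample_sizes) == k
    fold_sizes = [n - s for s in undersample_sizes]  # implied test-fold sizes
    assert sum(fold_sizes) == n
    assert max(fold_sizes) - min(fold_sizes) <= 1
    assert len(scaler_calls) == k
    for (n_train, n_test), n_fold in zip(scaler_calls, fold_sizes):
        assert n_test == n_fold          # test fold passes through untouched
        assert n_train <= n - n_fold     # balanced train is a subsample


def test_cached_objective_counts_unique_masks(separable_dataset,
                                              knn_objective_cfg):
    X, y = separable_dataset
    objective = SubsetObjective(X, y, knn_objective_cfg)
    mask = np.array([1, 0, 1])
    a = objective(mask)
    b = objective(mask.copy())
    assert objective.n_evaluations == 1
    assert a is b
    objective(np.array([0, 1, 1]))
    assert objective.n_evaluations == 2
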