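import itertools

import numpy as np
import pytest

from admetnet.preprocess import build_assay_matrix
from admetnet.splits import (SplitPlan, check_coverage, cluster_split,
                             random_split_matched, time_split)


def exhaustive_two_means(points):
    """Oracle: the bipartition minimizing within-cluster sum of squares."""
    n = len(points)
    best, best_cost = None, np.inf
    for assignment in itertools.product([0, 1], repeat=n):
        labels = np.array(assignment)
        if labels.min() == labels.max():
            continue
        cost = sum(((points[labels == c] - points[labels == c].mean(axis=0)) ** 2).sum()
                   for c in (0, 1))
        if cost < best_cost:
            best, best_cost = labels, cost
    return best


def test_two_blob_recovery_matches_exhaustive_oracle():
    rng = np.random.default_rng(0)
    blob_a = rng.normal(0.0, 0.5, size=(6, 3))
    blob_b = rng.normal(40.0, 0.5, size=(6, 3))
    points = np.vstack([blob_a, blob_b])
    mask = np.ones((12, 1), bool)
    plan = cluster_split(points, mask, [f"c{i}" for i in range(12)], K=2, seed=0)
    oracle = exhaustive_two_means(points)
    got = plan.fold_of_compound
    same = (got == got[0]) == (oracle == oracle[0])
    assert same.all()


def test_cluster_split_partition_and_coverage(tiny_matrix, tiny_fps):
    matrix, _ = tiny_matrix
    plan = cluster_split(tiny_fps, matrix.mask, matrix.compound_ids, K=4, seed=1)
    assert plan.fold_of_compound.shape == (matrix.n_compounds,)
    assert check_coverage(plan.fold_of_compound, matrix.mask)
    # deterministic given (fingerprints, K, seed)
    again = cluster_split(tiny_fps, matrix.mask, matrix.compound_ids, K=4, seed=1)
    assert (plan.fold_of_compound == again.fold_of_compound).all()


def test_cluster_split_test_fold_designation(tiny_matrix, tiny_fps):
    matrix, _ = tiny_matrix
    plan = cluster_split(tiny_fps, matrix.mask, matrix.compound_ids, K=4, seed=1,
                         test_fold=0)
    assert (plan.fold_of_compound == -1).any()
    assert check_coverage(plan.fold_of_compound, matrix.mask)


def test_cluster_split_rejects_unsplittable_task(tiny_fps, tiny_matrix):
    matrix, _ = tiny_matrix
    mask = matrix.mask.copy()
    mask[:, 0] = False
    mask[0, 0] = True  # a task with a single labeled compound
    with pytest.raises(ValueError):
        cluster_split(tiny_fps, mask, matrix.compound_ids, K=4, seed=0)


def test_matched_random_preserves_sizes_and_coverage(tiny_matrix, tiny_fps):
    matrix, _ = tiny_matrix
    plan = cluster_split(tiny_fps, matrix.mask, matrix.compound_ids, K=4, seed=1)
    rand = random_split_matched(plan, matrix.mask, seed=3)
    assert sorted(rand.fold_sizes().values()) == sorted(plan.fold_sizes().values())
    assert check_coverage(rand.fold_of_compound, matrix.mask)
    other = random_split_matched(plan, matrix.mask, seed=4)
    assert not (rand.fold_of_compound == other.fold_of_compound).all()
    assert sorted(other.fold_sizes().values()) == sorted(plan.fold_sizes().values())


def test_plan_serialization_round_trip(tmp_path, tiny_matrix, tiny_fps):
    matrix, _ = tiny_matrix
    plan = cluster_split(tiny_fps, matrix.mask, matrix.compound_ids, K=3, seed=0,
                         test_fold=1)
    path = tmp_path / "plan.tsv"
    plan.save(path)
    loaded = SplitPlan.load(path)
    assert loaded.strategy == plan.strategy
    assert loaded.compound_ids == plan.compound_ids
    assert (loaded.fold_of_compound == plan.fold_of_compound).all()


def test_time_split_taskwise_and_strict(tiny_matrix):
    matrix, _ = tiny_matrix
    taskwise = time_split(matrix, "2014-06-30", strict=False)
    strict = time_split(matrix, "2014-06-30", strict=True)
    for plan in (taskwise, strict):
        assert not (plan.train_mask & plan.test_mask).any()
        assert (plan.train_mask | plan.test_mask).sum() <= matrix.mask.sum()
    # strict: no compound is both train (any task) and test (any task)
    assert not (strict.train_mask.any(1) & strict.test_mask.any(1)).any()
    # taskwise keeps at least as many training cells as strict
    assert taskwise.train_mask.sum() >= strict.train_mask.sum()
    # the undated task (LOA) is split randomly at the same overall fraction
    t_loa = matrix.endpoint_codes.index("LOA")
    assert taskwise.test_mask[:, t_loa].sum() > 0


def test_taskwise_allows_cross_task_overlap(tiny_matrix):
    matrix, _ = tiny_matrix
    plan = time_split(matrix, "2014-06-30", strict=False)
    overlap = (plan.train_mask.any(1) & plan.test_mask.any(1)).sum()
    assert overlap > 0  # replicate-rich panel: overlap expected


def test_time_split_serialization_round_trip(tmp_path, tiny_matrix):
    matrix, _ = tiny_matrix
    plan = time_split(matrix, "2014-06-30", strict=True)
    path = tmp_path / "plan.tsv"
    plan.save(path)
    loaded = SplitPlan.load(path, n_tasks=matrix.n_tasks)
    # compounds without any assigned cell are absent from the file
    keep = (plan.train_mask | plan.test_mask).any(1)
    idx = [plan.compound_ids.index(c) for c in loaded.compound_ids]
    assert (loaded.train_mask == plan.train_mask[idx]).all()
    assert (loaded.test_mask == plan.test_mask[idx]).all()


def test_time_split_degenerate_cutoffs(tiny_matrix):
    matrix, _ = tiny_matrix
    with pytest.raises(ValueError):
        time_split(matrix, "2030-01-01")
    with pytest.raises(ValueError):
        time_split(matrix, "1990-01-01")
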