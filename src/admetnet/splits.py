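"""Train/test splitting strategies for multitask assay matrices.

Three families are provided:

- *leave-cluster-out*: compounds are clustered in fingerprint space by
  k-means (K = 10 by default); clusters that do not contain compounds of
  every task are merged into larger clusters; the resulting clusters are
  the cross-validation folds (optionally with one designated test fold).
  Test compounds then lie in chemical space unseen during training.
- *matched random*: a random partition with exactly the same fold sizes as
  a given cluster plan, repaired so every fold covers every task.
- *time splits*: per-task-cell assignment by measurement date against a
  cutoff.  The *taskwise* variant lets a compound be train in one task and
  test in another; the *strict* variant removes from all training sets any
  compound appearing in any task's test set.  Tasks without dates are
  split randomly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .preprocess import AssayMatrix

__all__ = ["SplitPlan", "cluster_split", "random_split_matched", "time_split",
           "check_coverage"]

TEST_FOLD = -1


@dataclass
class SplitPlan:
    """Fold/test assignment of compounds (or of task cells for time splits).

    For ``cluster`` and ``random`` strategies ``fold_of_compound`` holds a
    fold index per compound, with −1 marking the designated test set.  For
    time splits the assignment is per task cell: ``test_mask`` /
    ``train_mask`` are boolean (n, T) matrices over labeled cells.
    """

    strategy: str
    compound_ids: list[str]
    fold_of_compound: np.ndarray | None = None
    train_mask: np.ndarray | None = None
    test_mask: np.ndarray | None = None
    K: int | None = None
    cutoff_date: np.datetime64 | None = None

    @property
    def folds(self) -> np.ndarray:
        """Sorted fold labels, excluding the test marker."""
        f = np.unique(self.fold_of_compound)
        return f[f != TEST_FOLD]

    def fold_sizes(self) -> dict[int, int]:
        labels, counts = np.unique(self.fold_of_compound, return_counts=True)
        return dict(zip(labels.tolist(), counts.tolist()))

    def cv_masks(self, mask: np.ndarray):
        """Yield (fold, train_mask, val_mask) cell masks for each CV fold."""
        for f in self.folds:
            val_rows = self.fold_of_compound == f
            train_rows = (self.fold_of_compound != f) & (self.fold_of_compound != TEST_FOLD)
            yield int(f), mask & train_rows[:, None], mask & val_rows[:, None]

    def holdout_masks(self, mask: np.ndarray):
        """(train, test) cell masks for the designated test set / time split."""
        if self.fold_of_compound is not None:
            test_rows = self.fold_of_compound == TEST_FOLD
            if not test_rows.any():
                raise ValueError("plan has no designated test fold")
            return mask & ~test_rows[:, None], mask & test_rows[:, None]
        return self.train_mask.copy(), self.test_mask.copy()

    # -- serialization ----------------------------------------------------
    def save(self, path) -> None:
        if self.fold_of_compound is not None:
            df = pd.DataFrame({"compound_id": self.compound_ids,
                               "fold": self.fold_of_compound})
        else:
            rows = []
            for i, cid in enumerate(self.compound_ids):
                for t in range(self.train_mask.shape[1]):
                    if self.train_mask[i, t]:
                        rows.append((cid, t, "train"))
                    elif self.test_mask[i, t]:
                        rows.append((cid, t, "test"))
            df = pd.DataFrame(rows, columns=["compound_id", "task", "set"])
        with open(path, "w") as fh:
            fh.write(f"# strategy={self.strategy} K={self.K} cutoff={self.cutoff_date}\n")
            df.to_csv(fh, sep="\t", index=False)

    @classmethod
    def load(cls, path, n_tasks: int | None = None) -> "SplitPlan":
        with open(path) as fh:
            header = fh.readline().strip().lstrip("# ")
            meta = dict(kv.split("=", 1) for kv in header.split())
            df = pd.read_csv(fh, sep="\t")
        strategy = meta["strategy"]
        K = None if meta.get("K") in (None, "None") else int(meta["K"])
        cutoff = None if meta.get("cutoff") in (None, "None") else np.datetime64(meta["cutoff"])
        if "fold" in df.columns:
            return cls(strategy=strategy, compound_ids=df["compound_id"].astype(str).tolist(),
                       fold_of_compound=df["fold"].to_numpy(), K=K, cutoff_date=cutoff)
        ids = list(dict.fromkeys(df["compound_id"].astype(str)))
        row_of = {c: i for i, c in enumerate(ids)}
        T = n_tasks if n_tasks is not None else int(df["task"].max()) + 1
        train = np.zeros((len(ids), T), bool)
        test = np.zeros((len(ids), T), bool)
        for cid, task, which in df.itertuples(index=False):
            (train if which == "train" else test)[row_of[str(cid)], int(task)] = True
        return cls(strategy=strategy, compound_ids=ids, train_mask=train,
                   test_mask=test, K=K, cutoff_date=cutoff)


def check_coverage(fold_of_compound: np.ndarray, mask: np.ndarray) -> bool:
    """True when every fold (incl. test) has ≥1 labeled compound per task."""
    for f in np.unique(fold_of_compound):
        if not mask[fold_of_compound == f].any(axis=0).all():
            return False
    return True


def cluster_split(fingerprints: np.ndarray, mask: np.ndarray, compound_ids: list[str],
                  K: int = 10, seed: int = 0, test_fold: int | None = None) -> SplitPlan:
    """Leave-cluster-out split: k-means on count fingerprints, then merge
    clusters missing a task into their nearest larger cluster.

    ``test_fold`` (index after merging/relabeling) marks one fold as the
    held-out test set (−1 in the plan).
    """
    X = np.asarray(fingerprints, dtype=np.float64)
    n = X.shape[0]
    if n < K:
        raise ValueError(f"need at least K={K} compounds, got {n}")
    if np.any(mask.sum(axis=0) < 2):
        raise ValueError("every task needs at least 2 labeled compounds to split")
    labels = KMeans(n_clusters=K, random_state=seed, n_init=4).fit_predict(X)

    # merge clusters that do not contain every task into larger clusters
    while True:
        ids = np.unique(labels)
        if len(ids) <= 1:
            break
        sizes = {c: int((labels == c).sum()) for c in ids}
        centroids = {c: X[labels == c].mean(axis=0) for c in ids}
        deficient = [c for c in ids if not mask[labels == c].any(axis=0).all()]
        if not deficient:
            break
        c = min(deficient, key=lambda c: sizes[c])  # smallest first
        larger = [d for d in ids if d != c and sizes[d] > sizes[c]]
        candidates = larger if larger else [d for d in ids if d != c]
        target = min(candidates,
                     key=lambda d: float(np.linalg.norm(centroids[d] - centroids[c])))
        labels[labels == c] = target

    if not mask[labels == labels[0]].any(axis=0).all() and len(np.unique(labels)) == 1:
        raise ValueError("task coverage infeasible: some task too small to split")
    # relabel 0..F-1 in decreasing size order for stable fold numbering
    ids, counts = np.unique(labels, return_counts=True)
    relabel = {c: r for r, c in enumerate(ids[np.argsort(-counts, kind="stable")])}
    folds = np.array([relabel[c] for c in labels])
    if test_fold is not None:
        if test_fold not in relabel.values():
            raise ValueError(f"test_fold {test_fold} not among folds")
        folds = np.where(folds == test_fold, TEST_FOLD,
                         np.where(folds > test_fold, folds - 1, folds))
    plan = SplitPlan(strategy="cluster", compound_ids=list(compound_ids),
                     fold_of_compound=folds, K=K)
    if not check_coverage(folds, mask):
        raise ValueError("task coverage infeasible after merging")
    return plan


def random_split_matched(plan: SplitPlan, mask: np.ndarray, seed: int = 0,
                         max_repair_passes: int = 1000) -> SplitPlan:
    """Random partition with the same fold sizes as a cluster plan.

    After the random permutation, a repair pass swaps compounds between
    folds until every fold contains at least one labeled compound of every
    task (keeping all fold sizes unchanged).
    """
    if plan.fold_of_compound is None:
        raise ValueError("matched random split requires a fold-based plan")
    rng = np.random.default_rng(seed)
    template = plan.fold_of_compound
    folds = template.copy()
    rng.shuffle(folds)

    for _ in range(max_repair_passes):
        deficits = []
        for f in np.unique(folds):
            covered = mask[folds == f].any(axis=0)
            deficits.extend((f, t) for t in np.flatnonzero(~covered))
        if not deficits:
            break
        f, t = deficits[0]
        donors = np.flatnonzero(mask[:, t] & (folds != f))
        # prefer donor folds that keep coverage of task t after the swap
        donor_ok = [i for i in donors if mask[(folds == folds[i]), t].sum() >= 2]
        if not donor_ok:
            raise ValueError("task coverage infeasible for matched random split")
        donor = int(rng.choice(donor_ok))
        receivers = np.flatnonzero(folds == f)
        swap = int(rng.choice(receivers))
        folds[donor], folds[swap] = folds[swap], folds[donor]
    else:
        raise ValueError("could not repair task coverage within pass limit")
    return SplitPlan(strategy="random", compound_ids=list(plan.compound_ids),
                     fold_of_compound=folds, K=plan.K)


def time_split(matrix: AssayMatrix, cutoff, strict: bool = False,
               seed: int = 0) -> SplitPlan:
    """Temporal split: cells dated after ``cutoff`` are test, earlier train.

    Tasks with no dated cells are split randomly with the same overall test
    fraction.  With ``strict=True`` any compound occurring in some task's
    test set is removed from every task's training set.
    """
    cutoff = np.datetime64(cutoff, "D")
    mask = matrix.mask
    dates = matrix.dates
    has_date = ~np.isnat(dates)
    dated_tasks = (mask & has_date).any(axis=0)

    test = np.zeros_like(mask)
    test[mask & has_date] = dates[mask & has_date] > cutoff
    n_dated = int((mask & has_date).sum())
    if n_dated == 0:
        raise ValueError("no dated cells; time split impossible")
    test_fraction = float(test.sum()) / n_dated
    if test_fraction == 0.0:
        raise ValueError("cutoff after all measurement dates: empty test set")
    if test[mask & has_date].all():
        raise ValueError("cutoff before all measurement dates: empty training set")

    rng = np.random.default_rng(seed)
    for t in np.flatnonzero(~dated_tasks):
        rows = np.flatnonzero(mask[:, t])
        n_test = int(round(test_fraction * rows.size))
        test[rng.choice(rows, size=n_test, replace=False), t] = True

    train = mask & ~test
    if strict:
        test_compounds = test.any(axis=1)
        train[test_compounds] = False
    return SplitPlan(strategy="time_strict" if strict else "time_taskwise",
                     compound_ids=list(matrix.compound_ids),
                     train_mask=train, test_mask=test, cutoff_date=cutoff)
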