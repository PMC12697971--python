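"""Fitness of binary feature masks: cross-validated SVM-RBF accuracy.

A mask's fitness is the mean k-fold accuracy of an RBF-kernel SVM on the
masked matrix, with (C, gamma) chosen by grid search. Two protocols exist:

* flat (default): one seeded stratified split per run; grid search maximizes
  mean fold accuracy directly, matching how wrapper searches are usually
  scored on these benchmarks;
* nested: an outer split for assessment with grid search *and* min-max
  normalization refit inside every outer training fold, so no test-fold
  statistic leaks into model choice.

Fitness comparison is lexicographic: accuracy first, then shorter subsets,
then the smaller lowest feature index — a deterministic total order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.svm import SVC

from .datasets import ExpressionDataset, stratified_folds


class EvaluationError(ValueError):
    pass


def _default_c_grid() -> list[float]:
    return [2.0**k for k in (-2, 0, 2, 4, 6, 8)]


def _default_gamma_grid() -> list[float]:
    return [2.0**k for k in (-8, -6, -4, -2, 0, 2)]


@dataclass
class CVConfig:
    """Cross-validation and SVM grid-search settings."""

    k: int = 10
    nested: bool = False
    c_grid: list[float] = field(default_factory=_default_c_grid)
    gamma_grid: list[float] = field(default_factory=_default_gamma_grid)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 2:
            raise EvaluationError("k must be >= 2")
        if not self.c_grid or not self.gamma_grid:
            raise EvaluationError("grids must be non-empty")


@dataclass
class FitnessResult:
    """Accuracy and subset-length record for one evaluated mask."""

    acc_mean: float
    fold_accs: list[float]
    subset_length: int
    feature_indices: tuple[int, ...]
    chosen_c: float
    chosen_gamma: float

    def __post_init__(self) -> None:
        if abs(self.acc_mean - float(np.mean(self.fold_accs))) > 1e-12:
            raise EvaluationError("acc_mean must equal the mean of fold_accs")
        if self.subset_length != len(self.feature_indices) or self.subset_length < 1:
            raise EvaluationError("subset_length must equal |feature_indices| >= 1")


def compare_fitness(a: FitnessResult, b: FitnessResult) -> int:
    """-1 if ``a`` is better, +1 if ``b`` is better, 0 if fully tied.

    Higher accuracy wins; exact accuracy ties go to the shorter subset;
    remaining ties go to the lexicographically smaller sorted index tuple
    (so the smaller lowest feature index wins first), making this a total
    order over distinct subsets.
    """
    if a.acc_mean != b.acc_mean:
        return -1 if a.acc_mean > b.acc_mean else 1
    if a.subset_length != b.subset_length:
        return -1 if a.subset_length < b.subset_length else 1
    ta, tb = tuple(sorted(a.feature_indices)), tuple(sorted(b.feature_indices))
    if ta != tb:
        return -1 if ta < tb else 1
    return 0


def _mask_to_indices(mask) -> tuple[int, ...]:
    """Boolean vectors are masks; anything else is a feature-index collection."""
    arr = np.asarray(mask)
    if arr.dtype == bool:
        idx = np.flatnonzero(arr)
    else:
        idx = np.asarray(arr, dtype=int)
    return tuple(sorted(int(j) for j in idx))


def _grid_search_cv(X, ylab, folds, c_grid, gamma_grid):
    """Mean-fold-accuracy grid search; returns (best_accs, best_c, best_gamma).

    Ties resolve to the earliest grid entry (smaller C, then smaller gamma),
    keeping the search deterministic.
    """
    best = None
    for c in c_grid:
        for g in gamma_grid:
            accs = []
            for tr, te in folds:
                clf = SVC(C=c, gamma=g, kernel="rbf")
                clf.fit(X[tr], ylab[tr])
                accs.append(float(np.mean(clf.predict(X[te]) == ylab[te])))
            mean_acc = float(np.mean(accs))
            if best is None or mean_acc > best[0]:
                best = (mean_acc, accs, c, g)
    return best[1], best[2], best[3]


class FitnessEvaluator:
    """Evaluates masks against one dataset, caching by feature-index tuple.

    The fold split is drawn once per evaluator from ``cfg.seed``, so every
    mask in a run is scored against the same partition.
    """

    def __init__(self, ds: ExpressionDataset, cfg: CVConfig):
        self.ds = ds
        self.cfg = cfg
        self.folds = stratified_folds(ds, cfg.k, cfg.seed)
        self._cache: dict[tuple[int, ...], FitnessResult] = {}
        self.n_evaluations = 0  # cache misses, i.e. actual CV runs

    def evaluate(self, mask) -> FitnessResult:
        idx = _mask_to_indices(mask)
        if not idx:
            raise EvaluationError("mask selects no features")
        hit = self._cache.get(idx)
        if hit is not None:
            return hit
        res = evaluate_fitness(self.ds, idx, self.cfg, folds=self.folds)
        self._cache[idx] = res
        self.n_evaluations += 1
        return res


def evaluate_fitness(
    ds: ExpressionDataset,
    mask,
    cfg: CVConfig,
    folds=None,
    _trace: list | None = None,
) -> FitnessResult:
    """Score a feature mask by cross-validated SVM-RBF accuracy.

    ``mask`` is a binary vector over the dataset's features or an index tuple.
    ``_trace``, when given, records ("fit"/"transform", fold, split) events of
    the nested protocol's per-fold normalization for leakage auditing.
    """
    idx = _mask_to_indices(mask)
    if not idx:
        raise EvaluationError("mask selects no features")
    X = ds.matrix[:, list(idx)]
    ylab = ds.labels
    if folds is None:
        folds = stratified_folds(ds, cfg.k, cfg.seed)

    if not cfg.nested:
        accs, c, g = _grid_search_cv(X, ylab, folds, cfg.c_grid, cfg.gamma_grid)
        return FitnessResult(
            acc_mean=float(np.mean(accs)),
            fold_accs=accs,
            subset_length=len(idx),
            feature_indices=idx,
            chosen_c=c,
            chosen_gamma=g,
        )

    # nested: per outer fold, refit normalization and grid-search on the
    # training part only, assess once on the held-out part
    outer_accs = []
    last_c, last_g = cfg.c_grid[0], cfg.gamma_grid[0]
    for fold_no, (tr, te) in enumerate(folds):
        lo = X[tr].min(axis=0)
        hi = X[tr].max(axis=0)
        span = np.where(hi > lo, hi - lo, 1.0)
        if _trace is not None:
            _trace.append(("fit", fold_no, "train"))
        Xtr = (X[tr] - lo) / span
        Xte = np.clip((X[te] - lo) / span, 0.0, 1.0)
        if _trace is not None:
            _trace.append(("transform", fold_no, "train"))
            _trace.append(("transform", fold_no, "test"))
        # inner split over the training part only
        inner = ExpressionDataset(
            Xtr, ylab[tr], [f"f{j}" for j in range(Xtr.shape[1])], [str(i) for i in tr]
        )
        inner_k = min(cfg.k, int(np.bincount(ylab[tr]).min()))
        inner_folds = stratified_folds(inner, max(inner_k, 2), cfg.seed)
        _, c, g = _grid_search_cv(Xtr, ylab[tr], inner_folds, cfg.c_grid, cfg.gamma_grid)
        clf = SVC(C=c, gamma=g, kernel="rbf")
        clf.fit(Xtr, ylab[tr])
        outer_accs.append(float(np.mean(clf.predict(Xte) == ylab[te])))
        last_c, last_g = c, g
    return FitnessResult(
        acc_mean=float(np.mean(outer_accs)),
        fold_accs=outer_accs,
        subset_length=len(idx),
        feature_indices=idx,
        chosen_c=last_c,
        chosen_gamma=last_g,
    )
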