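"""Filter-stage scoring: RF importance pre-screening and the mSMMI bivariate filter.

Two scoring conventions coexist deliberately. Entropy and information gain
(used to describe the tree-ensemble screening criterion) are in bits, while
the plug-in mutual information used by the bivariate filter is in nats with
each distinct value treated as its own category — the convention under which
the reference worked examples (MI = 1.609 = ln 5, MI = 0.673) hold exactly.
Spearman redundancy uses average ranks for ties plugged into the classical
1 - 6*sum(d^2)/(n(n^2-1)) formula without a tie-correction term.

The greedy mSMMI selection trades relevance against redundancy with
iteration-dependent weights s = cos((i/I)*pi/2) and y = sin((i/I)*pi/2):
early restarts favour label relevance, late restarts favour diversity.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier

from .datasets import ExpressionDataset


class FilterError(ValueError):
    """Raised on malformed filter inputs."""


class ScoreKind(str, Enum):
    RF_IMPORTANCE = "rf_importance"
    MUTUAL_INFORMATION = "mutual_information"
    MSMMI = "msmmi"


@dataclass
class ScoredFeatureList:
    """Ordered (feature_index, score) pairs, best first."""

    entries: list[tuple[int, float]]
    score_kind: ScoreKind

    def __post_init__(self) -> None:
        idx = [i for i, _ in self.entries]
        if len(set(idx)) != len(idx):
            raise FilterError("duplicate feature index in scored list")
        scores = [s for _, s in self.entries]
        if any(a < b for a, b in zip(scores, scores[1:])):
            raise FilterError("entries must be sorted by score, descending")

    @property
    def indices(self) -> list[int]:
        return [i for i, _ in self.entries]

    def to_csv(self, path, feature_ids: Sequence[str]) -> None:
        import csv

        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["feature_id", "score"])
            for i, s in self.entries:
                w.writerow([feature_ids[i], s])


# ---------------------------------------------------------------------------
# entropy / information gain (bits) — the tree-screening criterion
# ---------------------------------------------------------------------------


def entropy(labels: Sequence) -> float:
    """Shannon entropy of a class-code vector, in bits."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise FilterError("entropy of an empty vector is undefined")
    _, counts = np.unique(labels, return_counts=True)
    p = counts / labels.size
    return float(-(p * np.log2(p)).sum())


def information_gain(labels: Sequence, partition: Iterable[Sequence[int]]) -> float:
    """Entropy reduction (bits) of splitting ``labels`` by ``partition``.

    ``partition`` must cover every sample index exactly once.
    """
    labels = np.asarray(labels)
    parts = [np.asarray(p, dtype=int) for p in partition]
    flat = np.concatenate(parts) if parts else np.array([], dtype=int)
    if sorted(flat.tolist()) != list(range(labels.size)):
        raise FilterError("parts do not form a partition of the sample indices")
    h = entropy(labels)
    cond = sum(p.size / labels.size * entropy(labels[p]) for p in parts if p.size)
    return float(h - cond)


def rf_fim_rank(ds: ExpressionDataset, k1: int, seed: int, n_trees: int = 100) -> ScoredFeatureList:
    """Top-``k1`` features by random-forest mean impurity-decrease importance.

    The forest is trained on the full (normalized) matrix with the entropy
    split criterion, so importances are information-gain based. Deterministic
    under ``seed``; ties broken by lowest feature index.
    """
    if not (1 <= k1 <= ds.n_features):
        raise FilterError(f"k1={k1} out of range [1, {ds.n_features}]")
    rf = RandomForestClassifier(
        n_estimators=n_trees, criterion="entropy", random_state=seed % (2**31), n_jobs=1
    )
    rf.fit(ds.matrix, ds.labels)
    imp = rf.feature_importances_
    # stable sort on (-score, index) => descending score, lowest index on ties
    order = np.lexsort((np.arange(imp.size), -imp))[:k1]
    return ScoredFeatureList(
        entries=[(int(j), float(imp[j])) for j in order], score_kind=ScoreKind.RF_IMPORTANCE
    )


# ---------------------------------------------------------------------------
# plug-in mutual information (nats) and Spearman redundancy
# ---------------------------------------------------------------------------


def _discretize(x: np.ndarray, bins: int) -> np.ndarray:
    lo, hi = x.min(), x.max()
    if hi == lo:
        return np.zeros(x.size, dtype=int)
    edges = np.linspace(lo, hi, bins + 1)
    return np.clip(np.digitize(x, edges[1:-1]), 0, bins - 1)


def mutual_information(x: Sequence, y: Sequence, bins: int | None = None) -> float:
    """Plug-in mutual information in nats over the empirical joint distribution.

    Each distinct value is its own category by default; pass ``bins`` to
    equal-width discretize both arguments first (sensible for continuous
    expression values, where every value being unique degenerates the
    distinct-value estimate to log n).
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if x.size != y.size:
        raise FilterError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < 2:
        raise FilterError("need at least 2 observations")
    if bins is not None:
        x = _discretize(x.astype(float), bins)
        y = _discretize(y.astype(float), bins)
    n = x.size
    cxy = Counter(zip(x.tolist(), y.tolist()))
    cx = Counter(x.tolist())
    cy = Counter(y.tolist())
    mi = 0.0
    for (a, b), c in cxy.items():
        pxy = c / n
        mi += pxy * math.log(pxy * n * n / (cx[a] * cy[b]))
    return max(mi, 0.0)


def mmi(
    candidates: Iterable[int], ds: ExpressionDataset, bins: int | None = None
) -> tuple[int, float]:
    """Candidate with maximum MI against the label; ties -> lowest index."""
    cand = sorted(set(candidates))
    if not cand:
        raise FilterError("empty candidate set")
    best_j, best_v = cand[0], -math.inf
    for j in cand:
        v = mutual_information(ds.labels, ds.matrix[:, j], bins=bins)
        if v > best_v:
            best_j, best_v = j, v
    return best_j, best_v


def spearman(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman coefficient: 1 - 6*sum(d^2)/(n(n^2-1)), average ranks for ties.

    The classical no-tie-correction formula is used deliberately; with ties it
    differs from the Pearson-of-ranks estimator.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise FilterError(f"length mismatch: {x.size} vs {y.size}")
    n = x.size
    if n < 2:
        raise FilterError("need at least 2 observations")
    d = rankdata(x) - rankdata(y)
    return float(1.0 - 6.0 * np.sum(d * d) / (n * (n * n - 1)))


def ms1(
    f_known: int, candidates: Iterable[int], ds: ExpressionDataset
) -> tuple[int, float]:
    """Candidate minimizing Spearman correlation with the known feature."""
    cand = sorted(set(candidates))
    if not cand:
        raise FilterError("empty candidate set")
    if f_known in cand:
        raise FilterError("known feature must not be among the candidates")
    best_j, best_v = cand[0], math.inf
    xk = ds.matrix[:, f_known]
    for j in cand:
        v = spearman(xk, ds.matrix[:, j])
        if v < best_v:
            best_j, best_v = j, v
    return best_j, best_v


def ms2(
    selected: Sequence[int], candidates: Iterable[int], ds: ExpressionDataset
) -> tuple[int, float]:
    """Candidate minimizing its minimum Spearman against the selected set."""
    sel = list(selected)
    cand = sorted(set(candidates))
    if not sel or not cand:
        raise FilterError("selected and candidate sets must be non-empty")
    if set(sel) & set(cand):
        raise FilterError("selected and candidate sets overlap")
    best_j, best_v = cand[0], math.inf
    for j in cand:
        xj = ds.matrix[:, j]
        v = min(spearman(xj, ds.matrix[:, p]) for p in sel)
        if v < best_v:
            best_j, best_v = j, v
    return best_j, best_v


# ---------------------------------------------------------------------------
# s/y schedule and feature budget
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SYSchedule:
    """Wrapper-iteration position (i of I) driving the relevance/redundancy weights."""

    i: int
    I: int

    def __post_init__(self) -> None:
        if self.I < 1 or not (0 <= self.i <= self.I):
            raise FilterError(f"invalid schedule position i={self.i}, I={self.I}")

    @property
    def s(self) -> float:
        return math.cos((self.i / self.I) * math.pi / 2)

    @property
    def y(self) -> float:
        return math.sin((self.i / self.I) * math.pi / 2)


def sy_schedule(state: SYSchedule) -> tuple[float, float]:
    """(s, y) weights at the schedule position; s falls 1->0 as y rises 0->1."""
    return state.s, state.y


@dataclass(frozen=True)
class FilterBudget:
    """Parameters of the stochastic feature-count formula.

    The selected count is ``RandnumA + (f*rand()/e) * cos(p*e)`` with ``f``
    features and ``e`` samples; the baseline RandnumA range is multiplied by
    10 for the first-stage (tree-importance) screen. The result is clamped to
    ``[k_min, ceil(k_max_fraction * f)]``.
    """

    randnum_a_low: int = 10
    randnum_a_high: int = 20
    p: float = 0.8
    rand_low: float = 1.0
    rand_high: float = 10.0
    k_min: int = 5
    k_max_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.randnum_a_low >= self.randnum_a_high:
            raise FilterError("randnum_a_low must be < randnum_a_high")
        if self.rand_low >= self.rand_high:
            raise FilterError("rand_low must be < rand_high")
        if self.k_min < 2:
            raise FilterError("k_min must be >= 2")
        if not (0 < self.k_max_fraction <= 1):
            raise FilterError("k_max_fraction must be in (0, 1]")


def feature_budget(
    ds: ExpressionDataset,
    budget: FilterBudget,
    stage: str,
    rng: np.random.Generator,
    available: int | None = None,
) -> int:
    """Draw the number of features the given filter stage should keep.

    ``stage`` is "M1" (tree-importance screen; baseline range x10) or "M2"
    (bivariate filter). ``available`` caps the result below the pool actually
    on offer (defaults to ``ds.n_features``).
    """
    if stage not in {"M1", "M2"}:
        raise FilterError(f"unknown stage {stage!r}")
    scale = 10 if stage == "M1" else 1
    a = rng.uniform(budget.randnum_a_low * scale, budget.randnum_a_high * scale)
    r = rng.uniform(budget.rand_low, budget.rand_high)
    f = ds.n_features
    e = ds.n_samples
    raw = a + (f * r / e) * math.cos(budget.p * e)
    avail = ds.n_features if available is None else available
    k_max = max(budget.k_min, math.ceil(budget.k_max_fraction * avail))
    return int(min(max(round(raw), budget.k_min), k_max))


# ---------------------------------------------------------------------------
# greedy mSMMI selection
# ---------------------------------------------------------------------------


def msmmi_select(
    candidates: Iterable[int],
    ds: ExpressionDataset,
    k2: int,
    schedule: SYSchedule,
    bins: int | None = None,
) -> list[int]:
    """Greedy relevance-minus-redundancy selection of ``k2`` features.

    The first pick maximizes ``s * MI(label, f)``. Each later pick maximizes
    ``s * MI(label, f) - y * redundancy(f)`` where redundancy is the Spearman
    correlation with the first selected feature while only one feature is
    selected, and the minimum Spearman against the whole selected set
    thereafter. Ties break to the lowest feature index. Invariant to the
    ordering of the candidate iterable.
    """
    cand = sorted(set(candidates))
    if k2 > len(cand):
        raise FilterError(f"k2={k2} exceeds candidate pool of {len(cand)}")
    if k2 < 1:
        raise FilterError("k2 must be >= 1")
    s, y = schedule.s, schedule.y
    mi_cache = {
        j: mutual_information(ds.labels, ds.matrix[:, j], bins=bins) for j in cand
    }
    selected: list[int] = []
    remaining = list(cand)
    # min Spearman of each remaining candidate against the selected set,
    # maintained incrementally
    min_rho: dict[int, float] = {}
    while len(selected) < k2:
        best_j, best_score = None, -math.inf
        for j in remaining:
            score = s * mi_cache[j]
            if selected:
                score -= y * min_rho[j]
            if score > best_score:
                best_j, best_score = j, score
        assert best_j is not None
        selected.append(best_j)
        remaining.remove(best_j)
        xb = ds.matrix[:, best_j]
        for j in remaining:
            rho = spearman(ds.matrix[:, j], xb)
            if len(selected) == 1:
                min_rho[j] = rho
            else:
                min_rho[j] = min(min_rho[j], rho)
    return selected
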