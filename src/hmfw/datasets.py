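"""Expression-matrix containers, I/O, normalization, synthetic fixtures and CV folds.

The central container is :class:`ExpressionDataset`: a dense samples x features
real matrix with one categorical class label per sample, the shape shared by
public microarray/proteome classification benchmarks (tens to a few hundred
samples, thousands to tens of thousands of features).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold


class DatasetError(ValueError):
    """Raised for malformed or infeasible dataset inputs."""


@dataclass
class ExpressionDataset:
    """Samples x features expression matrix with per-sample class labels.

    Parameters
    ----------
    matrix
        Real-valued array of shape ``(n_samples, n_features)``.
    labels
        Integer class codes, length ``n_samples``.
    feature_ids
        Unique feature identifiers, length ``n_features``.
    sample_ids
        Sample identifiers, length ``n_samples``.
    """

    matrix: np.ndarray
    labels: np.ndarray
    feature_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.matrix.ndim != 2:
            raise DatasetError("matrix must be 2-D (samples x features)")
        n, f = self.matrix.shape
        if len(self.labels) != n:
            raise DatasetError(f"{len(self.labels)} labels for {n} samples")
        if len(self.feature_ids) != f:
            raise DatasetError(f"{len(self.feature_ids)} feature ids for {f} features")
        if len(self.sample_ids) != n:
            raise DatasetError(f"{len(self.sample_ids)} sample ids for {n} samples")
        if len(set(self.feature_ids)) != f:
            dupes = sorted({x for x in self.feature_ids if self.feature_ids.count(x) > 1})
            raise DatasetError(f"duplicate feature ids: {dupes[:5]}")
        if np.isnan(self.matrix).any():
            raise DatasetError("matrix contains missing values")
        if len(np.unique(self.labels)) < 2:
            raise DatasetError("need at least 2 distinct classes")

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]

    @property
    def n_classes(self) -> int:
        return len(np.unique(self.labels))

    def to_csv(self, path: str | Path, label_column: str = "class") -> None:
        """Write samples-in-rows CSV with a trailing label column."""
        df = pd.DataFrame(self.matrix, columns=self.feature_ids, index=self.sample_ids)
        df[label_column] = self.labels
        df.to_csv(path, index_label="sample_id")


def load_expression_table(
    path: str | Path,
    label_column: str = "class",
    orientation: str = "samples-in-rows",
    impute_median: bool = False,
) -> ExpressionDataset:
    """Read a CSV/TSV expression table into an :class:`ExpressionDataset`.

    The delimiter is chosen from the file extension (``.tsv``/``.txt`` = tab,
    otherwise comma). ``orientation="features-in-rows"`` transposes the table
    first (common for microarray exports); the label column/row is then located
    in the transposed frame.

    Missing values are rejected by default; ``impute_median=True`` replaces
    them with the per-feature median instead.
    """
    path = Path(path)
    if not path.exists():
        raise DatasetError(f"dataset file not found: {path}")
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)[1:]
    if orientation == "samples-in-rows" and len(set(header)) != len(header):
        # pandas silently renames duplicate columns, so check the raw header
        dupes = sorted({c for c in header if header.count(c) > 1})
        raise DatasetError(f"duplicate feature ids in header: {dupes[:5]}")
    df = pd.read_csv(path, sep=sep, index_col=0)
    if orientation == "features-in-rows":
        df = df.T
    elif orientation != "samples-in-rows":
        raise DatasetError(f"unknown orientation: {orientation!r}")
    if label_column not in df.columns:
        raise DatasetError(
            f"label column {label_column!r} not found; columns start with "
            f"{list(df.columns[:5])}"
        )
    labels_raw = df[label_column]
    feats = df.drop(columns=[label_column])
    feature_ids = [str(c) for c in feats.columns]
    if len(set(feature_ids)) != len(feature_ids):
        seen: set[str] = set()
        dupes = sorted({c for c in feature_ids if c in seen or seen.add(c)})  # type: ignore[func-returns-value]
        raise DatasetError(f"duplicate feature ids in header: {dupes[:5]}")
    mat = feats.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    raw_na = feats.isna().to_numpy()
    coerced_na = np.isnan(mat) & ~raw_na
    if coerced_na.any():
        r, c = np.argwhere(coerced_na)[0]
        raise DatasetError(
            f"non-numeric value {feats.iat[r, c]!r} at row {feats.index[r]!r}, "
            f"column {feature_ids[c]!r}"
        )
    if np.isnan(mat).any():
        if impute_median:
            med = np.nanmedian(mat, axis=0)
            idx = np.where(np.isnan(mat))
            mat[idx] = np.take(med, idx[1])
        else:
            r, c = np.argwhere(np.isnan(mat))[0]
            raise DatasetError(
                f"missing value at row {feats.index[r]!r}, column {feature_ids[c]!r} "
                "(pass impute_median=True to impute)"
            )
    codes, _ = pd.factorize(labels_raw)
    return ExpressionDataset(
        matrix=mat,
        labels=codes,
        feature_ids=feature_ids,
        sample_ids=[str(i) for i in df.index],
    )


def minmax_normalize(ds: ExpressionDataset) -> ExpressionDataset:
    """Affinely map every feature column to [0, 1]; constant columns map to 0.

    Labels are untouched. Idempotent on already-normalized data.
    """
    lo = ds.matrix.min(axis=0)
    hi = ds.matrix.max(axis=0)
    span = hi - lo
    out = np.zeros_like(ds.matrix)
    nz = span > 0
    out[:, nz] = (ds.matrix[:, nz] - lo[nz]) / span[nz]
    return ExpressionDataset(out, ds.labels.copy(), list(ds.feature_ids), list(ds.sample_ids))


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for a synthetic omics classification dataset.

    Emulates the statistical regime of the public benchmarks the method
    targets: a small planted set of class-informative features, correlated
    redundant copies of them, and a large majority of pure Gaussian noise
    features.
    """

    n_samples: int = 100
    n_features: int = 2000
    n_informative: int = 10
    n_redundant_per_informative: int = 2
    n_classes: int = 2
    class_separation: float = 2.0  # class-mean gap in units of noise_sd
    redundancy_rho: float = 0.8
    noise_sd: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_informative * (1 + self.n_redundant_per_informative) > self.n_features:
            raise DatasetError("informative + redundant features exceed n_features")
        if not (0 < self.redundancy_rho < 1):
            raise DatasetError("redundancy_rho must be in (0,1)")
        if self.noise_sd <= 0:
            raise DatasetError("noise_sd must be positive")
        if self.n_classes < 2:
            raise DatasetError("need at least 2 classes")
        if self.n_samples < 2 * self.n_classes:
            raise DatasetError("too few samples for the requested class count")


@dataclass
class PlantedFeatures:
    """Indices of the planted signal, recorded as report metadata."""

    informative: list[int]
    redundant: list[int] = field(default_factory=list)
    parent_of_redundant: dict[int, int] = field(default_factory=dict)

    def to_json(self, path: str | Path, spec: SyntheticSpec | None = None) -> None:
        payload = {
            "informative": self.informative,
            "redundant": self.redundant,
            "parent_of_redundant": {str(k): v for k, v in self.parent_of_redundant.items()},
        }
        if spec is not None:
            payload["spec"] = spec.__dict__
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "PlantedFeatures":
        d = json.loads(Path(path).read_text())
        return cls(
            informative=list(d["informative"]),
            redundant=list(d["redundant"]),
            parent_of_redundant={int(k): v for k, v in d.get("parent_of_redundant", {}).items()},
        )


def generate_synthetic_omics(spec: SyntheticSpec) -> tuple[ExpressionDataset, PlantedFeatures]:
    """Generate a seeded synthetic dataset matching ``spec``.

    Informative features get class-dependent means separated by
    ``class_separation * noise_sd``; each redundant feature is
    ``rho * parent + sqrt(1 - rho^2) * independent noise``; all remaining
    features are pure noise. Deterministic: the same spec yields a bitwise
    identical dataset.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n, f = spec.n_samples, spec.n_features
    labels = np.arange(n) % spec.n_classes  # balanced classes
    rng.shuffle(labels)
    mat = rng.normal(0.0, spec.noise_sd, size=(n, f))

    n_red_total = spec.n_informative * spec.n_redundant_per_informative
    # scatter planted columns uniformly so column order carries no signal
    planted_pos = rng.choice(f, size=spec.n_informative + n_red_total, replace=False)
    informative = [int(j) for j in planted_pos[: spec.n_informative]]
    redundant = [int(j) for j in planted_pos[spec.n_informative :]]
    parent_of = {}

    gap = spec.class_separation * spec.noise_sd
    for j in informative:
        # random sign pattern of class means keeps features non-collinear
        class_means = rng.permutation(spec.n_classes) * gap
        mat[:, j] += class_means[labels]
    rho = spec.redundancy_rho
    for r_pos, j in enumerate(redundant):
        parent = informative[r_pos % spec.n_informative]
        parent_of[j] = parent
        parent_col = mat[:, parent]
        pc = (parent_col - parent_col.mean()) / (parent_col.std() or 1.0)
        noise = rng.normal(0.0, 1.0, size=n)
        mat[:, j] = rho * pc + np.sqrt(1.0 - rho * rho) * noise

    ds = ExpressionDataset(
        matrix=mat,
        labels=labels,
        feature_ids=[f"g{j}" for j in range(f)],
        sample_ids=[f"s{i}" for i in range(n)],
    )
    return ds, PlantedFeatures(informative, redundant, parent_of)


def stratified_folds(
    ds: ExpressionDataset, k: int, seed: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Seeded stratified k-fold split; returns (train_idx, test_idx) pairs.

    Every class must have at least ``k`` samples so each fold sees every class.
    """
    _, counts = np.unique(ds.labels, return_counts=True)
    if counts.min() < k:
        raise DatasetError(
            f"smallest class has {counts.min()} samples; cannot stratify into {k} folds"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed % (2**31))
    return [(tr, te) for tr, te in skf.split(ds.matrix, ds.labels)]


def subset_features(ds: ExpressionDataset, indices: Sequence[int]) -> ExpressionDataset:
    """View of the dataset restricted to the given feature columns (in order)."""
    idx = list(indices)
    return ExpressionDataset(
        matrix=ds.matrix[:, idx],
        labels=ds.labels,
        feature_ids=[ds.feature_ids[j] for j in idx],
        sample_ids=list(ds.sample_ids),
    )
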