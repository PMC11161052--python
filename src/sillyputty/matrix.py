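"""Core data containers: feature matrices, distance matrices, cluster labels.

A :class:`FeatureMatrix` holds a samples x features block of log-scale
expression values; a :class:`DistanceMatrix` holds the symmetric pairwise
dissimilarities the clustering heuristic actually consumes; a
:class:`ClusterLabels` holds one integer cluster id per sample.  All three
are thin, validated wrappers around NumPy arrays with ordered string ids,
and round-trip through CSV/TSV via pandas.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    AsymmetricDistanceError,
    InvalidMatrixError,
    LabelMismatchError,
    MissingValuesError,
    NegativeDistanceError,
)

__all__ = [
    "FeatureMatrix",
    "DistanceMatrix",
    "ClusterLabels",
    "read_feature_matrix",
    "write_feature_matrix",
    "read_distance_matrix",
    "write_distance_matrix",
    "read_labels",
    "write_labels",
]

#: Asymmetry below this is averaged away silently; above it is an error.
SYMMETRY_TOL = 1e-6
#: Strict symmetry tolerance a constructed DistanceMatrix must satisfy.
SYMMETRY_STRICT = 1e-9


def _check_ids(ids: Sequence[str], what: str, n: int) -> tuple[str, ...]:
    ids = tuple(str(i) for i in ids)
    if len(ids) != n:
        raise InvalidMatrixError(f"{what}: expected {n} ids, got {len(ids)}")
    if len(set(ids)) != len(ids):
        raise InvalidMatrixError(f"{what}: ids are not unique")
    return ids


def _default_ids(prefix: str, n: int) -> tuple[str, ...]:
    width = max(1, len(str(n)))
    return tuple(f"{prefix}{i + 1:0{width}d}" for i in range(n))


@dataclass(frozen=True)
class FeatureMatrix:
    """Samples x features numeric matrix (log-expression scale, unitless).

    Parameters
    ----------
    values : ndarray, shape (n_samples, n_features)
        Finite float values; at least 2 samples and 1 feature.
    sample_ids, feature_ids : sequence of str, optional
        Unique ordered identifiers; autogenerated if omitted.
    """

    values: np.ndarray
    sample_ids: tuple[str, ...] = field(default=())
    feature_ids: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise InvalidMatrixError("feature matrix must be 2-dimensional")
        n, f = values.shape
        if n < 2:
            raise InvalidMatrixError(f"need at least 2 samples, got {n}")
        if f < 1:
            raise InvalidMatrixError(f"need at least 1 feature, got {f}")
        if not np.all(np.isfinite(values)):
            raise MissingValuesError("feature matrix contains NaN or infinite values")
        object.__setattr__(self, "values", values)
        sample_ids = self.sample_ids or _default_ids("S", n)
        feature_ids = self.feature_ids or _default_ids("G", f)
        object.__setattr__(self, "sample_ids", _check_ids(sample_ids, "sample_ids", n))
        object.__setattr__(self, "feature_ids", _check_ids(feature_ids, "feature_ids", f))

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "FeatureMatrix":
        return cls(df.to_numpy(dtype=float), tuple(map(str, df.index)), tuple(map(str, df.columns)))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.sample_ids), columns=list(self.feature_ids))


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric n x n pairwise dissimilarity matrix with zero diagonal."""

    values: np.ndarray
    sample_ids: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2 or values.shape[0] != values.shape[1]:
            raise InvalidMatrixError("distance matrix must be square")
        if not np.all(np.isfinite(values)):
            raise MissingValuesError("distance matrix contains NaN or infinite values")
        gap = float(np.max(np.abs(values - values.T), initial=0.0))
        if gap > SYMMETRY_STRICT:
            raise AsymmetricDistanceError(
                f"distance matrix asymmetric (max |D - D^T| = {gap:.3g} > {SYMMETRY_STRICT:g})"
            )
        if np.any(values < 0):
            raise NegativeDistanceError("distance matrix contains negative entries")
        if np.any(np.diag(values) != 0):
            raise InvalidMatrixError("distance matrix diagonal must be exactly zero")
        object.__setattr__(self, "values", values)
        ids = self.sample_ids or _default_ids("S", values.shape[0])
        object.__setattr__(self, "sample_ids", _check_ids(ids, "sample_ids", values.shape[0]))

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "DistanceMatrix":
        from .distances import validate_distance_matrix

        return validate_distance_matrix(df.to_numpy(dtype=float), tuple(map(str, df.index)))

    def to_dataframe(self) -> pd.DataFrame:
        ids = list(self.sample_ids)
        return pd.DataFrame(self.values, index=ids, columns=ids)

    def scaled(self, c: float) -> "DistanceMatrix":
        """Return a copy with all dissimilarities multiplied by ``c`` > 0."""
        if c <= 0:
            raise InvalidMatrixError("scale factor must be positive")
        return DistanceMatrix(self.values * c, self.sample_ids)


@dataclass(frozen=True)
class ClusterLabels:
    """One integer cluster id per sample, aligned with a matrix row order."""

    assignment: np.ndarray
    sample_ids: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        arr = np.asarray(self.assignment)
        if arr.ndim != 1 or arr.size == 0:
            raise LabelMismatchError("label assignment must be a nonempty 1-d vector")
        if not np.issubdtype(arr.dtype, np.integer):
            rounded = np.asarray(arr, dtype=float)
            if not np.all(np.isfinite(rounded)) or np.any(rounded != np.round(rounded)):
                raise LabelMismatchError("cluster ids must be integers")
            arr = rounded.astype(np.int64)
        object.__setattr__(self, "assignment", arr.astype(np.int64))
        ids = self.sample_ids or _default_ids("S", arr.size)
        object.__setattr__(self, "sample_ids", _check_ids(ids, "sample_ids", arr.size))

    def __len__(self) -> int:
        return self.assignment.size

    @property
    def k(self) -> int:
        """Number of distinct clusters actually present."""
        return int(np.unique(self.assignment).size)

    @property
    def cluster_ids(self) -> np.ndarray:
        return np.unique(self.assignment)

    def sizes(self) -> dict[int, int]:
        ids, counts = np.unique(self.assignment, return_counts=True)
        return {int(i): int(c) for i, c in zip(ids, counts)}

    def relabeled(self, mapping: dict[int, int]) -> "ClusterLabels":
        new = np.array([mapping.get(int(v), int(v)) for v in self.assignment], dtype=np.int64)
        return ClusterLabels(new, self.sample_ids)


def as_labels(labels: "ClusterLabels | Iterable[int]", sample_ids: Sequence[str] = ()) -> ClusterLabels:
    """Coerce an array-like of ints into :class:`ClusterLabels`."""
    if isinstance(labels, ClusterLabels):
        return labels
    return ClusterLabels(np.asarray(list(labels)), tuple(sample_ids))


# ---------------------------------------------------------------------------
# Text I/O: first column = sample id, header row = feature / sample ids.
# Delimiter auto-detected from the extension (.csv -> comma, else tab),
# overridable via `delimiter`.
# ---------------------------------------------------------------------------

def _sep(path: Path | str, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "," if str(path).lower().endswith(".csv") else "\t"


def read_feature_matrix(path: Path | str, delimiter: str | None = None) -> FeatureMatrix:
    df = pd.read_csv(path, sep=_sep(path, delimiter), index_col=0)
    return FeatureMatrix.from_dataframe(df)


def write_feature_matrix(X: FeatureMatrix, path: Path | str, delimiter: str | None = None) -> None:
    X.to_dataframe().to_csv(path, sep=_sep(path, delimiter))


def read_distance_matrix(path: Path | str, delimiter: str | None = None) -> DistanceMatrix:
    df = pd.read_csv(path, sep=_sep(path, delimiter), index_col=0)
    return DistanceMatrix.from_dataframe(df)


def write_distance_matrix(D: DistanceMatrix, path: Path | str, delimiter: str | None = None) -> None:
    D.to_dataframe().to_csv(path, sep=_sep(path, delimiter))


def read_labels(path: Path | str, delimiter: str | None = None) -> ClusterLabels:
    df = pd.read_csv(path, sep=_sep(path, delimiter), index_col=0)
    return ClusterLabels(df.iloc[:, 0].to_numpy(), tuple(map(str, df.index)))


def write_labels(labels: ClusterLabels, path: Path | str, delimiter: str | None = None) -> None:
    pd.DataFrame(
        {"cluster": labels.assignment}, index=list(labels.sample_ids)
    ).rename_axis("sample").to_csv(path, sep=_sep(path, delimiter))
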