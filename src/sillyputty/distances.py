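"""Distance-matrix construction and validation.

Two metrics are supported natively — Euclidean distance and correlation
distance (1 - Pearson r between sample rows) — plus validation of arbitrary
precomputed matrices.  Distances are computed exactly in double precision:
the refinement loop compares mean distances, so approximate shortcuts are
deliberately avoided.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .exceptions import (
    AsymmetricDistanceError,
    InvalidMatrixError,
    MissingValuesError,
    NegativeDistanceError,
    ZeroVarianceError,
)
from .matrix import SYMMETRY_TOL, DistanceMatrix, FeatureMatrix

__all__ = ["euclidean_distances", "correlation_distances", "validate_distance_matrix"]


def euclidean_distances(X: FeatureMatrix) -> DistanceMatrix:
    """Pairwise Euclidean distances between sample rows.

    D[i, j] = sqrt(sum_f (x_if - x_jf)^2); symmetric with an exactly zero
    diagonal.
    """
    if not isinstance(X, FeatureMatrix):
        X = FeatureMatrix(np.asarray(X, dtype=float))
    D = squareform(pdist(X.values, metric="euclidean"))
    return DistanceMatrix(D, X.sample_ids)


def correlation_distances(X: FeatureMatrix) -> DistanceMatrix:
    """Correlation distance between sample rows: D[i, j] = 1 - pearson(x_i, x_j).

    Values lie in [0, 2]; rows with zero variance have undefined correlation
    and are rejected with a :class:`ZeroVarianceError` naming the sample.
    """
    if not isinstance(X, FeatureMatrix):
        X = FeatureMatrix(np.asarray(X, dtype=float))
    if X.n_features < 2:
        raise InvalidMatrixError("correlation distance needs at least 2 features")
    sd = X.values.std(axis=1)
    flat = np.flatnonzero(sd == 0)
    if flat.size:
        bad = ", ".join(X.sample_ids[i] for i in flat[:5])
        raise ZeroVarianceError(f"zero-variance sample row(s): {bad}")
    r = np.corrcoef(X.values)
    D = 1.0 - r
    # corrcoef can stray past [-1, 1] by ~1e-16; clip, then enforce structure.
    D = np.clip(D, 0.0, 2.0)
    D = (D + D.T) / 2.0
    np.fill_diagonal(D, 0.0)
    return DistanceMatrix(D, X.sample_ids)


def validate_distance_matrix(
    values: np.ndarray, sample_ids: Sequence[str] = ()
) -> DistanceMatrix:
    """Validate a precomputed square matrix and coerce it to a DistanceMatrix.

    Asymmetry below ``SYMMETRY_TOL`` (1e-6, covering decimal-text round trips)
    is averaged away silently and the diagonal forced to zero; anything worse,
    negative entries, or non-finite values raise named errors.
    """
    D = np.array(values, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise InvalidMatrixError("distance matrix must be square")
    if not np.all(np.isfinite(D)):
        raise MissingValuesError("distance matrix contains NaN or infinite values")
    gap = float(np.max(np.abs(D - D.T), initial=0.0))
    if gap > SYMMETRY_TOL:
        raise AsymmetricDistanceError(
            f"asymmetry {gap:.3g} exceeds tolerance {SYMMETRY_TOL:g}"
        )
    if np.any(D < -SYMMETRY_TOL):
        raise NegativeDistanceError("distance matrix contains negative entries")
    D = (D + D.T) / 2.0
    np.clip(D, 0.0, None, out=D)
    np.fill_diagonal(D, 0.0)
    return DistanceMatrix(D, tuple(sample_ids))
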