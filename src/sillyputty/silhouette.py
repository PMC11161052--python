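"""Per-sample silhouette widths from a distance matrix and a labeling.

For sample ``x_i`` in cluster ``C``:

* cohesion  ``a(x_i)`` — mean distance from ``x_i`` to the *other* members
  of ``C`` (self excluded, divisor ``|C| - 1``);
* separation ``b(x_i)`` — the minimum, over clusters ``C' != C``, of the
  mean distance from ``x_i`` to the members of ``C'``;
* silhouette ``s(x_i) = (b - a) / max(a, b)``, in ``[-1, 1]``.

Samples alone in their cluster follow Rousseeuw's convention ``s = 0``
(with ``a`` marked undefined as NaN), matching R's ``cluster::silhouette``.
The mean silhouette width (ASW) is the unweighted mean of ``s`` over all
samples, singletons included.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import DegenerateClusteringError, LabelMismatchError
from .matrix import ClusterLabels, DistanceMatrix, as_labels

__all__ = ["SilhouetteProfile", "silhouette_profile", "mean_silhouette"]


@dataclass(frozen=True)
class SilhouetteProfile:
    """Per-sample silhouette decomposition plus the mean width.

    Attributes
    ----------
    a, b, s : ndarray
        Cohesion, separation and silhouette per sample; ``a`` is NaN for
        singleton-cluster samples (whose ``s`` is 0 by convention).
    nearest_foreign : ndarray
        Cluster id attaining ``b`` for each sample (ties -> lowest id).
    asw : float
        Arithmetic mean of ``s`` over all samples.
    """

    a: np.ndarray
    b: np.ndarray
    s: np.ndarray
    nearest_foreign: np.ndarray
    asw: float

    def to_frame(self, labels: ClusterLabels) -> pd.DataFrame:
        """Tabular layout mirroring the reference R silhouette object."""
        return pd.DataFrame(
            {
                "cluster": labels.assignment,
                "neighbor": self.nearest_foreign,
                "sil_width": self.s,
            },
            index=list(labels.sample_ids),
        ).rename_axis("sample")

    def to_tsv(self, labels: ClusterLabels, path: Path | str) -> None:
        self.to_frame(labels).to_csv(path, sep="\t")


def silhouette_profile(D: DistanceMatrix, labels) -> SilhouetteProfile:
    """Compute the full silhouette profile of ``labels`` under ``D``.

    Raises
    ------
    DegenerateClusteringError
        If fewer than two clusters are present (separation is undefined).
    LabelMismatchError
        If the label vector length differs from the matrix size.
    """
    labels = as_labels(labels)
    n = D.n_samples
    if len(labels) != n:
        raise LabelMismatchError(
            f"{len(labels)} labels for a {n}-sample distance matrix"
        )
    cluster_ids = labels.cluster_ids  # sorted, so argmin tie-break = lowest id
    k = cluster_ids.size
    if k < 2:
        raise DegenerateClusteringError("silhouette requires at least 2 clusters")

    # column c of `member` flags membership of cluster_ids[c]
    member = labels.assignment[:, None] == cluster_ids[None, :]
    counts = member.sum(axis=0)
    sums = D.values @ member  # (n, k) total distance from each sample to each cluster

    own_col = np.searchsorted(cluster_ids, labels.assignment)
    own_count = counts[own_col]
    own_sum = sums[np.arange(n), own_col]
    with np.errstate(invalid="ignore", divide="ignore"):
        a = np.where(own_count > 1, own_sum / np.maximum(own_count - 1, 1), np.nan)

    foreign = sums / counts[None, :]
    foreign[np.arange(n), own_col] = np.inf
    b = foreign.min(axis=1)
    nearest_foreign = cluster_ids[foreign.argmin(axis=1)]

    denom = np.fmax(a, b)
    with np.errstate(invalid="ignore", divide="ignore"):
        s = (b - a) / denom
    # singleton clusters -> s = 0; duplicate points with a = b = 0 -> s = 0
    s = np.where(own_count == 1, 0.0, s)
    s = np.where(np.isnan(s), 0.0, s)

    return SilhouetteProfile(a=a, b=b, s=s, nearest_foreign=nearest_foreign, asw=float(s.mean()))


def mean_silhouette(D: DistanceMatrix, labels) -> float:
    """Mean silhouette width (ASW): unweighted mean of per-sample widths."""
    return silhouette_profile(D, labels).asw
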