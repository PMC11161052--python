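"""Cluster validity indices: ARI, normalized entropy, WSS/NWSS, PCC.

External indices (ARI, entropy, perfect-classification) compare a predicted
partition against ground truth; internal ones (ASW, WSS) score a partition
on the data alone.  The normalized within-group sum of squares (NWSS)
divides WSS by the WSS of the true labels so values are comparable across
data sets (1 at the truth, typically >= 1 elsewhere).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from sklearn.metrics import adjusted_rand_score

from .exceptions import SillyPuttyError, LabelMismatchError
from .matrix import DistanceMatrix, FeatureMatrix, as_labels
from .silhouette import mean_silhouette

__all__ = [
    "ContingencyTable",
    "EvaluationReport",
    "contingency_table",
    "adjusted_rand_index",
    "cluster_entropy",
    "wss",
    "normalized_wss",
    "perfect_classification",
    "evaluate_clustering",
]

#: |1 - ARI| below this counts as a perfect classification.
PERFECT_TOL = 1e-12


def _pair(p, t) -> tuple[np.ndarray, np.ndarray]:
    p, t = as_labels(p), as_labels(t)
    if len(p) != len(t):
        raise LabelMismatchError(f"label vectors differ in length: {len(p)} vs {len(t)}")
    return p.assignment, t.assignment


@dataclass(frozen=True)
class ContingencyTable:
    """Cross-tabulation of two partitions of the same samples."""

    counts: np.ndarray  # rows: clusters of solution 1, cols: clusters of solution 2
    row_ids: np.ndarray
    col_ids: np.ndarray

    @property
    def row_sums(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_sums(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def contingency_table(p, t) -> ContingencyTable:
    a, b = _pair(p, t)
    rows, ri = np.unique(a, return_inverse=True)
    cols, ci = np.unique(b, return_inverse=True)
    counts = np.zeros((rows.size, cols.size), dtype=np.int64)
    np.add.at(counts, (ri, ci), 1)
    return ContingencyTable(counts, rows, cols)


def adjusted_rand_index(p, t) -> float:
    """Chance-corrected pair-counting agreement between two partitions.

    1 iff the partitions are identical up to relabeling; symmetric in its
    arguments.
    """
    a, b = _pair(p, t)
    return float(adjusted_rand_score(a, b))


def cluster_entropy(p, t) -> float:
    """Size-weighted normalized entropy of truth composition within predicted clusters.

    For predicted cluster ``S`` with truth-class counts ``n_j``,
    ``E(S) = -1/log(K) * sum_j (n_j/|S|) log(n_j/|S|)`` with ``K`` the number
    of truth classes (0*log 0 = 0); the global value is the |S|/n-weighted
    mean, in [0, 1].  0 means every predicted cluster is pure.
    """
    a, b = _pair(p, t)
    k_truth = np.unique(b).size
    if k_truth < 2:
        raise SillyPuttyError("entropy undefined for a single truth class (log K = 0)")
    table = contingency_table(a, b)
    n = table.total
    log_k = np.log(k_truth)
    global_entropy = 0.0
    for row, size in zip(table.counts, table.row_sums):
        props = row[row > 0] / size
        e = -np.sum(props * np.log(props)) / log_k
        global_entropy += (size / n) * e
    return float(global_entropy)


def wss(X: FeatureMatrix, labels) -> float:
    """Within-group sum of squares: sum of squared distances to cluster centroids."""
    labels = as_labels(labels)
    if not isinstance(X, FeatureMatrix):
        X = FeatureMatrix(np.asarray(X, dtype=float))
    if len(labels) != X.n_samples:
        raise LabelMismatchError(
            f"{len(labels)} labels for {X.n_samples} samples"
        )
    total = 0.0
    for cid in labels.cluster_ids:
        block = X.values[labels.assignment == cid]
        total += float(np.sum((block - block.mean(axis=0)) ** 2))
    return total


def normalized_wss(X: FeatureMatrix, labels, truth) -> float:
    """WSS of ``labels`` divided by the WSS of the true assignment."""
    denom = wss(X, truth)
    if denom == 0:
        raise SillyPuttyError("WSS of the true labels is 0; NWSS undefined")
    return wss(X, labels) / denom


def perfect_classification(p, t) -> bool:
    """True iff the partitions agree exactly up to relabeling (ARI = 1)."""
    return bool(abs(adjusted_rand_index(p, t) - 1.0) <= PERFECT_TOL)


@dataclass(frozen=True)
class EvaluationReport:
    """The five benchmark columns for one (method, dataset) cell."""

    asw: float
    ari: float
    entropy: float
    wss: float
    nwss: float
    perfect: bool

    def to_dict(self) -> dict:
        return asdict(self)


def evaluate_clustering(
    X: FeatureMatrix,
    D: DistanceMatrix,
    labels,
    truth,
) -> EvaluationReport:
    """Score one predicted partition against truth on all five indices."""
    labels, truth = as_labels(labels), as_labels(truth)
    return EvaluationReport(
        asw=mean_silhouette(D, labels),
        ari=adjusted_rand_index(labels, truth),
        entropy=cluster_entropy(labels, truth),
        wss=wss(X, labels),
        nwss=normalized_wss(X, labels, truth),
        perfect=perfect_classification(labels, truth),
    )
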