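"""The silhouette-refinement heuristic and its model/results interface.

The algorithm starts from *any* labeling of the samples and repeatedly

1. computes every sample's silhouette width under the current labeling,
2. finds the sample with the most negative width (the worst-clustered one),
3. moves that sample to its nearest foreign cluster (the cluster attaining
   its separation ``b``),

halting when all widths are non-negative (*converged*), when an iteration
cap is hit, or when the silhouette vector recurs within a sliding window
(a cycle).  On cycle/cap termination the best-ASW state seen is returned.

Entry points mirror common usage: :func:`run_sillyputty` refines a given
initial labeling (:func:`sillyputty_warm` is the named hybrid alias),
:func:`sillyputty_random` restarts from many random partitions and keeps
the best final ASW.  The :class:`SillyPutty` class wraps these in a
model-object interface whose :meth:`SillyPutty.fit` returns a
:class:`SillyPuttyResults`.
"""

from __future__ import annotations

import enum
from collections import deque
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .distances import correlation_distances, euclidean_distances
from .exceptions import DegenerateClusteringError, LabelMismatchError, SillyPuttyError
from .matrix import ClusterLabels, DistanceMatrix, FeatureMatrix, as_labels
from .silhouette import SilhouetteProfile, silhouette_profile

__all__ = [
    "SillyPuttyConfig",
    "SillyPuttyResults",
    "Termination",
    "sillyputty_step",
    "run_sillyputty",
    "sillyputty_random",
    "sillyputty_warm",
    "SillyPutty",
]


class Termination(str, enum.Enum):
    CONVERGED = "converged"
    MAX_ITER = "max_iter"
    CYCLE_DETECTED = "cycle_detected"


@dataclass(frozen=True)
class SillyPuttyConfig:
    """Tuning knobs for the refinement loop.

    max_iter : hard cap on reassignment moves (default 1000).
    loop_window : number of trailing silhouette vectors kept for cycle
        detection (default 20).
    n_starts : number of random restarts for the random-start driver
        (default 100).
    seed : root seed; child seeds are spawned per restart so multi-start
        runs are reproducible.
    """

    max_iter: int = 1000
    loop_window: int = 20
    n_starts: int = 100
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.max_iter < 1 or self.loop_window < 1 or self.n_starts < 1:
            raise SillyPuttyError("max_iter, loop_window and n_starts must be positive")
        if self.loop_window > self.max_iter:
            raise SillyPuttyError("loop_window must not exceed max_iter")


@dataclass(frozen=True)
class TraceRecord:
    """One reassignment: which sample moved where, and the state before it."""

    iteration: int
    sample: str
    sample_index: int
    from_cluster: int
    to_cluster: int
    min_silhouette: float
    asw: float


@dataclass(frozen=True)
class SillyPuttyResults:
    """Outcome of one refinement run.

    Carries the final labeling, its silhouette profile and ASW, the number
    of moves performed, why the loop stopped, and the per-move trace.
    """

    labels: ClusterLabels
    profile: SilhouetteProfile
    asw: float
    n_iterations: int
    termination: Termination
    trace: tuple[TraceRecord, ...]
    initial_asw: float
    n_starts: int = 1

    @property
    def labels_(self) -> np.ndarray:
        """Final assignment vector (sklearn-style accessor)."""
        return self.labels.assignment

    @property
    def k(self) -> int:
        return self.labels.k

    def summary(self) -> str:
        sizes = self.labels.sizes()
        lines = [
            "Silhouette-refinement clustering results",
            "=" * 44,
            f"samples:            {len(self.labels)}",
            f"clusters (final):   {self.k}",
            f"cluster sizes:      {sizes}",
            f"ASW (final):        {self.asw:.6f}",
            f"ASW (initial):      {self.initial_asw:.6f}",
            f"min silhouette:     {float(self.profile.s.min()):.6f}",
            f"iterations (moves): {self.n_iterations}",
            f"termination:        {self.termination.value}",
            f"random starts:      {self.n_starts}",
        ]
        return "\n".join(lines)

    def plot_silhouette(self, ax=None):
        """Sorted per-cluster silhouette bar plot (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        order = np.lexsort((-self.profile.s, self.labels.assignment))
        ax.barh(np.arange(order.size), self.profile.s[order], height=1.0)
        ax.axvline(self.asw, color="red", linestyle="--", label=f"ASW = {self.asw:.3f}")
        ax.set_xlabel("silhouette width")
        ax.set_ylabel("samples (grouped by cluster)")
        ax.legend()
        return ax


def sillyputty_step(
    D: DistanceMatrix, labels
) -> tuple[ClusterLabels, int | None]:
    """One refinement move.

    If every silhouette is non-negative the labeling is a fixed point and is
    returned unchanged with ``moved = None``.  Otherwise the sample with the
    most negative width (ties -> lowest sample index) moves to its nearest
    foreign cluster (ties -> lowest cluster id) and its index is returned.
    """
    labels = as_labels(labels)
    prof = silhouette_profile(D, labels)
    if prof.s.min() >= 0:
        return labels, None
    i = int(prof.s.argmin())  # argmin returns the first (lowest) index on ties
    dest = int(prof.nearest_foreign[i])
    _check_not_degenerate(labels, i)
    new = labels.assignment.copy()
    new[i] = dest
    return ClusterLabels(new, labels.sample_ids), i


def _check_not_degenerate(labels: ClusterLabels, i: int) -> None:
    src = int(labels.assignment[i])
    src_size = int(np.sum(labels.assignment == src))
    if src_size == 1 and labels.k <= 2:
        raise DegenerateClusteringError(
            f"moving sample {labels.sample_ids[i]} would leave a single cluster"
        )


def run_sillyputty(
    D: DistanceMatrix,
    init,
    cfg: SillyPuttyConfig | None = None,
) -> SillyPuttyResults:
    """Refine ``init`` until convergence, the iteration cap, or a cycle.

    Halting is checked on freshly computed silhouettes at the top of each
    iteration.  A cluster may legitimately empty out mid-run (k shrinks);
    only reaching k = 1 is an error, raised with the trace attached.
    """
    cfg = cfg or SillyPuttyConfig()
    labels = as_labels(init)
    if len(labels) != D.n_samples:
        raise LabelMismatchError(
            f"{len(labels)} initial labels for a {D.n_samples}-sample matrix"
        )
    trace: list[TraceRecord] = []
    recent: deque[tuple] = deque(maxlen=cfg.loop_window)
    best: tuple[float, ClusterLabels, SilhouetteProfile] | None = None
    initial_asw: float | None = None
    moves = 0

    while True:
        if labels.k < 2:
            raise DegenerateClusteringError(
                "clustering degenerated to a single cluster", trace=trace
            )
        prof = silhouette_profile(D, labels)
        if initial_asw is None:
            initial_asw = prof.asw
        if best is None or prof.asw > best[0]:
            best = (prof.asw, labels, prof)

        if prof.s.min() >= 0:
            return SillyPuttyResults(
                labels, prof, prof.asw, moves, Termination.CONVERGED,
                tuple(trace), initial_asw,
            )
        key = tuple(np.round(prof.s, 12))
        if key in recent:
            asw, blabels, bprof = best
            return SillyPuttyResults(
                blabels, bprof, asw, moves, Termination.CYCLE_DETECTED,
                tuple(trace), initial_asw,
            )
        recent.append(key)
        if moves >= cfg.max_iter:
            asw, blabels, bprof = best
            return SillyPuttyResults(
                blabels, bprof, asw, moves, Termination.MAX_ITER,
                tuple(trace), initial_asw,
            )

        i = int(prof.s.argmin())
        dest = int(prof.nearest_foreign[i])
        _check_not_degenerate(labels, i)
        new = labels.assignment.copy()
        src = int(new[i])
        new[i] = dest
        labels = ClusterLabels(new, labels.sample_ids)
        moves += 1
        trace.append(
            TraceRecord(
                iteration=moves,
                sample=labels.sample_ids[i],
                sample_index=i,
                from_cluster=src,
                to_cluster=dest,
                min_silhouette=float(prof.s[i]),
                asw=prof.asw,
            )
        )


def sillyputty_warm(
    D: DistanceMatrix, init_from_method, cfg: SillyPuttyConfig | None = None
) -> SillyPuttyResults:
    """Hybrid entry point: refine another method's labels (warm start)."""
    return run_sillyputty(D, init_from_method, cfg)


def _random_partition(n: int, k: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform random labeling with every cluster dealt at least one sample."""
    labels = np.empty(n, dtype=np.int64)
    perm = rng.permutation(n)
    labels[perm[:k]] = np.arange(k)
    labels[perm[k:]] = rng.integers(0, k, size=n - k)
    return labels


def sillyputty_random(
    D: DistanceMatrix, k: int, cfg: SillyPuttyConfig | None = None
) -> SillyPuttyResults:
    """Standalone driver: refine ``n_starts`` random partitions, keep best ASW.

    Each restart draws from a child of the root seed, so runs are
    reproducible and restarts could be fanned out in parallel without
    changing the answer.  Ties on final ASW keep the earliest restart.
    """
    cfg = cfg or SillyPuttyConfig()
    n = D.n_samples
    if k < 2:
        raise SillyPuttyError("need k >= 2 clusters")
    if n < k:
        raise SillyPuttyError(f"cannot split {n} samples into {k} clusters")
    children = np.random.SeedSequence(cfg.seed).spawn(cfg.n_starts)
    best: SillyPuttyResults | None = None
    for child in children:
        rng = np.random.default_rng(child)
        init = ClusterLabels(_random_partition(n, k, rng), D.sample_ids)
        res = run_sillyputty(D, init, cfg)
        if best is None or res.asw > best.asw:
            best = res
    return replace(best, n_starts=cfg.n_starts)


class SillyPutty:
    """Silhouette-refinement clustering model.

    Built from a distance matrix (the algorithm's sole view of the data),
    or from a feature matrix via :meth:`from_features` /
    :meth:`from_dataframe`.  If ``init_labels`` is given, :meth:`fit`
    warm-starts from them; otherwise ``n_clusters`` must be given and the
    multi-restart random driver is used.

    Examples
    --------
    >>> model = SillyPutty.from_features(X, n_clusters=3, seed=17)
    >>> res = model.fit()
    >>> print(res.summary())
    """

    def __init__(
        self,
        distance: DistanceMatrix,
        init_labels=None,
        n_clusters: int | None = None,
        config: SillyPuttyConfig | None = None,
        **config_kwargs,
    ) -> None:
        if config is not None and config_kwargs:
            raise SillyPuttyError("pass either a config object or keyword overrides, not both")
        self.distance = distance
        self.init_labels = None if init_labels is None else as_labels(init_labels)
        self.n_clusters = n_clusters
        self.config = config or SillyPuttyConfig(**config_kwargs)
        if self.init_labels is None and n_clusters is None:
            raise SillyPuttyError("provide init_labels or n_clusters")

    @classmethod
    def from_features(
        cls,
        X: FeatureMatrix | np.ndarray,
        metric: str = "euclidean",
        **kwargs,
    ) -> "SillyPutty":
        if not isinstance(X, FeatureMatrix):
            X = FeatureMatrix(np.asarray(X, dtype=float))
        if metric == "euclidean":
            D = euclidean_distances(X)
        elif metric == "correlation":
            D = correlation_distances(X)
        else:
            raise SillyPuttyError(f"unknown metric {metric!r} (euclidean or correlation)")
        return cls(D, **kwargs)

    @classmethod
    def from_dataframe(cls, df, metric: str = "euclidean", **kwargs) -> "SillyPutty":
        return cls.from_features(FeatureMatrix.from_dataframe(df), metric=metric, **kwargs)

    def fit(self) -> SillyPuttyResults:
        if self.init_labels is not None:
            return sillyputty_warm(self.distance, self.init_labels, self.config)
        return sillyputty_random(self.distance, self.n_clusters, self.config)
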