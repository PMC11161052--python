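"""Benchmark harness: baseline clusterers, hybrids, and grid aggregation.

Reruns the method comparison over a (scaled) simulation grid: for every
dataset it computes Euclidean distances, runs each requested method —
standalone baselines, the random-start silhouette refiner, and hybrids
(base labels handed to the refiner as a warm start) — and scores all five
validity indices against ground truth.  Aggregates are per-method means of
ASW/ARI/NWSS/entropy plus the summed perfect-classification count.

Baselines delegate to established implementations where one exists
(scipy Ward linkage, scikit-learn k-means and spectral clustering); PAM
(BUILD + SWAP) and CLARA (subsampled PAM) are implemented here directly.
Per-method seeds derive from the dataset seed, so every method sees
identical data and hybrid bases reproduce their standalone runs exactly.
"""

from __future__ import annotations

import hashlib
import json
import warnings
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import cdist, squareform
from sklearn.cluster import KMeans, SpectralClustering

from .core import SillyPuttyConfig, sillyputty_random, sillyputty_warm
from .distances import euclidean_distances
from .exceptions import SillyPuttyError
from .matrix import ClusterLabels, DistanceMatrix, FeatureMatrix
from .metrics import evaluate_clustering
from .synthetic import SimulationConfig, SimulatedDataset, simulate_dataset

__all__ = [
    "MethodSpec",
    "BenchmarkTable",
    "STANDALONE_METHODS",
    "run_baseline",
    "run_benchmark",
]

STANDALONE_METHODS = (
    "hierarchical_ward",
    "kmeans",
    "pam",
    "clara",
    "spectral",
    "sillyputty_random",
)


@dataclass(frozen=True)
class MethodSpec:
    """A named clustering method plus free-form parameters.

    ``hybrid:<base>`` runs the named standalone base and refines its labels
    with the silhouette refiner; ``truth`` is a pseudo-method returning the
    ground-truth labels (useful as a table reference row).
    """

    name: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        base = self.base_method
        if base is not None and base not in STANDALONE_METHODS:
            raise SillyPuttyError(f"unknown hybrid base {base!r}")
        if base is None and self.name not in STANDALONE_METHODS + ("truth",):
            raise SillyPuttyError(f"unknown method {self.name!r}")

    @property
    def is_hybrid(self) -> bool:
        return self.name.startswith("hybrid:")

    @property
    def base_method(self) -> str | None:
        if self.is_hybrid:
            return self.name.split(":", 1)[1]
        return None


def _method_seed(data_seed: int, method_name: str) -> int:
    """Stable per-(dataset, method) seed below 2^31."""
    mix = np.random.SeedSequence([data_seed, zlib.crc32(method_name.encode())])
    return int(mix.generate_state(1)[0] & 0x7FFFFFFF)


# ---------------------------------------------------------------------------
# PAM (partitioning around medoids) and CLARA, on a distance matrix.
# ---------------------------------------------------------------------------

def _pam_build(D: np.ndarray, k: int) -> np.ndarray:
    """Greedy BUILD phase: medoids chosen to minimize total assignment cost."""
    n = D.shape[0]
    medoids = [int(D.sum(axis=1).argmin())]
    nearest = D[:, medoids[0]].copy()
    while len(medoids) < k:
        # gain of adding candidate j: sum of max(nearest - D[:, j], 0)
        gain = np.maximum(nearest[:, None] - D, 0.0).sum(axis=0)
        gain[medoids] = -np.inf
        j = int(gain.argmax())
        medoids.append(j)
        nearest = np.minimum(nearest, D[:, j])
    return np.array(sorted(medoids), dtype=np.int64)


def _pam(D: np.ndarray, k: int, max_swaps: int = 200) -> np.ndarray:
    """BUILD + first-improvement-free SWAP; returns labels 0..k-1."""
    medoids = _pam_build(D, k)
    n = D.shape[0]
    for _ in range(max_swaps):
        dist_to_med = D[:, medoids]  # (n, k)
        order = np.argsort(dist_to_med, axis=1)
        nearest = dist_to_med[np.arange(n), order[:, 0]]
        second = dist_to_med[np.arange(n), order[:, 1]]
        nearest_idx = order[:, 0]
        best_delta, best_swap = -1e-12, None
        non_medoids = np.setdiff1d(np.arange(n), medoids, assume_unique=False)
        for mi in range(k):
            served = nearest_idx == mi
            # cost change of removing medoid mi and adding candidate h:
            # served points fall back to min(second, D[:, h]); others may switch to h
            for h in non_medoids:
                dh = D[:, h]
                delta = np.sum(np.minimum(second[served], dh[served]) - nearest[served])
                others = ~served
                delta += np.sum(np.minimum(dh[others] - nearest[others], 0.0))
                if delta < best_delta:
                    best_delta, best_swap = delta, (mi, h)
        if best_swap is None:
            break
        mi, h = best_swap
        medoids[mi] = h
        medoids = np.sort(medoids)
    labels = np.argmin(D[:, medoids], axis=1)
    return labels.astype(np.int64)


def _clara(
    X: np.ndarray, k: int, seed: int, n_draws: int = 5, sample_size: int | None = None
) -> np.ndarray:
    """CLARA: PAM on random subsamples, keeping the best full-data cost."""
    n = X.shape[0]
    if sample_size is None:
        sample_size = min(n, 40 + 2 * k)
    rng = np.random.default_rng(seed)
    best_cost, best_medoids = np.inf, None
    for _ in range(n_draws):
        idx = rng.choice(n, size=sample_size, replace=False)
        sub_D = cdist(X[idx], X[idx])
        sub_labels = _pam(sub_D, k)
        # medoid of each subcluster, mapped back to full indices
        medoids = []
        for c in range(k):
            members = idx[sub_labels == c]
            if members.size == 0:
                continue
            local = cdist(X[members], X[members]).sum(axis=1)
            medoids.append(int(members[local.argmin()]))
        if len(medoids) < k:
            continue
        d_full = cdist(X, X[medoids])
        cost = float(d_full.min(axis=1).sum())
        if cost < best_cost:
            best_cost, best_medoids = cost, medoids
    d_full = cdist(X, X[best_medoids])
    return d_full.argmin(axis=1).astype(np.int64)


# ---------------------------------------------------------------------------
# Baseline dispatch
# ---------------------------------------------------------------------------

def run_baseline(
    m: MethodSpec,
    X: FeatureMatrix,
    D: DistanceMatrix,
    k: int,
    seed: int,
) -> ClusterLabels:
    """Run one standalone method and return its labels.

    Ward-linkage agglomeration is cut at ``k`` on the distance matrix;
    k-means and spectral clustering run on the feature matrix; PAM runs on
    the distance matrix and CLARA on the feature matrix.  All runs are
    deterministic given ``seed``.
    """
    if k < 2:
        raise SillyPuttyError("need k >= 2")
    name = m.name
    params = dict(m.params)
    if name == "hierarchical_ward":
        Z = linkage(squareform(D.values, checks=False), method="ward")
        labels = fcluster(Z, t=k, criterion="maxclust") - 1
    elif name == "kmeans":
        km = KMeans(n_clusters=k, n_init=params.get("n_init", 100), random_state=seed)
        labels = km.fit_predict(X.values)
    elif name == "pam":
        labels = _pam(D.values, k)
    elif name == "clara":
        labels = _clara(
            X.values, k, seed,
            n_draws=params.get("n_draws", 5),
            sample_size=params.get("sample_size"),
        )
    elif name == "spectral":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sc = SpectralClustering(
                n_clusters=k,
                affinity="nearest_neighbors",
                n_neighbors=params.get("n_neighbors", 10),
                random_state=seed,
                assign_labels="kmeans",
            )
            labels = sc.fit_predict(X.values)
    elif name == "sillyputty_random":
        cfg = SillyPuttyConfig(
            n_starts=params.get("n_starts", 100),
            max_iter=params.get("max_iter", 1000),
            seed=seed,
        )
        return sillyputty_random(D, k, cfg).labels
    else:
        raise SillyPuttyError(f"{name!r} is not a standalone method")
    return ClusterLabels(np.asarray(labels), D.sample_ids)


# ---------------------------------------------------------------------------
# Grid runner
# ---------------------------------------------------------------------------

@dataclass
class BenchmarkTable:
    """Per-cell results plus per-method aggregates."""

    cells: pd.DataFrame

    def aggregate(self) -> pd.DataFrame:
        """Per-method means of SW/ARI/NWSS/entropy and summed PCC."""
        ok = self.cells[self.cells["error"].isna()]
        agg = ok.groupby("method").agg(
            sw=("asw", "mean"),
            ari=("ari", "mean"),
            nwss=("nwss", "mean"),
            entropy=("entropy", "mean"),
            pcc=("perfect", "sum"),
            n_cells=("ari", "size"),
        )
        return agg

    def mean_ari(self, method: str) -> float:
        ok = self.cells[(self.cells["method"] == method) & self.cells["error"].isna()]
        return float(ok["ari"].mean())

    def perfect_rate(self, method: str) -> float:
        """Fraction of datasets the method recovered exactly."""
        ok = self.cells[(self.cells["method"] == method) & self.cells["error"].isna()]
        return float(ok["perfect"].mean())

    def to_tsv(self, path: Path | str) -> None:
        self.cells.to_csv(path, sep="\t", index=False)


def _cell_key(cfg: SimulationConfig, m: MethodSpec) -> str:
    payload = json.dumps([asdict(cfg), m.name, sorted(m.params.items())], sort_keys=True)
    return hashlib.sha1(payload.encode()).hexdigest()


def _run_method(
    m: MethodSpec,
    ds: SimulatedDataset,
    D: DistanceMatrix,
    silly_params: dict,
) -> ClusterLabels:
    cfg = ds.config
    if m.name == "truth":
        return ds.truth
    if m.is_hybrid:
        base = MethodSpec(m.base_method, m.params)
        init = run_baseline(base, ds.X, D, cfg.k, _method_seed(cfg.seed, m.base_method))
        sp_cfg = SillyPuttyConfig(
            max_iter=silly_params.get("max_iter", 1000),
            seed=_method_seed(cfg.seed, m.name),
        )
        return sillyputty_warm(D, init, sp_cfg).labels
    if m.name == "sillyputty_random":
        params = {**silly_params, **m.params}
        spec = MethodSpec(m.name, params)
        return run_baseline(spec, ds.X, D, cfg.k, _method_seed(cfg.seed, m.name))
    return run_baseline(m, ds.X, D, cfg.k, _method_seed(cfg.seed, m.name))


def run_benchmark(
    grid: Sequence[SimulationConfig],
    methods: Sequence[MethodSpec],
    cache_dir: Path | str | None = None,
    silly_params: dict | None = None,
    progress: Callable[[str], None] | None = None,
) -> BenchmarkTable:
    """Simulate every grid cell and score every method on it.

    Per-cell failures are recorded in the ``error`` column rather than
    aborting the run.  If ``cache_dir`` is given, each (config, method)
    cell is cached as JSON keyed by its parameters, making reruns
    resumable.
    """
    if not grid or not methods:
        raise SillyPuttyError("grid and methods must be nonempty")
    silly_params = silly_params or {}
    cache = Path(cache_dir) if cache_dir is not None else None
    if cache is not None:
        cache.mkdir(parents=True, exist_ok=True)

    rows = []
    for cfg in grid:
        ds: SimulatedDataset | None = None
        D: DistanceMatrix | None = None
        for m in methods:
            meta = {
                "method": m.name,
                "k": cfg.k,
                "noise": cfg.noise_level,
                "n_samples": cfg.effective_n_samples,
                "n_features": cfg.effective_n_features,
                "seed": cfg.seed,
            }
            key = _cell_key(cfg, m) + ".json"
            if cache is not None and (cache / key).exists():
                rows.append(json.loads((cache / key).read_text()))
                continue
            if ds is None:
                ds = simulate_dataset(cfg)
                D = euclidean_distances(ds.X)
            try:
                labels = _run_method(m, ds, D, silly_params)
                report = evaluate_clustering(ds.X, D, labels, ds.truth)
                row = {**meta, **report.to_dict(), "error": None}
            except Exception as exc:  # recorded, not fatal
                row = {
                    **meta,
                    "asw": np.nan, "ari": np.nan, "entropy": np.nan,
                    "wss": np.nan, "nwss": np.nan, "perfect": False,
                    "error": f"{type(exc).__name__}: {exc}",
                }
            rows.append(row)
            if cache is not None:
                (cache / key).write_text(json.dumps(row))
            if progress is not None:
                progress(f"{m.name} k={cfg.k} noise={cfg.noise_level} ari={row['ari']}")
    cells = pd.DataFrame(rows)
    cells["error"] = cells["error"].astype(object)
    return BenchmarkTable(cells)
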