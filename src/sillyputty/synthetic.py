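"""Cluster-structured expression-like data with known ground truth.

The generator emulates log-scale transcriptomic data with an additive
noise model: the observed value is ``Y_gi = S_gi + e_gi`` where ``S`` is a
block-signature true signal and ``e_gi ~ N(nu, tau_g)``, with ``nu = 0.1``
and the per-feature noise SD ``tau_g`` drawn from a gamma distribution
whose mean sets the difficulty (low / medium / high presets).

The signal is transparent by design: each feature has a baseline
log-expression level shared by all samples, and each cluster owns a
disjoint *signature block* of features shifted by ``+-signal_amplitude``
(sign drawn per feature, shared by all samples of the cluster).  Samples
are assigned to clusters as evenly as possible.  The study grid
(:func:`table1_grid`) spans k in {3, 6, 12}, n in {600, 1000}, F in
{5000, 10000} and the three noise levels, in 27 combinations; a ``scale``
factor shrinks n and F proportionally for desk-scale runs.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from typing import Literal

import numpy as np

from .exceptions import SimulationError
from .matrix import ClusterLabels, FeatureMatrix

__all__ = [
    "NOISE_PRESETS",
    "SimulationConfig",
    "SimulatedDataset",
    "simulate_dataset",
    "table1_grid",
    "TABLE1_ROWS",
]

#: Mean of the gamma distribution of per-feature noise SDs, per preset.
#: Calibrated (see docs/methods.md) so that at desk scale the low preset is
#: near-perfectly separable, medium is intermediate, high is genuinely hard.
NOISE_PRESETS: dict[str, float] = {"low": 0.195, "medium": 0.2125, "high": 0.7}

NoiseLevel = Literal["low", "medium", "high"]


@dataclass(frozen=True)
class SimulationConfig:
    """One cell of the simulation grid.

    ``tau_mean`` defaults to the preset value for ``noise_level`` but can be
    overridden for calibration sweeps.  ``scale`` multiplies ``n_samples``
    and ``n_features`` (rounded) for reduced-scale runs.
    """

    k: int
    n_samples: int
    n_features: int
    noise_level: NoiseLevel = "low"
    signature_fraction: float = 0.10
    signal_amplitude: float = 1.0
    nu: float = 0.1
    tau_mean: float | None = None
    tau_shape: float = 2.0
    seed: int = 0
    scale: float = 1.0

    def __post_init__(self) -> None:
        if self.k < 2:
            raise SimulationError("need at least 2 clusters")
        if not (0 < self.signature_fraction <= 1):
            raise SimulationError("signature_fraction must be in (0, 1]")
        if not (0 < self.scale <= 1):
            raise SimulationError("scale must be in (0, 1]")
        if self.effective_tau_mean <= 0 or self.tau_shape <= 0:
            raise SimulationError("tau_mean and tau_shape must be positive")
        if self.effective_n_samples < self.k:
            raise SimulationError(
                f"{self.effective_n_samples} samples cannot hold {self.k} clusters"
            )
        if self.effective_n_features < 1:
            raise SimulationError("scaled feature count is zero")

    @property
    def effective_n_samples(self) -> int:
        return int(round(self.n_samples * self.scale))

    @property
    def effective_n_features(self) -> int:
        return int(round(self.n_features * self.scale))

    @property
    def effective_tau_mean(self) -> float:
        if self.tau_mean is not None:
            return self.tau_mean
        return NOISE_PRESETS[self.noise_level]

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


@dataclass(frozen=True)
class SimulatedDataset:
    """Observed matrix, true signal, truth labels, and the config that made them."""

    X: FeatureMatrix
    S: FeatureMatrix
    truth: ClusterLabels
    config: SimulationConfig


def simulate_dataset(cfg: SimulationConfig) -> SimulatedDataset:
    """Draw one dataset from the block-signature noise model.

    Deterministic given ``cfg.seed``: same seed, bit-identical output.
    """
    n, F, k = cfg.effective_n_samples, cfg.effective_n_features, cfg.k
    rng = np.random.default_rng(cfg.seed)

    block = math.ceil(cfg.signature_fraction * F / k)
    if k * block > F:
        raise SimulationError(
            f"signature blocks ({k} x {block}) do not fit in {F} features"
        )

    # baseline log-expression level per feature, shared across samples
    base = rng.normal(loc=6.0, scale=1.5, size=F)

    # disjoint signature block per cluster, +-amplitude shift per feature
    perm = rng.permutation(F)
    blocks = [perm[c * block : (c + 1) * block] for c in range(k)]
    signs = rng.choice([-1.0, 1.0], size=(k, block))

    # balanced assignment, shuffled
    truth = np.arange(n) % k
    rng.shuffle(truth)

    S = np.tile(base, (n, 1))
    for c in range(k):
        members = truth == c
        S[np.ix_(members, blocks[c])] += signs[c] * cfg.signal_amplitude

    tau = rng.gamma(shape=cfg.tau_shape, scale=cfg.effective_tau_mean / cfg.tau_shape, size=F)
    eps = rng.normal(loc=cfg.nu, scale=tau[None, :], size=(n, F))

    sample_ids = tuple(f"S{i + 1:04d}" for i in range(n))
    feature_ids = tuple(f"G{g + 1:05d}" for g in range(F))
    return SimulatedDataset(
        X=FeatureMatrix(S + eps, sample_ids, feature_ids),
        S=FeatureMatrix(S, sample_ids, feature_ids),
        truth=ClusterLabels(truth, sample_ids),
        config=cfg,
    )


#: The 27 (k, noise, n_samples, n_features) study combinations, in grid
#: order.  Not a full factorial: the high-noise level appears only at
#: n = 1000, F = 10000, once per cluster count.
TABLE1_ROWS: tuple[tuple[int, str, int, int], ...] = (
    (12, "high", 1000, 10000),
    (12, "low", 1000, 10000),
    (12, "low", 1000, 5000),
    (12, "low", 600, 10000),
    (12, "low", 600, 5000),
    (12, "medium", 1000, 10000),
    (12, "medium", 1000, 5000),
    (12, "medium", 600, 10000),
    (12, "medium", 600, 5000),
    (3, "high", 1000, 10000),
    (3, "low", 1000, 10000),
    (3, "low", 1000, 5000),
    (3, "low", 600, 10000),
    (3, "low", 600, 5000),
    (3, "medium", 1000, 10000),
    (3, "medium", 1000, 5000),
    (3, "medium", 600, 10000),
    (3, "medium", 600, 5000),
    (6, "high", 1000, 10000),
    (6, "low", 1000, 10000),
    (6, "low", 1000, 5000),
    (6, "low", 600, 10000),
    (6, "low", 600, 5000),
    (6, "medium", 1000, 10000),
    (6, "medium", 1000, 5000),
    (6, "medium", 600, 10000),
    (6, "medium", 600, 5000),
)


def table1_grid(
    scale: float = 1.0,
    replicates: int = 1,
    base_seed: int = 0,
    **overrides,
) -> list[SimulationConfig]:
    """The 27-combination study grid, each combination replicated.

    Every config gets a distinct seed derived from ``base_seed``; replicates
    of the same combination are adjacent in the returned list.  Extra
    keyword arguments override :class:`SimulationConfig` fields uniformly
    (useful for calibration sweeps).
    """
    if not (0 < scale <= 1):
        raise SimulationError("scale must be in (0, 1]")
    if replicates < 1:
        raise SimulationError("replicates must be >= 1")
    seeds = np.random.SeedSequence(base_seed).generate_state(27 * replicates) & 0x7FFFFFFF
    configs = []
    i = 0
    for k, noise, n, f in TABLE1_ROWS:
        for _ in range(replicates):
            configs.append(
                SimulationConfig(
                    k=k,
                    n_samples=n,
                    n_features=f,
                    noise_level=noise,  # type: ignore[arg-type]
                    seed=int(seeds[i]),
                    scale=scale,
                    **overrides,
                )
            )
            i += 1
    return configs
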