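# Methods

## The refinement heuristic

Given a symmetric dissimilarity matrix `D` over `n` samples and a labeling
into `k ≥ 2` clusters, each sample's silhouette width is
`s = (b − a) / max(a, b)`, where `a` is the mean distance to the *other*
members of its own cluster (divisor `m − 1`, self excluded) and `b` is the
smallest mean distance to the members of any foreign cluster. The
refinement loop is greedy and single-moved: at the top of each iteration
the full profile is recomputed; if `min(s) ≥ 0` the run has converged;
otherwise the sample attaining `min(s)` is reassigned to the cluster
attaining its `b` and the loop repeats. Because only one sample moves per
iteration and the profile is recomputed in full, the trajectory is exactly
reproducible and the per-move bookkeeping (who moved, from/to, `min(s)`,
ASW) is kept as a trace.

The heuristic *locally* improves the moved sample (its new cohesion equals
its former separation, so its own silhouette strictly increases), but the
global ASW is not monotone per move; the loop can cycle. Three halting
rules therefore apply: convergence (`min(s) ≥ 0`), an iteration cap, and
cycle detection — the silhouette vector, rounded to 12 decimals, is
compared against a ring buffer of the previous `loop_window` vectors. On
cap or cycle termination the best-ASW state seen during the run is
returned; on convergence the converged state itself is returned (these can
differ, since the converged state need not have the highest ASW
encountered).

Assumptions: the method sees only `D`; it inherits the silhouette's
cluster model (compact, mutually separated groups under the chosen
metric), is scale-invariant in `D`, and requires `k ≥ 2` throughout.

### Conventions and degenerate cases

* **Singletons.** A sample alone in its cluster has `s = 0` and undefined
  `a` (stored as NaN), Rousseeuw's convention and the one used by R's
  `cluster::silhouette`. This matters structurally: `0` is non-negative,
  so the loop never selects a singleton, a cluster can never be emptied of
  its last member, and `k` can never collapse to 1 during a run. The
  guards for those conditions exist but are defensive.
* **Ties.** Equal minimal silhouettes: the lowest sample index moves.
  Equal separations: the lowest cluster id wins. Both are deterministic
  and seed-independent.
* **Coincident points.** If `a = b = 0` (duplicated points split across
  clusters) the silhouette is defined as 0.
* **ASW** is the unweighted mean of `s` over all samples, singletons
  included.

### Tunable parameters

| parameter | default | role |
|---|---|---|
| `max_iter` | 1000 | hard cap on moves; generous — converged runs at `n ≤ 1000` use far fewer |
| `loop_window` | 20 | cycle-detection window; cycles observed in practice are short (2–10 states) |
| `n_starts` | 100 | random restarts for the standalone driver; the benchmark uses 20 at desk scale |
| `seed` | none | root seed; restarts draw from spawned child seeds, so the fan-out is reproducible and parallelizable |

Random initial partitions deal one sample to each of the `k` clusters
first, then assign the rest uniformly, so every start has exactly `k`
nonempty clusters.

## Distances

Euclidean and correlation (1 − Pearson `r` between sample rows) distances
are computed exactly in double precision — the loop compares mean
distances, so approximate neighbor methods are not used. Precomputed
matrices are accepted with an asymmetry tolerance of 1e-6 (below it the
matrix is silently symmetrized and the diagonal zeroed; decimal text
round-trips otherwise fail spuriously); asymmetry above tolerance,
negative entries, or non-finite values are errors. Features are *not*
standardized before Euclidean distances anywhere in the benchmark; the
simulated features share a common scale by construction, and
standardization would reweight the informative blocks.

## Validity indices

* **ARI** — pair-counting agreement corrected for chance; computed via
  scikit-learn, cross-checked in the tests against an explicit
  pair-enumeration implementation.
* **Normalized entropy** — for each predicted cluster, the entropy of its
  ground-truth composition normalized by `log K` (`K` = number of truth
  classes, natural logs; the normalizer makes the base cancel), weighted
  by cluster size and summed. `0 log 0 = 0`. One index pitfall is
  resolved explicitly: the per-cluster sum runs over *truth classes
  within a predicted cluster*, so a perfect clustering scores 0 and a
  cluster containing all truth classes in equal parts contributes exactly 1.
* **WSS / NWSS** — within-cluster sum of squared distances to centroids;
  NWSS divides by the WSS of the true labels (exactly 1 at the truth;
  slightly below 1 is possible when a competing partition has lower WSS
  than the generative truth on a noisy draw).
* **Perfect classification** — ARI within 1e-12 of 1, counted over a
  batch of datasets (PCC).

## The synthetic-data generator

The generator emulates log-scale expression data with cluster structure:
`Y = S + ε` with `ε ~ N(ν, τ_g)`, `ν = 0.1`, and per-feature noise SD
`τ_g ~ Gamma(shape 2, mean set by the noise preset)`. The signal `S` is
transparent by design: a per-feature baseline level (`N(6, 1.5)`, shared
by all samples, hence irrelevant to distances), plus one disjoint
*signature block* of `⌈0.1 F / k⌉` features per cluster shifted by ±1
(sign drawn per feature, shared within the cluster) for that cluster's
samples. Samples are assigned to clusters as evenly as possible. The
study grid covers 27 combinations of k ∈ {3, 6, 12}, n ∈ {600, 1000},
F ∈ {5000, 10000} and three noise levels (high noise occurs only at
n = 1000, F = 10000, once per k); a `scale` factor shrinks n and F
proportionally for desk-scale runs.

**Noise presets.** The preset means of the `τ` distribution are
calibrated, not inherited: low = 0.195, medium = 0.2125, high = 0.70,
chosen from a sweep over all twelve (k, n, F) cell types at scale 0.1 so
that the low regime is near-perfectly separable for every cluster count,
the medium regime stays separable for k ≤ 6 but visibly degrades k = 12,
and the high regime defeats k ≥ 6 entirely while leaving k = 3 imperfect.
This reproduces the qualitative difficulty ordering of the full-scale
study (accuracy non-increasing in noise and in cluster count) at desk
scale. The absolute values are meaningful only relative to the ±1
signature amplitude and the 10% signature fraction, and — because the
signal-to-noise ratio of a mean-distance comparison grows with the
signature block size, i.e. with `F/k` — the same presets at a different
`scale` give a different difficulty profile.

**What the generator does not emulate.** Real expression data have
correlated genes, heavy-tailed and mean-dependent variability, unbalanced
cluster prevalences, batch structure, and markers shared across clusters;
this generator has independent features, Gaussian additive noise, balanced
clusters, and disjoint signatures. Passing benchmarks here demonstrates
correct algorithmic behavior under the stated noise law, not performance
on real tissue data. An option for Dirichlet-weighted (unbalanced)
cluster sizes is deliberately absent; balanced assignment keeps every
cell of the grid feasible at small `n`.

## Benchmark harness

Baselines are delegated where a maintained implementation exists: Ward
linkage (scipy, cut at the true k), k-means and spectral clustering
(scikit-learn). Spectral clustering uses a nearest-neighbors affinity
(10 neighbors): on log-expression-scale squared distances the default RBF
kernel at unit bandwidth underflows to an all-zero affinity. k-means runs
with 100 restarts — with twelve small clusters the default 10 lose to
local optima far more often than a strong baseline should. PAM
(greedy BUILD + steepest-descent SWAP on the distance matrix) and CLARA
(PAM on five subsamples of size `min(n, 40 + 2k)`, keeping the medoid set
with the best full-data cost) are implemented in-package; no installed
library provides them. Hybrids rerun the base method with the same
derived seed as its standalone row — so a hybrid differs from its base
only by refinement — and per-method seeds derive from the dataset seed,
so all methods see identical data. Per-cell failures are recorded, not
fatal, and cells can be cached to disk keyed by (config, method), making
long runs resumable.

Problem sizes: the shipped benchmark and the acceptance script run the
grid at scale 0.1 (60–100 samples, 500–1000 features) with 3 replicates
per combination — 81 datasets — and 20 random starts for the standalone
refiner; these sizes keep a full comparison of eleven methods around a
minute on one CPU while preserving every qualitative contrast of the
full-scale study.

## Known limitations

* The refiner is a local heuristic on a non-convex objective: it can
  return silhouette-suboptimal fixed points, and with few restarts the
  standalone driver inherits that variance.
* One sample moves per iteration with a full profile recomputation —
  O(n²) per move. Incremental recomputation of only the two affected
  clusters would be bit-identical and faster, but is not implemented.
* `k` is taken as known; the package does not select it.
* At desk scale, k-means' within-cluster sum of squares optimum genuinely
  departs from the generative truth on the noisy k = 12 cells, so its
  benchmark mean is lower, relative to the refiner, than a full-scale run
  would show; restart counts beyond ~100 do not close the gap.
* The sharp k = 12 difficulty cliff (signature blocks shrink as 1/k and
  scaled clusters hold 5–8 samples) means aggregate scores at scale 0.1
  are dominated by those cells; moving between nearby noise presets mostly
  moves the k = 12 column.
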