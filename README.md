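# sillyputty

Silhouette-width-driven clustering for expression-like data, with the
validity indices, a ground-truth simulator, and a benchmark harness used to
evaluate it.

## The idea

The silhouette width scores how well each individual sample sits in its
assigned cluster. For a sample *x<sub>i</sub>* with cohesion
*a(x<sub>i</sub>)* (mean distance to the other members of its cluster) and
separation *b(x<sub>i</sub>)* (smallest mean distance to any foreign
cluster),

> *s(x<sub>i</sub>)* = (*b* − *a*) / max(*a*, *b*) ∈ [−1, 1].

Negative *s* means the sample is closer, on average, to another cluster
than to its own. Most pipelines only look at the mean silhouette width
(ASW) as a global quality score; this package treats the per-sample values
as *actionable*: starting from any labeling, it repeatedly finds the sample
with the most negative silhouette width and moves it to its nearest foreign
cluster (the cluster attaining its *b*), recomputing the full profile after
every move. The loop halts when every width is non-negative, when an
iteration cap is reached, or when the silhouette vector recurs within a
sliding window (a cycle); on cap/cycle termination the best-ASW state seen
is returned.

Two drivers are provided: a standalone one that refines many random
partitions and keeps the best final ASW, and a *warm-start* (hybrid) one
that refines the labels of any other algorithm — in practice,
Ward-linkage hierarchical clustering followed by silhouette refinement is
both fast and the most accurate combination in our benchmark.

The heuristic only ever sees a distance matrix, so it works with Euclidean
distances on log-expression features, correlation distance (1 − Pearson
*r*), or any precomputed symmetric dissimilarity.

## Worked example

```python
from sillyputty import (SimulationConfig, simulate_dataset, SillyPutty,
                        euclidean_distances, evaluate_clustering)

# 90 samples x 300 genes, 3 clusters, medium additive noise, known truth
cfg = SimulationConfig(k=3, n_samples=90, n_features=300,
                       noise_level="medium", seed=17)
data = simulate_dataset(cfg)

model = SillyPutty.from_features(data.X, n_clusters=3, n_starts=20, seed=17)
res = model.fit()
print(res.summary())
```

```
Silhouette-refinement clustering results
============================================
samples:            90
clusters (final):   3
cluster sizes:      {0: 30, 1: 30, 2: 30}
ASW (final):        0.156670
ASW (initial):      -0.010273
min silhouette:     0.076139
iterations (moves): 56
termination:        converged
random starts:      20
```

The best of 20 random starts converged after 56 single-sample moves: every
sample now has a non-negative silhouette width, and the ASW rose from
−0.01 (its random start) to 0.157. Scoring against the simulation's ground
truth:

```python
D = euclidean_distances(data.X)
print(evaluate_clustering(data.X, D, res.labels, data.truth).to_dict())
```

```
{'asw': 0.1567, 'ari': 1.0, 'entropy': 0.0, 'wss': 2128.1767,
 'nwss': 1.0, 'perfect': True}
```

ARI = 1 and entropy = 0 mean the recovered partition equals the truth up
to relabeling; NWSS = 1 means its within-cluster sum of squares matches
the true assignment's.

A warm start from another method is one argument away:

```python
res = SillyPutty(D, init_labels=ward_labels).fit()   # hybrid refinement
```

## Command line

```sh
sillyputty simulate --clusters 6 --samples 600 --features 10000 \
    --noise medium --seed 7 --out-prefix sim1
sillyputty cluster --matrix sim1.matrix.tsv --k 6 --starts 100 \
    --seed 1 --out result.json --labels-out labels.tsv
sillyputty evaluate --labels labels.tsv --truth sim1.truth.tsv \
    --matrix sim1.matrix.tsv --out report.json
sillyputty benchmark --scale 0.1 --replicates 3 --seed 42 --out bench/
```

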