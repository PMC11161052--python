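"""Independent brute-force reference implementations used only by tests.

Deliberately naive (explicit loops, direct formulas) so they share no code
path with the package.
"""

from __future__ import annotations

import math

import numpy as np


def naive_silhouette(D: np.ndarray, labels: np.ndarray):
    """Triple-loop silhouette profile. Returns (a, b, s, nearest_foreign)."""
    n = len(labels)
    clusters = sorted(set(int(c) for c in labels))
    a = np.full(n, np.nan)
    b = np.full(n, np.nan)
    s = np.zeros(n)
    nearest = np.zeros(n, dtype=int)
    for i in range(n):
        own = [j for j in range(n) if labels[j] == labels[i] and j != i]
        best_b, best_c = math.inf, None
        for c in clusters:
            if c == labels[i]:
                continue
            members = [j for j in range(n) if labels[j] == c]
            mean_d = sum(D[i][j] for j in members) / len(members)
            if mean_d < best_b:
                best_b, best_c = mean_d, c
        b[i], nearest[i] = best_b, best_c
        if not own:
            s[i] = 0.0  # singleton convention
            continue
        a[i] = sum(D[i][j] for j in own) / len(own)
        denom = max(a[i], b[i])
        s[i] = (b[i] - a[i]) / denom if denom > 0 else 0.0
    return a, b, s, nearest


def pair_counting_ari(x: np.ndarray, y: np.ndarray) -> float:
    """ARI by explicit enumeration of all sample pairs."""
    n = len(x)
    ss = sd = ds = dd = 0  # same/same, same/diff, diff/same, diff/diff
    for i in range(n):
        for j in range(i + 1, n):
            sx, sy = x[i] == x[j], y[i] == y[j]
            if sx and sy:
                ss += 1
            elif sx:
                sd += 1
            elif sy:
                ds += 1
            else:
                dd += 1
    total = ss + sd + ds + dd
    expected = (ss + sd) * (ss + ds) / total
    max_index = 0.5 * ((ss + sd) + (ss + ds))
    if max_index == expected:
        return 1.0
    return (ss - expected) / (max_index - expected)


def direct_entropy(pred: np.ndarray, truth: np.ndarray) -> float:
    """Normalized size-weighted entropy computed directly from the formulas."""
    n = len(pred)
    k_truth = len(set(int(t) for t in truth))
    total = 0.0
    for c in set(int(p) for p in pred):
        members = [i for i in range(n) if pred[i] == c]
        size = len(members)
        e = 0.0
        for t in set(int(t) for t in truth):
            cnt = sum(1 for i in members if truth[i] == t)
            if cnt:
                p = cnt / size
                e -= p * math.log(p)
        total += (size / n) * e / math.log(k_truth)
    return total


def naive_wss(X: np.ndarray, labels: np.ndarray) -> float:
    total = 0.0
    for c in set(int(v) for v in labels):
        block = X[np.asarray(labels) == c]
        mu = block.mean(axis=0)
        for row in block:
            total += float(np.sum((row - mu) ** 2))
    return total
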