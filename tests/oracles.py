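"""Independent brute-force oracles used to cross-check the library.

These deliberately recompute everything from first principles (exhaustive
enumeration, direct definitions) and share no code with the implementation
paths they validate.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def ward_oracle(points: np.ndarray) -> list[tuple[frozenset[int], float]]:
    """Exhaustive Ward agglomeration, recomputed from raw coordinates.

    At every step, for every cluster pair, the increase in total
    within-cluster sum of squares caused by the merge is recomputed from
    scratch; the cheapest pair merges.  Heights use the convention
    height = sqrt(2 * delta-SSE) (equal to the Euclidean distance for two
    singletons).  Returns [(leaf set of new cluster, height), ...].
    """
    points = np.asarray(points, dtype=float)
    clusters: list[frozenset[int]] = [frozenset([i]) for i in range(len(points))]
    merges = []
    while len(clusters) > 1:
        best = None
        for a, b in combinations(range(len(clusters)), 2):
            ia, ib = sorted(clusters[a]), sorted(clusters[b])
            pa, pb = points[ia], points[ib]
            union = np.vstack([pa, pb])

            def sse(x):
                return float(np.sum((x - x.mean(axis=0)) ** 2))

            delta = sse(union) - sse(pa) - sse(pb)
            if best is None or delta < best[0]:
                best = (delta, a, b)
        delta, a, b = best
        merged = clusters[a] | clusters[b]
        clusters = [c for i, c in enumerate(clusters) if i not in (a, b)] + [merged]
        merges.append((merged, float(np.sqrt(2.0 * delta))))
    return merges


def regression_tree_oracle(x: np.ndarray, y: np.ndarray, max_depth: int) -> np.ndarray:
    """Predictions of an exhaustive-best-split variance-reduction tree.

    One feature only.  At each node every midpoint between consecutive
    distinct sorted feature values is tried; the split minimizing the
    summed child SSE wins, ties going to the lowest threshold.  Leaves
    predict the mean.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    out = np.empty_like(y)

    def grow(idx: np.ndarray, depth: int) -> None:
        yy = y[idx]
        if depth == max_depth or np.allclose(yy, yy[0]):
            out[idx] = yy.mean()
            return
        xs = np.unique(x[idx])
        if xs.size < 2:
            out[idx] = yy.mean()
            return
        best = None
        for t in (xs[:-1] + xs[1:]) / 2.0:
            left = idx[x[idx] <= t]
            right = idx[x[idx] > t]
            cost = sum(
                float(np.sum((y[s] - y[s].mean()) ** 2)) for s in (left, right) if s.size
            )
            if best is None or cost < best[0] - 1e-12:
                best = (cost, t, left, right)
        _, t, left, right = best
        grow(left, depth + 1)
        grow(right, depth + 1)

    grow(np.arange(len(y)), 0)
    return out


def ari_oracle(labels_a: np.ndarray, labels_b: np.ndarray) -> float:
    """Adjusted Rand index by direct pair counting over all item pairs."""
    labels_a = np.asarray(labels_a)
    labels_b = np.asarray(labels_b)
    n = len(labels_a)
    together_a = together_b = together_both = 0
    for i, j in combinations(range(n), 2):
        sa = labels_a[i] == labels_a[j]
        sb = labels_b[i] == labels_b[j]
        together_a += sa
        together_b += sb
        together_both += sa and sb
    n_pairs = n * (n - 1) // 2
    expected = together_a * together_b / n_pairs
    max_index = (together_a + together_b) / 2.0
    if max_index == expected:
        return 1.0
    return (together_both - expected) / (max_index - expected)


def boltzmann_dg_oracle(
    w_of_s, layer_start: float, delta: float, kBT: float, n: int = 200001
) -> float:
    """High-resolution trapezoidal Boltzmann average of an analytic PMF."""
    s = np.linspace(layer_start, layer_start + delta, n)
    integrand = np.exp(-np.asarray(w_of_s(s), dtype=float) / kBT)
    return float(-kBT * np.log(np.trapezoid(integrand, s) / delta))
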