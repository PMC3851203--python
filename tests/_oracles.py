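"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written from first principles (nested loops, literal
definitions, closed forms) and never calls into the code paths it checks.
"""

from __future__ import annotations

import numpy as np


def overlap_count_oracle(query_ivs, track_ivs) -> int:
    """O(n*m) all-pairs member-centric overlap count.

    ``*_ivs`` are (chrom, start, end) triples; half-open coordinates.
    """
    count = 0
    for qc, qs, qe in query_ivs:
        for tc, ts, te in track_ivs:
            if qc == tc and max(qs, ts) < min(qe, te):
                count += 1
                break
    return count


def bh_oracle(p: np.ndarray) -> np.ndarray:
    """Literal Benjamini-Hochberg step-up definition, O(m^2).

    adjusted(i) = min(1, min over j with rank(j) >= rank(i) of p_(j) * m / j).
    """
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    adj_sorted = np.empty(m)
    for i in range(m):
        candidates = [sorted_p[j] * m / (j + 1) for j in range(i, m)]
        adj_sorted[i] = min(1.0, min(candidates))
    out = np.empty(m)
    out[order] = adj_sorted
    return out


def pearson_oracle(x, y) -> float:
    """Textbook Pearson correlation via explicit sums."""
    x = list(map(float, x))
    y = list(map(float, y))
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    den = (
        sum((a - mx) ** 2 for a in x) ** 0.5 * sum((b - my) ** 2 for b in y) ** 0.5
    )
    return num / den


def chebyshev_oracle(u, v) -> float:
    """Maximum coordinate-wise absolute difference, by explicit loop."""
    return max(abs(float(a) - float(b)) for a, b in zip(u, v))


def _ward_cluster_distance(W: np.ndarray, A: tuple, B: tuple) -> float:
    """Closed-form Ward cluster dissimilarity from pairwise values.

    Treating the entries of ``W`` as squared Euclidean distances, the Ward
    criterion between clusters equals
    ``2 |A||B| / (|A|+|B|) * (cross - withinA - withinB)`` where ``cross`` is
    the mean pairwise value across clusters and ``within*`` are half the
    mean pairwise values inside each cluster.  This closed form reproduces
    the Lance-Williams Ward recurrence (initial cluster distance = matrix
    entry) without any iterative updates.
    """
    a, b = len(A), len(B)
    cross = sum(W[i][j] for i in A for j in B) / (a * b)
    within_a = sum(W[i][j] for i in A for j in A) / (2 * a * a)
    within_b = sum(W[i][j] for i in B for j in B) / (2 * b * b)
    return 2.0 * a * b / (a + b) * (cross - within_a - within_b)


def ward_oracle(D: np.ndarray, squared: bool = False):
    """Exhaustive-search Ward agglomeration recomputing the objective.

    At every step, evaluates the closed-form Ward criterion for every pair
    of current clusters from scratch and merges the minimum.  Returns a list
    of (leafset_a, leafset_b, height) in merge order.
    """
    D = np.asarray(D, dtype=float)
    W = D**2 if squared else D
    clusters: list[tuple[int, ...]] = [(i,) for i in range(len(D))]
    merges = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = _ward_cluster_distance(W, clusters[i], clusters[j])
                if best is None or d < best[0] - 1e-15:
                    best = (d, i, j)
        d, i, j = best
        height = float(np.sqrt(d)) if squared else float(d)
        merges.append((frozenset(clusters[i]), frozenset(clusters[j]), height))
        merged = tuple(sorted(clusters[i] + clusters[j]))
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [merged]
    return merges


def hypergeometric_moments(N: int, M: int, k: int) -> tuple[float, float]:
    """Closed-form mean and variance of the overlap count under sampling
    without replacement: k members from a pool of N containing M hits."""
    p = M / N
    mean = k * p
    var = k * p * (1 - p) * (N - k) / (N - 1)
    return mean, var
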