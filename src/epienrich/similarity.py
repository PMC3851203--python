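"""Profile similarity: Pearson correlation of class enrichment profiles,
best-partner reporting, and hierarchical clustering with Chebyshev
(maximum) distance and Ward agglomeration.

The Ward step is implemented as the classical Lance–Williams recurrence
applied to the supplied dissimilarities as-is (no pre-squaring) — the
behaviour historically associated with ``ward.D``.  A ``squared=True``
switch applies the recurrence to squared dissimilarities and reports square
roots of the merge criteria (``ward.D2``); on Euclidean distance matrices
that variant matches :func:`scipy.cluster.hierarchy.linkage` with
``method="ward"``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .matrixops import EnrichmentMatrix

__all__ = [
    "CorrelationMatrix",
    "Dendrogram",
    "pearson_profiles",
    "best_partners",
    "chebyshev_distances",
    "ward_linkage",
    "heatmap_export",
]


@dataclass(frozen=True)
class CorrelationMatrix:
    """Symmetric Pearson correlation matrix over class score profiles.

    Classes with a constant profile have undefined correlations; their rows
    and columns are NaN and their labels are listed in ``constant`` rather
    than being silently zero-filled.
    """

    labels: tuple[str, ...]
    r: np.ndarray
    constant: tuple[str, ...] = ()

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.r, index=list(self.labels), columns=list(self.labels))


@dataclass(frozen=True)
class Dendrogram:
    """Agglomerative merge history over named leaves.

    ``merges`` lists ``(id_a, id_b, height, size)``; leaves are numbered
    ``0 .. n-1`` in label order and the merge at step ``s`` creates cluster
    ``n + s``.  Heights are non-decreasing (Ward is monotone).
    """

    labels: tuple[str, ...]
    merges: tuple[tuple[int, int, float, int], ...]

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def heights(self) -> list[float]:
        return [m[2] for m in self.merges]

    def _children(self) -> dict[int, tuple[int, int]]:
        n = self.n_leaves
        return {n + s: (a, b) for s, (a, b, _, _) in enumerate(self.merges)}

    def leaves_of(self, node: int) -> list[int]:
        children = self._children()

        def rec(i: int) -> list[int]:
            if i < self.n_leaves:
                return [i]
            a, b = children[i]
            return rec(a) + rec(b)

        return rec(node)

    def leaf_order(self) -> list[str]:
        """Left-to-right leaf labels of the drawn tree."""
        if not self.merges:
            return list(self.labels)
        root = self.n_leaves + len(self.merges) - 1
        return [self.labels[i] for i in self.leaves_of(root)]

    def first_bipartition(self) -> tuple[frozenset, frozenset]:
        """Leaf-label sets of the two subtrees below the root."""
        if not self.merges:
            raise ValueError("dendrogram has no merges")
        a, b, _, _ = self.merges[-1]
        left = frozenset(self.labels[i] for i in self.leaves_of(a))
        right = frozenset(self.labels[i] for i in self.leaves_of(b))
        return left, right

    def to_linkage(self) -> np.ndarray:
        """SciPy-style (n-1, 4) linkage array for plotting interop."""
        return np.array([[a, b, h, s] for a, b, h, s in self.merges], dtype=float)

    def to_newick(self) -> str:
        """Newick string; branch lengths are parent-height minus child-height."""
        children = self._children()
        height = {i: 0.0 for i in range(self.n_leaves)}
        for s, (_, _, h, _) in enumerate(self.merges):
            height[self.n_leaves + s] = h

        def rec(i: int, parent_h: float) -> str:
            bl = parent_h - height[i]
            if i < self.n_leaves:
                return f"{self.labels[i]}:{bl:.10g}"
            a, b = children[i]
            return f"({rec(a, height[i])},{rec(b, height[i])}):{bl:.10g}"

        if not self.merges:
            return (self.labels[0] + ";") if self.labels else ";"
        root = self.n_leaves + len(self.merges) - 1
        a, b = children[root]
        h = height[root]
        return f"({rec(a, h)},{rec(b, h)});"


def pearson_profiles(
    matrix: EnrichmentMatrix,
    alpha: float = 0.01,
    tracks: Sequence[str] | None = None,
) -> CorrelationMatrix:
    """Pairwise Pearson correlation of class score profiles.

    By default profiles run over the tracks significant (``p_adj < alpha``)
    in at least one class — the presence-filtered set, without the flatness
    rule.  An explicit ``tracks`` selection overrides that rule.  At least 3
    tracks are required; classes whose profile is constant over the selected
    tracks get NaN correlations and are flagged.
    """
    if tracks is None:
        tracks = [
            t for t in matrix.track_labels if bool((matrix.p_adj[t] < alpha).any())
        ]
    tracks = list(tracks)
    if len(tracks) < 3:
        raise ValueError(f"need >= 3 tracks for profile correlation, got {len(tracks)}")
    X = matrix.scores[tracks].to_numpy(dtype=float)
    labels = tuple(matrix.class_labels)
    centered = X - X.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered**2).sum(axis=1))
    defined = norms > 0
    r = np.full((len(labels), len(labels)), np.nan)
    if defined.any():
        sub = centered[defined] / norms[defined, None]
        block = np.clip(sub @ sub.T, -1.0, 1.0)
        idx = np.flatnonzero(defined)
        r[np.ix_(idx, idx)] = block
        r[idx, idx] = 1.0
    constant = tuple(lab for lab, d in zip(labels, defined) if not d)
    return CorrelationMatrix(labels=labels, r=r, constant=constant)


def best_partners(corr: CorrelationMatrix) -> pd.DataFrame:
    """Per class, the best-correlated and best-anticorrelated other class.

    Ties break toward the earlier label in matrix order; undefined (NaN)
    entries are excluded from the argmax/argmin.  Returns a DataFrame with
    columns class, best_partner, best_r, worst_partner, worst_r.
    """
    n = len(corr.labels)
    if n < 2:
        raise ValueError("need >= 2 classes for partner analysis")
    rows = []
    for i, lab in enumerate(corr.labels):
        candidates = [
            (j, corr.r[i, j]) for j in range(n) if j != i and np.isfinite(corr.r[i, j])
        ]
        if not candidates:
            rows.append((lab, None, np.nan, None, np.nan))
            continue
        best_j, best_r = max(candidates, key=lambda jr: (jr[1], -jr[0]))
        worst_j, worst_r = min(candidates, key=lambda jr: (jr[1], jr[0]))
        rows.append((lab, corr.labels[best_j], best_r, corr.labels[worst_j], worst_r))
    return pd.DataFrame(
        rows, columns=["class", "best_partner", "best_r", "worst_partner", "worst_r"]
    )


def chebyshev_distances(vectors, axis: str = "rows") -> np.ndarray:
    """Pairwise maximum (Chebyshev) distances between rows or columns."""
    X = np.asarray(
        vectors.to_numpy() if isinstance(vectors, pd.DataFrame) else vectors,
        dtype=float,
    )
    if axis == "columns":
        X = X.T
    elif axis != "rows":
        raise ValueError("axis must be 'rows' or 'columns'")
    if X.shape[0] < 2:
        raise ValueError("need >= 2 vectors")
    return squareform(pdist(X, metric="chebyshev"))


def ward_linkage(
    dist: np.ndarray,
    labels: Sequence[str] | None = None,
    *,
    squared: bool = False,
) -> Dendrogram:
    """Agglomerative Ward clustering of a precomputed distance matrix.

    Repeatedly merges the pair of clusters at minimal current dissimilarity
    and updates distances to every other cluster by the Lance–Williams Ward
    recurrence::

        d(k, i+j) = [(n_i + n_k) d(k, i) + (n_j + n_k) d(k, j)
                     - n_k d(i, j)] / (n_i + n_j + n_k)

    With ``squared=False`` the recurrence runs on the distances as given;
    with ``squared=True`` it runs on their squares and merge heights are the
    square roots of the merge criteria.  Ties break toward the smallest
    cluster-id pair.
    """
    D = np.asarray(dist, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    n = D.shape[0]
    if n < 2:
        raise ValueError("need >= 2 leaves")
    if not np.allclose(D, D.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(D), 0.0, atol=1e-8):
        raise ValueError("distance matrix must have a zero diagonal")
    if labels is None:
        labels = [str(i) for i in range(n)]
    if len(labels) != n:
        raise ValueError("labels length does not match matrix size")

    work = D.copy() ** 2 if squared else D.copy()
    np.fill_diagonal(work, np.inf)
    size = {i: 1 for i in range(n)}
    cluster_id = {i: i for i in range(n)}  # row slot -> current cluster id
    active = list(range(n))
    merges: list[tuple[int, int, float, int]] = []
    next_id = n
    for _ in range(n - 1):
        best = (np.inf, None, None)
        for ai in range(len(active)):
            for aj in range(ai + 1, len(active)):
                u, v = active[ai], active[aj]
                d = work[u, v]
                if d < best[0] - 1e-15:
                    best = (d, u, v)
        crit, u, v = best
        height = float(np.sqrt(crit)) if squared else float(crit)
        id_u, id_v = cluster_id[u], cluster_id[v]
        a, b = (id_u, id_v) if id_u <= id_v else (id_v, id_u)
        new_size = size[u] + size[v]
        merges.append((a, b, height, new_size))
        # Lance-Williams update written into slot u; slot v retired
        for k in active:
            if k in (u, v):
                continue
            work[u, k] = work[k, u] = (
                (size[u] + size[k]) * work[u, k]
                + (size[v] + size[k]) * work[v, k]
                - size[k] * crit
            ) / (size[u] + size[v] + size[k])
        active.remove(v)
        size[u] = new_size
        cluster_id[u] = next_id
        next_id += 1
    return Dendrogram(labels=tuple(str(l) for l in labels), merges=tuple(merges))


def heatmap_export(
    matrix: EnrichmentMatrix,
    row_dendro: Dendrogram | None,
    col_dendro: Dendrogram | None,
    path,
    *,
    cap: float | None = None,
    table_path=None,
) -> pd.DataFrame:
    """Write a diverging blue–yellow heatmap and the reordered score table.

    Rows/columns are reordered to the dendrogram leaf orders when given.
    The colour scale is symmetric about zero (blue = depleted, yellow =
    enriched); ``cap`` clips the *displayed/exported* values to ``[-cap,
    cap]`` for readability while the analysis matrix itself is untouched.
    Returns the reordered (and capped, if requested) DataFrame.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import LinearSegmentedColormap

    ordered = matrix.scores.copy()
    if row_dendro is not None:
        if set(row_dendro.labels) != set(ordered.index):
            raise ValueError("row dendrogram leaves do not match matrix classes")
        ordered = ordered.loc[row_dendro.leaf_order()]
    if col_dendro is not None:
        if set(col_dendro.labels) != set(ordered.columns):
            raise ValueError("column dendrogram leaves do not match matrix tracks")
        ordered = ordered[col_dendro.leaf_order()]
    if cap is not None:
        ordered = ordered.clip(lower=-abs(cap), upper=abs(cap))

    vmax = float(np.nanmax(np.abs(ordered.to_numpy()))) if ordered.size else 0.0
    if vmax == 0.0:
        vmax = 1.0  # all-zero matrix renders as the midpoint colour
    cmap = LinearSegmentedColormap.from_list(
        "blue_yellow", ["#2166ac", "#0b0b0b", "#ffd700"]
    )
    fig, ax = plt.subplots(
        figsize=(max(4.0, 0.25 * ordered.shape[1] + 2), max(3.0, 0.3 * ordered.shape[0] + 1.5))
    )
    im = ax.imshow(ordered.to_numpy(), cmap=cmap, vmin=-vmax, vmax=vmax, aspect="auto")
    ax.set_xticks(range(ordered.shape[1]))
    ax.set_xticklabels(ordered.columns, rotation=90, fontsize=5)
    ax.set_yticks(range(ordered.shape[0]))
    ax.set_yticklabels(ordered.index, fontsize=6)
    fig.colorbar(im, ax=ax, label="signed -log10(adjusted p)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    if table_path is not None:
        ordered.to_csv(table_path, sep="\t", index_label="class")
    return ordered
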