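"""Assembly and filtering of the classes-by-tracks signed-score matrix, and
per-class variability summaries.

The central object is :class:`EnrichmentMatrix`: rows are query classes,
columns are annotation tracks, and the three parallel layers hold the signed
-log10 adjusted p-values, the adjusted p-values themselves, and the test
directions.  Tracks can be dropped by two rules — no class significant at the
cutoff (presence rule), or a score standard deviation across classes below a
threshold (flatness rule) — while class rows are never removed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import EnrichmentResult, signed_score

__all__ = [
    "EnrichmentMatrix",
    "ClassVariability",
    "VariabilityReport",
    "assemble_matrix",
    "filter_tracks",
    "class_variability",
]


class EnrichmentMatrix:
    """Classes x tracks matrix of signed scores with parallel p_adj/direction.

    The three DataFrames share identical index (class labels) and columns
    (track labels).  ``scores[i, j]`` is reproducible from ``p_adj[i, j]``
    and ``directions[i, j]`` via :func:`epienrich.enrichment.signed_score`.
    """

    def __init__(
        self, scores: pd.DataFrame, p_adj: pd.DataFrame, directions: pd.DataFrame
    ) -> None:
        for layer, name in ((p_adj, "p_adj"), (directions, "directions")):
            if not layer.index.equals(scores.index) or not layer.columns.equals(
                scores.columns
            ):
                raise ValueError(f"layer {name} does not align with scores")
        self.scores = scores
        self.p_adj = p_adj
        self.directions = directions

    @property
    def class_labels(self) -> list[str]:
        return list(self.scores.index)

    @property
    def track_labels(self) -> list[str]:
        return list(self.scores.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.scores.shape

    def select_tracks(self, tracks: Sequence[str]) -> "EnrichmentMatrix":
        return EnrichmentMatrix(
            self.scores[list(tracks)], self.p_adj[list(tracks)], self.directions[list(tracks)]
        )

    def to_tsv(self, scores_path, sidecar_path=None) -> None:
        """Write scores as TSV; optionally a long-form sidecar of p_adj/direction."""
        self.scores.to_csv(scores_path, sep="\t", index_label="class")
        if sidecar_path is not None:
            long = (
                self.p_adj.stack()
                .rename("p_adj")
                .to_frame()
                .join(self.directions.stack().rename("direction"))
                .reset_index()
            )
            long.columns = ["class", "track", "p_adj", "direction"]
            long.to_csv(sidecar_path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, scores_path, sidecar_path) -> "EnrichmentMatrix":
        scores = pd.read_csv(scores_path, sep="\t", index_col="class")
        long = pd.read_csv(sidecar_path, sep="\t")
        p_adj = long.pivot(index="class", columns="track", values="p_adj")
        directions = long.pivot(index="class", columns="track", values="direction")
        p_adj = p_adj.loc[scores.index, scores.columns]
        directions = directions.loc[scores.index, scores.columns]
        p_adj.index.name = directions.index.name = scores.index.name
        return cls(scores, p_adj, directions)

    def __repr__(self) -> str:
        n, m = self.shape
        return f"EnrichmentMatrix({n} classes x {m} tracks)"


@dataclass(frozen=True, slots=True)
class ClassVariability:
    """Per-class spread of signed scores across all tracks."""

    class_label: str
    size: int
    score_sd: float


@dataclass(frozen=True, slots=True)
class VariabilityReport:
    """Class-size vs score-SD summary (the per-class variability analysis)."""

    table: pd.DataFrame  # columns: class, size, score_sd
    pearson_r: float
    pearson_p: float
    excluded: tuple[str, ...]
    pearson_r_excluded: float
    pearson_p_excluded: float


def assemble_matrix(results: Iterable[EnrichmentResult]) -> EnrichmentMatrix:
    """Arrange per-pair test results into a complete classes x tracks matrix.

    Rows and columns follow first-seen order.  Every (class, track) pair must
    appear exactly once; duplicates and gaps raise a ``ValueError`` naming
    the offending pair.
    """
    results = list(results)
    class_order: list[str] = []
    track_order: list[str] = []
    cells: dict[tuple[str, str], EnrichmentResult] = {}
    for r in results:
        key = (r.class_label, r.track_label)
        if key in cells:
            raise ValueError(f"duplicate result for pair {key}")
        cells[key] = r
        if r.class_label not in class_order:
            class_order.append(r.class_label)
        if r.track_label not in track_order:
            track_order.append(r.track_label)
    missing = [
        (c, t) for c in class_order for t in track_order if (c, t) not in cells
    ]
    if missing:
        raise ValueError(f"missing result for pair {missing[0]}")
    scores = pd.DataFrame(
        [[cells[(c, t)].score for t in track_order] for c in class_order],
        index=pd.Index(class_order, name="class"),
        columns=track_order,
        dtype=float,
    )
    p_adj = pd.DataFrame(
        [[cells[(c, t)].p_adj for t in track_order] for c in class_order],
        index=scores.index.copy(),
        columns=track_order,
        dtype=float,
    )
    directions = pd.DataFrame(
        [[cells[(c, t)].direction for t in track_order] for c in class_order],
        index=scores.index.copy(),
        columns=track_order,
    )
    return EnrichmentMatrix(scores, p_adj, directions)


def filter_tracks(
    matrix: EnrichmentMatrix, alpha: float = 0.01, sd_min: float = 2.0
) -> EnrichmentMatrix:
    """Drop uninformative track columns; class rows are never removed.

    A track survives iff (a) at least one class reaches ``p_adj < alpha``
    (presence rule) and (b) the sample SD (n-1 denominator) of its signed
    scores across classes is ``>= sd_min`` (flatness rule).  Setting
    ``alpha = 1`` disables the presence rule and ``sd_min = 0`` the flatness
    rule, making the filter the identity; the flatness rule is also skipped
    when fewer than two classes exist (the sample SD is undefined).
    Idempotent: both rules depend only on surviving columns' own values.
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    if sd_min < 0:
        raise ValueError("sd_min must be >= 0")
    n_classes = len(matrix.class_labels)
    keep: list[str] = []
    for track in matrix.track_labels:
        present = alpha >= 1 or bool((matrix.p_adj[track] < alpha).any())
        if not present:
            continue
        if sd_min > 0 and n_classes >= 2:
            sd = float(matrix.scores[track].std(ddof=1))
            if sd < sd_min:
                continue
        keep.append(track)
    return matrix.select_tracks(keep)


def _safe_pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    if len(x) < 3 or np.std(x) == 0 or np.std(y) == 0:
        return float("nan"), float("nan")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def class_variability(
    matrix: EnrichmentMatrix,
    sizes: Mapping[str, int],
    exclude: Sequence[str] = (),
) -> VariabilityReport:
    """Per-class score SD across tracks, and its correlation with class size.

    Computed on the matrix as given (conventionally the unfiltered one, i.e.
    against all tracks).  The report carries the Pearson correlation of
    (class size, score SD) over all classes and over classes outside
    ``exclude`` — the latter mirrors dropping the extreme-variability classes
    from the size-vs-spread comparison.  With fewer than 3 classes the
    correlation is reported as NaN (undefined).
    """
    if len(matrix.track_labels) < 2:
        raise ValueError("need >= 2 tracks to compute a per-class SD")
    missing = [c for c in matrix.class_labels if c not in sizes]
    if missing:
        raise ValueError(f"sizes missing for classes: {missing}")
    rows = [
        ClassVariability(c, int(sizes[c]), float(matrix.scores.loc[c].std(ddof=1)))
        for c in matrix.class_labels
    ]
    table = pd.DataFrame(
        {
            "class": [r.class_label for r in rows],
            "size": [r.size for r in rows],
            "score_sd": [r.score_sd for r in rows],
        }
    )
    r_all, p_all = _safe_pearson(table["size"].to_numpy(float), table["score_sd"].to_numpy())
    sub = table[~table["class"].isin(set(exclude))]
    r_ex, p_ex = _safe_pearson(sub["size"].to_numpy(float), sub["score_sd"].to_numpy())
    return VariabilityReport(
        table=table,
        pearson_r=r_all,
        pearson_p=p_all,
        excluded=tuple(exclude),
        pearson_r_excluded=r_ex,
        pearson_p_excluded=p_ex,
    )
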