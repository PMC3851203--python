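"""Model/Results interface for the full enrichment-profiling analysis.

:class:`RegionEnrichment` holds the data (query classes and annotation
tracks) and the analysis settings; :meth:`RegionEnrichment.fit` runs the
member-centric overlap scan, the pooled sampled null, the chi-square tests
and the BH correction, and returns a :class:`RegionEnrichmentResults`
carrying the per-pair table, the signed-score matrix and everything built on
top of it (filtering, variability, correlations, partners, clustering,
exports).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .enrichment import (
    EnrichmentResult,
    adjust_bh,
    chi_square_test,
    estimate_null,
    member_incidence,
    pair_rng,
    signed_score,
)
from .matrixops import (
    EnrichmentMatrix,
    VariabilityReport,
    assemble_matrix,
    class_variability,
    filter_tracks,
)
from .regions import IntervalIndex, RegionSet, read_bed
from .similarity import (
    CorrelationMatrix,
    Dendrogram,
    best_partners,
    chebyshev_distances,
    heatmap_export,
    pearson_profiles,
    ward_linkage,
)

__all__ = ["RegionEnrichment", "RegionEnrichmentResults", "ValidationReport"]

logger = logging.getLogger("epienrich")

_TABLE_COLUMNS = [
    "class",
    "track",
    "observed",
    "class_size",
    "expected",
    "variance",
    "chi2",
    "p_raw",
    "p_adj",
    "direction",
    "score",
]


@dataclass(frozen=True)
class ValidationReport:
    """Input sanity report: per-set counts and chromosome-name mismatches."""

    query_counts: dict[str, int]
    annotation_counts: dict[str, int]
    missing_chromosomes: dict[str, list[str]]  # query label -> chroms absent from all annotations
    warnings: tuple[str, ...]

    @property
    def ok(self) -> bool:
        return not self.warnings

    def __str__(self) -> str:
        lines = [
            f"queries: {len(self.query_counts)} sets, "
            f"{sum(self.query_counts.values())} intervals",
            f"annotations: {len(self.annotation_counts)} sets, "
            f"{sum(self.annotation_counts.values())} intervals",
        ]
        lines += [f"WARNING: {w}" for w in self.warnings]
        return "\n".join(lines)


class RegionEnrichment:
    """Enrichment/depletion of query region-set classes in annotation tracks.

    The model tests each (class, track) pair: how many class members share
    >= 1 nt with the track, against the count expected for a same-size
    pseudo-class sampled without replacement from the pooled universe of all
    classes.  The pooled background makes the question "what distinguishes
    this class from the rest?" rather than "from the genome?".

    Parameters
    ----------
    queries : sequence of RegionSet
        Query classes (role ``query``); the pool is their union, including
        the class under test.
    annotations : sequence of RegionSet
        Annotation tracks (role ``annotation``).
    alpha : float
        Significance cutoff for the presence filter and profile selection.
    sd_min : float
        Score-SD threshold for the flatness filter.
    bh_scope : {"per_class", "global"}
        Whether BH correction runs across each class's tracks separately or
        across the whole matrix.
    statistic : {"gof", "contingency"}
        Chi-square construction, see
        :func:`epienrich.enrichment.chi_square_test`.
    """

    def __init__(
        self,
        queries: Sequence[RegionSet],
        annotations: Sequence[RegionSet],
        *,
        alpha: float = 0.01,
        sd_min: float = 2.0,
        bh_scope: str = "per_class",
        statistic: str = "gof",
        continuity: bool = False,
        min_p: float = 1e-300,
        ward_squared: bool = False,
    ) -> None:
        queries = list(queries)
        annotations = list(annotations)
        if not queries or not annotations:
            raise ValueError("need at least one query and one annotation RegionSet")
        for name, sets in (("query", queries), ("annotation", annotations)):
            labels = [s.label for s in sets]
            if len(set(labels)) != len(labels):
                raise ValueError(f"duplicate {name} labels: {labels}")
        if bh_scope not in ("per_class", "global"):
            raise ValueError("bh_scope must be 'per_class' or 'global'")
        if not 0 < alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        self.queries = queries
        self.annotations = annotations
        self.alpha = alpha
        self.sd_min = sd_min
        self.bh_scope = bh_scope
        self.statistic = statistic
        self.continuity = continuity
        self.min_p = min_p
        self.ward_squared = ward_squared

    @classmethod
    def from_bed_dirs(
        cls, query_dir, annotation_dir, **kwargs
    ) -> "RegionEnrichment":
        """Build the model from two directories of BED files (sorted order)."""

        def load(d: Path, role: str) -> list[RegionSet]:
            paths = sorted(
                p for p in Path(d).iterdir() if p.suffix in (".bed", ".gz")
            )
            return [read_bed(p, role=role) for p in paths]

        queries = load(Path(query_dir), "query")
        annotations = load(Path(annotation_dir), "annotation")
        if not queries:
            raise ValueError(f"no BED files in query dir {query_dir}")
        if not annotations:
            raise ValueError(f"no BED files in annotation dir {annotation_dir}")
        return cls(queries, annotations, **kwargs)

    @classmethod
    def from_study(cls, study, **kwargs) -> "RegionEnrichment":
        """Build the model from a generated :class:`SyntheticStudy`."""
        return cls(
            list(study.classes.values()), list(study.tracks.values()), **kwargs
        )

    def validate_inputs(self) -> ValidationReport:
        """Report per-set interval counts and chromosome-name mismatches."""
        annotation_chroms: set[str] = set()
        for a in self.annotations:
            annotation_chroms |= a.chromosomes()
        missing: dict[str, list[str]] = {}
        warnings: list[str] = []
        for q in self.queries:
            absent = sorted(q.chromosomes() - annotation_chroms)
            if absent:
                missing[q.label] = absent
                warnings.append(
                    f"query {q.label!r}: chromosomes {absent} absent from all "
                    "annotations (exact string comparison; no 'chr' aliasing)"
                )
        for q in self.queries:
            if q.size == 0:
                warnings.append(f"query {q.label!r} is empty")
        return ValidationReport(
            query_counts={q.label: q.size for q in self.queries},
            annotation_counts={a.label: a.size for a in self.annotations},
            missing_chromosomes=missing,
            warnings=tuple(warnings),
        )

    def fit(self, n_samplings: int = 1000, seed: int = 0) -> "RegionEnrichmentResults":
        """Run the full scan and return the results object.

        For each track, every pool member's overlap status is computed once;
        for each (class, track) pair, ``n_samplings`` same-size pseudo-classes
        are drawn from the pool on a deterministic per-pair substream of
        ``seed``, the chi-square test is applied against the sampled mean,
        and p-values are BH-corrected at the configured scope.
        """
        # canonical pool order (independent of query input order) so per-pair
        # substreams draw identical pseudo-classes however the data arrived
        tagged = sorted(
            ((iv, q.label) for q in self.queries for iv in q),
            key=lambda t: (t[0].chrom, t[0].start, t[0].end, t[0].name, t[1]),
        )
        pool = RegionSet("pool", [iv for iv, _ in tagged], role="query")
        masks = {
            q.label: np.array([lab == q.label for _, lab in tagged]) for q in self.queries
        }

        results: list[EnrichmentResult] = []
        for track in self.annotations:
            index = IntervalIndex(track)
            incidence = member_incidence(pool, index)
            for q in self.queries:
                observed = int(incidence[masks[q.label]].sum())
                rng = pair_rng(seed, q.label, track.label)
                null = estimate_null(
                    None,
                    None,
                    k=q.size,
                    n_samplings=n_samplings,
                    rng=rng,
                    incidence=incidence,
                )
                chi2, p_raw, direction = chi_square_test(
                    observed,
                    q.size,
                    null,
                    continuity=self.continuity,
                    statistic=self.statistic,
                )
                results.append(
                    EnrichmentResult(
                        class_label=q.label,
                        track_label=track.label,
                        observed=observed,
                        class_size=q.size,
                        expected=null.mean,
                        variance=null.variance,
                        chi2=chi2,
                        p_raw=p_raw,
                        direction=direction,
                    )
                )
            logger.info("tested track %s against %d classes", track.label, len(self.queries))

        if self.bh_scope == "global":
            adj = adjust_bh([r.p_raw for r in results])
            for r, a in zip(results, adj):
                r.p_adj = float(a)
        else:
            by_class: dict[str, list[EnrichmentResult]] = {}
            for r in results:
                by_class.setdefault(r.class_label, []).append(r)
            for rs in by_class.values():
                adj = adjust_bh([r.p_raw for r in rs])
                for r, a in zip(rs, adj):
                    r.p_adj = float(a)
        for r in results:
            r.score = signed_score(r.p_adj, r.direction, min_p=self.min_p)
        return RegionEnrichmentResults(self, results, n_samplings=n_samplings, seed=seed)


class RegionEnrichmentResults:
    """Fitted results: per-pair table, score matrix, and derived analyses."""

    def __init__(
        self,
        model: RegionEnrichment,
        results: list[EnrichmentResult],
        *,
        n_samplings: int,
        seed: int,
    ) -> None:
        self.model = model
        self.results = results
        self.n_samplings = n_samplings
        self.seed = seed
        self.matrix: EnrichmentMatrix = assemble_matrix(results)

    @property
    def table(self) -> pd.DataFrame:
        """Long-form per-pair results table."""
        return pd.DataFrame(
            [
                (
                    r.class_label,
                    r.track_label,
                    r.observed,
                    r.class_size,
                    r.expected,
                    r.variance,
                    r.chi2,
                    r.p_raw,
                    r.p_adj,
                    r.direction,
                    r.score,
                )
                for r in self.results
            ],
            columns=_TABLE_COLUMNS,
        )

    def filtered_matrix(
        self, alpha: float | None = None, sd_min: float | None = None
    ) -> EnrichmentMatrix:
        """Matrix after the presence and flatness track filters."""
        return filter_tracks(
            self.matrix,
            alpha=self.model.alpha if alpha is None else alpha,
            sd_min=self.model.sd_min if sd_min is None else sd_min,
        )

    def class_variability(self, exclude: Sequence[str] = ()) -> VariabilityReport:
        """Per-class score SD across all (unfiltered) tracks vs class size."""
        sizes = {q.label: q.size for q in self.model.queries}
        return class_variability(self.matrix, sizes, exclude=exclude)

    def correlations(
        self, alpha: float | None = None, tracks: Sequence[str] | None = None
    ) -> CorrelationMatrix:
        """Pearson correlations of class profiles over presence-passing tracks."""
        return pearson_profiles(
            self.matrix,
            alpha=self.model.alpha if alpha is None else alpha,
            tracks=tracks,
        )

    def best_partners(self, **kwargs) -> pd.DataFrame:
        return best_partners(self.correlations(**kwargs))

    def cluster_classes(
        self, on: str = "correlation", filtered: bool = True
    ) -> Dendrogram | None:
        """Ward dendrogram over classes; None when fewer than 2 remain.

        ``on="correlation"`` clusters Chebyshev distances between rows of the
        class-correlation matrix; ``on="scores"`` clusters Chebyshev
        distances between score profiles of the (filtered) matrix directly.
        """
        if on == "correlation":
            try:
                corr = self.correlations()
            except ValueError as exc:
                logger.info("clustering skipped: %s", exc)
                return None
            defined = [
                i for i, lab in enumerate(corr.labels) if lab not in corr.constant
            ]
            if len(defined) < 2:
                logger.info("clustering skipped: fewer than 2 classes with defined profiles")
                return None
            r = corr.r[np.ix_(defined, defined)]
            labels = [corr.labels[i] for i in defined]
            dist = chebyshev_distances(r, axis="rows")
        elif on == "scores":
            m = self.filtered_matrix() if filtered else self.matrix
            if len(m.class_labels) < 2 or len(m.track_labels) < 1:
                logger.info("clustering skipped: matrix too small")
                return None
            dist = chebyshev_distances(m.scores, axis="rows")
            labels = m.class_labels
        else:
            raise ValueError("on must be 'correlation' or 'scores'")
        return ward_linkage(dist, labels, squared=self.model.ward_squared)

    def cluster_tracks(self, filtered: bool = True) -> Dendrogram | None:
        """Ward dendrogram over (filtered) track columns; None if < 2 remain."""
        m = self.filtered_matrix() if filtered else self.matrix
        if len(m.track_labels) < 2 or len(m.class_labels) < 1:
            logger.info("track clustering skipped: fewer than 2 tracks")
            return None
        dist = chebyshev_distances(m.scores, axis="columns")
        return ward_linkage(dist, m.track_labels, squared=self.model.ward_squared)

    def summary(self, top: int = 10) -> str:
        """Human-readable fit summary."""
        t = self.table
        n_sig = int((t["p_adj"] < self.model.alpha).sum())
        lines = [
            "Region-set enrichment profile",
            "=" * 64,
            f"classes: {len(self.model.queries):>5}    tracks: {len(self.model.annotations):>5}"
            f"    pairs tested: {len(t)}",
            f"samplings per pair: {self.n_samplings}    seed: {self.seed}"
            f"    statistic: {self.model.statistic}",
            f"BH scope: {self.model.bh_scope}    alpha: {self.model.alpha}"
            f"    SD filter: {self.model.sd_min}",
            f"pairs with p_adj < alpha: {n_sig}",
            "",
            f"top associations by |score| (signed -log10 adjusted p):",
        ]
        top_rows = t.reindex(t["score"].abs().sort_values(ascending=False).index).head(top)
        lines.append(
            top_rows[
                ["class", "track", "observed", "expected", "p_adj", "direction", "score"]
            ].to_string(index=False, float_format=lambda x: f"{x:.4g}")
        )
        return "\n".join(lines)

    # -- persistence ------------------------------------------------------

    def save(self, out_dir, heatmap: bool = True) -> dict:
        """Write all result tables, dendrograms and the run manifest.

        Numeric text outputs (TSV/Newick) are deterministic for a fixed
        model configuration and seed; the manifest records the configuration
        and SHA-256 checksums of every text output.
        """
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        text_outputs: dict[str, Path] = {}

        self.table.to_csv(out_dir / "enrichment.tsv", sep="\t", index=False)
        text_outputs["enrichment"] = out_dir / "enrichment.tsv"
        self.matrix.to_tsv(out_dir / "matrix_scores.tsv", out_dir / "matrix_sidecar.tsv")
        text_outputs["matrix_scores"] = out_dir / "matrix_scores.tsv"
        text_outputs["matrix_sidecar"] = out_dir / "matrix_sidecar.tsv"
        filtered = self.filtered_matrix()
        filtered.scores.to_csv(out_dir / "filtered_scores.tsv", sep="\t", index_label="class")
        text_outputs["filtered_scores"] = out_dir / "filtered_scores.tsv"

        notices: list[str] = []
        try:
            var = self.class_variability()
            var.table.to_csv(out_dir / "variability.tsv", sep="\t", index=False)
            text_outputs["variability"] = out_dir / "variability.tsv"
        except ValueError as exc:
            notices.append(f"variability analysis skipped: {exc}")
        try:
            corr = self.correlations()
            corr.to_dataframe().to_csv(out_dir / "correlations.tsv", sep="\t", index_label="class")
            text_outputs["correlations"] = out_dir / "correlations.tsv"
            partners = best_partners(corr)
            partners.to_csv(out_dir / "partners.tsv", sep="\t", index=False)
            text_outputs["partners"] = out_dir / "partners.tsv"
        except ValueError as exc:
            notices.append(f"correlation analysis skipped: {exc}")

        class_dendro = self.cluster_classes()
        if class_dendro is not None:
            (out_dir / "class_dendrogram.newick").write_text(class_dendro.to_newick() + "\n")
            text_outputs["class_dendrogram"] = out_dir / "class_dendrogram.newick"
        else:
            notices.append("class clustering skipped (degenerate size)")
        track_dendro = self.cluster_tracks()
        if track_dendro is not None:
            (out_dir / "track_dendrogram.newick").write_text(track_dendro.to_newick() + "\n")
            text_outputs["track_dendrogram"] = out_dir / "track_dendrogram.newick"
        else:
            notices.append("track clustering skipped (degenerate size)")

        if heatmap and filtered.scores.size:
            row_d = (
                self.cluster_classes(on="scores")
                if len(filtered.class_labels) >= 2
                else None
            )
            heatmap_export(
                filtered,
                row_d,
                track_dendro,
                out_dir / "heatmap.png",
                table_path=out_dir / "heatmap_matrix.tsv",
            )
            text_outputs["heatmap_matrix"] = out_dir / "heatmap_matrix.tsv"

        manifest = {
            "package": "epienrich",
            "version": __version__,
            "seed": self.seed,
            "n_samplings": self.n_samplings,
            "config": {
                "alpha": self.model.alpha,
                "sd_min": self.model.sd_min,
                "bh_scope": self.model.bh_scope,
                "statistic": self.model.statistic,
                "continuity": self.model.continuity,
                "ward_squared": self.model.ward_squared,
            },
            "n_classes": len(self.model.queries),
            "n_tracks": len(self.model.annotations),
            "notices": notices,
            "checksums": {
                name: hashlib.sha256(path.read_bytes()).hexdigest()
                for name, path in sorted(text_outputs.items())
            },
        }
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
        return manifest
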