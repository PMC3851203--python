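"""Genomic interval data model, BED I/O and overlap-query indexing.

Coordinates follow the BED convention throughout: 0-based, half-open
``[start, end)``, so two intervals share at least one nucleotide iff
``max(starts) < min(ends)``.  Strand is carried for round-tripping but is
deliberately ignored by all overlap tests.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
from intervaltree import IntervalTree

__all__ = [
    "GenomicInterval",
    "RegionSet",
    "IntervalIndex",
    "BedParseError",
    "read_bed",
    "write_bed",
    "build_index",
]

_STRANDS = ("+", "-", ".")


class BedParseError(ValueError):
    """Raised when a BED line cannot be interpreted as a genomic interval."""


@dataclass(frozen=True, slots=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on one chromosome.

    Parameters
    ----------
    chrom : str
        Chromosome name, compared as an exact string (no ``chr1``/``1``
        aliasing).
    start, end : int
        0-based half-open coordinates; ``0 <= start < end`` is enforced, so
        zero-length intervals are rejected.
    name : str
        Optional identifier; empty string means unnamed.
    strand : str
        One of ``+``, ``-`` or ``.`` (unspecified).  Never consulted when
        testing overlap.
    """

    chrom: str
    start: int
    end: int
    name: str = ""
    strand: str = "."

    def __post_init__(self) -> None:
        if not isinstance(self.start, (int, np.integer)) or not isinstance(
            self.end, (int, np.integer)
        ):
            raise BedParseError(f"non-integer coordinates: {self.start!r}, {self.end!r}")
        if self.start < 0 or self.start >= self.end:
            raise BedParseError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}: "
                "need 0 <= start < end"
            )
        if self.strand not in _STRANDS:
            raise BedParseError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the two intervals share >= 1 nt (strand ignored)."""
        return (
            self.chrom == other.chrom
            and max(self.start, other.start) < min(self.end, other.end)
        )


class RegionSet:
    """An ordered, named collection of :class:`GenomicInterval`.

    A region set is either a *query* (a family of elements to be tested, e.g.
    one ncRNA class) or an *annotation* (a genomic track such as a histone
    mark peak set).  Duplicate intervals are kept — each member is countable —
    but member names are made unique by suffixing ``.1``, ``.2``, ... on
    collision.
    """

    def __init__(
        self,
        label: str,
        intervals: Iterable[GenomicInterval] = (),
        role: str = "query",
    ) -> None:
        if role not in ("query", "annotation"):
            raise ValueError(f"role must be 'query' or 'annotation', got {role!r}")
        self.label = str(label)
        self.role = role
        self.intervals: list[GenomicInterval] = []
        seen: dict[str, int] = {}
        for iv in intervals:
            name = iv.name
            if name in seen:
                seen[name] += 1
                iv = GenomicInterval(iv.chrom, iv.start, iv.end, f"{name}.{seen[name]}", iv.strand)
            elif name:
                seen[name] = 0
            self.intervals.append(iv)

    @property
    def size(self) -> int:
        return len(self.intervals)

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __getitem__(self, i: int) -> GenomicInterval:
        return self.intervals[i]

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, RegionSet)
            and self.label == other.label
            and self.intervals == other.intervals
        )

    def chromosomes(self) -> set[str]:
        return {iv.chrom for iv in self.intervals}

    def total_span(self) -> int:
        """Sum of interval lengths (double-counts self-overlap if any)."""
        return sum(iv.length for iv in self.intervals)

    def subset(self, indices: Iterable[int], label: str | None = None) -> "RegionSet":
        ivs = [self.intervals[i] for i in indices]
        return RegionSet(label or f"{self.label}_subset", ivs, role=self.role)

    def __repr__(self) -> str:
        return f"RegionSet({self.label!r}, n={self.size}, role={self.role!r})"


def _open_maybe_gzip(path: Path, mode: str = "rt"):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_bed(path, label: str | None = None, role: str = "query") -> RegionSet:
    """Read a BED3–BED6 file (optionally gzip-compressed) into a RegionSet.

    ``track``, ``browser`` and ``#`` comment lines are tolerated.  Unnamed
    intervals are named ``<label>_<line#>``.  An empty file yields an empty
    set; a malformed coordinate raises :class:`BedParseError` naming the line.
    """
    path = Path(path)
    if label is None:
        label = path.name
        for suffix in (".gz", ".bed"):
            if label.endswith(suffix):
                label = label[: -len(suffix)]
    intervals: list[GenomicInterval] = []
    with _open_maybe_gzip(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            if line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(f"{path}:{lineno}: fewer than 3 tab-separated fields")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            name = fields[3] if len(fields) > 3 and fields[3] not in ("", ".") else f"{label}_{lineno}"
            strand = fields[5] if len(fields) > 5 and fields[5] in ("+", "-") else "."
            try:
                intervals.append(GenomicInterval(chrom, start, end, name, strand))
            except BedParseError as exc:
                raise BedParseError(f"{path}:{lineno}: {exc}") from exc
    return RegionSet(label, intervals, role=role)


def write_bed(regions: RegionSet, path) -> None:
    """Write a RegionSet as BED6 (score column fixed at 0).

    Round-trip guarantee: ``read_bed`` of the written file reproduces every
    chrom/start/end/name/strand.
    """
    path = Path(path)
    try:
        with _open_maybe_gzip(path, "wt") as fh:
            for iv in regions:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t0\t{iv.strand}\n")
    except OSError as exc:
        raise OSError(f"cannot write BED file {path}: {exc}") from exc


def _merge_sorted(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Union of intervals given arrays sorted by start; touching runs merge."""
    m_starts, m_ends = [], []
    cur_s, cur_e = int(starts[0]), int(ends[0])
    for s, e in zip(starts[1:], ends[1:]):
        if s <= cur_e:
            cur_e = max(cur_e, int(e))
        else:
            m_starts.append(cur_s)
            m_ends.append(cur_e)
            cur_s, cur_e = int(s), int(e)
    m_starts.append(cur_s)
    m_ends.append(cur_e)
    return np.asarray(m_starts, dtype=np.int64), np.asarray(m_ends, dtype=np.int64)


class IntervalIndex:
    """Searchable per-chromosome structure over an annotation RegionSet.

    ``query`` returns the individual annotation intervals sharing >= 1 nt
    with a probe; ``incidence`` answers the same membership question for a
    whole RegionSet at once via a merged-interval binary search, which is the
    hot path of the enrichment scan.
    """

    def __init__(self, annotation: RegionSet) -> None:
        self.label = annotation.label
        self._trees: dict[str, IntervalTree] = {}
        self._merged: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        by_chrom: dict[str, list[GenomicInterval]] = {}
        for iv in annotation:
            by_chrom.setdefault(iv.chrom, []).append(iv)
        for chrom, ivs in by_chrom.items():
            tree = IntervalTree()
            for iv in ivs:
                tree.addi(iv.start, iv.end, iv)
            self._trees[chrom] = tree
            starts = np.array([iv.start for iv in ivs], dtype=np.int64)
            ends = np.array([iv.end for iv in ivs], dtype=np.int64)
            order = np.argsort(starts, kind="stable")
            self._merged[chrom] = _merge_sorted(starts[order], ends[order])

    def chromosomes(self) -> set[str]:
        return set(self._trees)

    def query(self, interval: GenomicInterval) -> list[GenomicInterval]:
        """All annotation intervals sharing >= 1 nt with ``interval``."""
        tree = self._trees.get(interval.chrom)
        if tree is None:
            return []
        hits = tree.overlap(interval.start, interval.end)
        return sorted((h.data for h in hits), key=lambda iv: (iv.start, iv.end, iv.name))

    def overlaps_any(self, interval: GenomicInterval) -> bool:
        merged = self._merged.get(interval.chrom)
        if merged is None:
            return False
        m_starts, m_ends = merged
        i = int(np.searchsorted(m_ends, interval.start, side="right"))
        return i < len(m_starts) and int(m_starts[i]) < interval.end

    def incidence(self, regions: RegionSet) -> np.ndarray:
        """Boolean vector: does each member of ``regions`` hit the track?

        Equivalent to ``[len(self.query(iv)) > 0 for iv in regions]`` but
        vectorised over merged annotation intervals.
        """
        out = np.zeros(regions.size, dtype=bool)
        by_chrom: dict[str, list[int]] = {}
        for i, iv in enumerate(regions):
            by_chrom.setdefault(iv.chrom, []).append(i)
        for chrom, idxs in by_chrom.items():
            merged = self._merged.get(chrom)
            if merged is None:
                continue
            m_starts, m_ends = merged
            starts = np.array([regions[i].start for i in idxs], dtype=np.int64)
            ends = np.array([regions[i].end for i in idxs], dtype=np.int64)
            pos = np.searchsorted(m_ends, starts, side="right")
            hit = np.zeros(len(idxs), dtype=bool)
            inside = pos < len(m_starts)
            hit[inside] = m_starts[pos[inside]] < ends[inside]
            out[np.asarray(idxs)] = hit
        return out


def build_index(annotation: RegionSet) -> IntervalIndex:
    """Build an overlap-query index over an annotation RegionSet."""
    return IntervalIndex(annotation)
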