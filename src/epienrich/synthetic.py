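"""Synthetic region-set studies with planted enrichment/depletion.

Generates a pooled universe of query classes and a panel of annotation
tracks whose statistical shape mirrors the real inputs the analysis targets:
~15 query classes of 52–3,024 members with right-skewed lengths of 15–8,302
nt, and annotation tracks of non-overlapping intervals covering variable
genome fractions.  Each (class, track) pair can carry a planted overlap-rate
multiplier (1 = null); the generator records a truth manifest and audits
itself by recomputing realized rates from the emitted intervals.

Placement model: a member designated "overlapping" starts uniformly inside
a randomly chosen (length-weighted) track interval, guaranteeing >= 1 nt of
overlap; a non-designated member is placed entirely inside the track's
complement.  The planted rate is therefore exact by construction, up to
binomial sampling noise in the designation step.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .regions import GenomicInterval, IntervalIndex, RegionSet, write_bed

__all__ = [
    "ClassSpec",
    "TrackSpec",
    "SyntheticStudySpec",
    "SyntheticStudy",
    "NCRNA_CLASS_PANEL",
    "generate_track",
    "generate_class",
    "generate_study",
    "ncrna_study_spec",
    "generate_shared_state_study",
]

#: (label, member count, min length, mean length, max length) for the 15
#: ncRNA classes emulated by the ncRNA-shaped default study.
NCRNA_CLASS_PANEL: tuple[tuple[str, int, int, int, int], ...] = (
    ("7SK", 316, 61, 293, 374),
    ("CD_box", 509, 30, 99, 238),
    ("HACA_box", 440, 52, 130, 329),
    ("lncRNA", 217, 36, 144, 463),
    ("miRNA", 2233, 15, 22, 27),
    ("piRNA", 2152, 20, 47, 8302),
    ("pri_miRNA", 1595, 41, 83, 180),
    ("rRNA", 611, 34, 119, 1860),
    ("scaRNA", 52, 82, 153, 419),
    ("snoRNA", 1001, 30, 115, 419),
    ("snRNA", 3024, 30, 109, 419),
    ("spliceosomal", 1812, 49, 111, 229),
    ("SRP_RNA", 941, 201, 286, 361),
    ("tRNA", 905, 59, 72, 107),
    ("Y_RNA", 893, 57, 102, 148),
)


@dataclass(frozen=True, slots=True)
class ClassSpec:
    """One query class: member count and a right-skewed length range (nt)."""

    label: str
    size: int
    min_length: int = 30
    mean_length: int = 110
    max_length: int = 500

    def __post_init__(self) -> None:
        if self.size < 1:
            raise ValueError("class size must be >= 1")
        if not 1 <= self.min_length <= self.mean_length <= self.max_length:
            raise ValueError("need 1 <= min <= mean <= max length")


@dataclass(frozen=True, slots=True)
class TrackSpec:
    """One annotation track: interval count and target genome coverage."""

    label: str
    n_intervals: int
    coverage: float

    def __post_init__(self) -> None:
        if self.n_intervals < 0:
            raise ValueError("interval count must be >= 0")
        if self.n_intervals > 0 and not 0 < self.coverage < 1:
            raise ValueError("coverage must be in (0, 1)")


@dataclass(frozen=True)
class SyntheticStudySpec:
    """Declarative description of genome, classes, tracks and planted effects.

    ``effects`` maps ``(class_label, track_label)`` to an overlap-rate
    multiplier (> 0, 1 = null).  At most one planted track per class is
    supported, because member placement is conditioned on a single
    designated track.
    """

    genome: tuple[tuple[str, int], ...]
    classes: tuple[ClassSpec, ...]
    tracks: tuple[TrackSpec, ...]
    effects: dict[tuple[str, str], float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        track_labels = {t.label for t in self.tracks}
        class_labels = {c.label for c in self.classes}
        per_class: dict[str, int] = {}
        for (cl, tr), mult in self.effects.items():
            if cl not in class_labels:
                raise ValueError(f"effect references unknown class {cl!r}")
            if tr not in track_labels:
                raise ValueError(f"effect references unknown track {tr!r}")
            if mult <= 0:
                raise ValueError("multipliers must be > 0")
            per_class[cl] = per_class.get(cl, 0) + 1
        multi = [c for c, k in per_class.items() if k > 1]
        if multi:
            raise ValueError(f"at most one planted track per class (violated by {multi})")


@dataclass(frozen=True)
class SyntheticStudy:
    """A generated study: per-class queries, per-track annotations, truth."""

    spec: SyntheticStudySpec
    classes: dict[str, RegionSet]
    tracks: dict[str, RegionSet]
    truth: pd.DataFrame  # class, track, multiplier, target_rate, realized_rate

    @property
    def class_sizes(self) -> dict[str, int]:
        return {label: rs.size for label, rs in self.classes.items()}

    def pool(self) -> RegionSet:
        """Union of all query classes, member identity preserved."""
        ivs = [iv for rs in self.classes.values() for iv in rs]
        return RegionSet("pool", ivs, role="query")


def _component_rng(seed: int, kind: int, label: str) -> np.random.Generator:
    ss = np.random.SeedSequence(
        [int(seed) & 0x7FFFFFFF, kind, zlib.crc32(label.encode("utf-8"))]
    )
    return np.random.default_rng(ss)


def _lognormal_lengths(
    n: int, min_len: int, mean_len: int, max_len: int, rng: np.random.Generator
) -> np.ndarray:
    """Right-skewed integer lengths with the requested range and mean."""
    if min_len == max_len:
        return np.full(n, min_len, dtype=np.int64)
    sigma = float(np.clip(np.log(max_len / max(min_len, 1)) / 4.0, 0.2, 1.2))
    mu = np.log(mean_len) - sigma**2 / 2.0
    lengths = np.exp(rng.normal(mu, sigma, size=n))
    return np.clip(np.round(lengths), min_len, max_len).astype(np.int64)


def _allocate_counts(n: int, weights: np.ndarray) -> np.ndarray:
    """Largest-remainder split of n items proportional to weights."""
    frac = n * weights / weights.sum()
    counts = np.floor(frac).astype(int)
    rem = n - counts.sum()
    order = np.argsort(-(frac - counts), kind="stable")
    counts[order[:rem]] += 1
    return counts


def generate_track(
    tspec: TrackSpec,
    genome: tuple[tuple[str, int], ...],
    rng: np.random.Generator,
) -> RegionSet:
    """Generate a non-self-overlapping annotation track at a target coverage.

    Interval lengths are drawn log-normally and rescaled so the realized
    genome coverage is within 10% (in practice, rounding error) of target;
    intervals are laid down per chromosome by distributing the free space
    into random gaps.  Raises on infeasible coverage.
    """
    chroms = [c for c, _ in genome]
    lens = np.array([l for _, l in genome], dtype=np.int64)
    G = int(lens.sum())
    if tspec.n_intervals == 0:
        return RegionSet(tspec.label, [], role="annotation")
    target_total = tspec.coverage * G
    mean_iv = target_total / tspec.n_intervals
    if mean_iv < 1:
        raise ValueError(
            f"track {tspec.label}: coverage {tspec.coverage} infeasible with "
            f"{tspec.n_intervals} intervals on a {G} nt genome"
        )
    raw = np.exp(rng.normal(np.log(mean_iv) - 0.125, 0.5, size=tspec.n_intervals))
    lengths = np.maximum(1, np.round(raw * target_total / raw.sum())).astype(np.int64)
    realized = int(lengths.sum())
    if abs(realized - target_total) / target_total > 0.10:
        lengths = np.maximum(1, np.round(lengths * target_total / realized)).astype(np.int64)
        realized = int(lengths.sum())
    if realized >= G:
        raise ValueError(f"track {tspec.label}: total interval length exceeds genome")
    counts = _allocate_counts(tspec.n_intervals, lens.astype(float))
    intervals: list[GenomicInterval] = []
    pos = 0
    idx = 0
    for chrom, L, n_c in zip(chroms, lens, counts):
        if n_c == 0:
            continue
        ls = lengths[pos : pos + n_c]
        pos += n_c
        total_c = int(ls.sum())
        if total_c >= L:
            raise ValueError(
                f"track {tspec.label}: intervals do not fit on {chrom} "
                f"({total_c} nt requested, {L} nt available)"
            )
        gaps = rng.dirichlet(np.ones(n_c + 1)) * (int(L) - total_c)
        gaps = np.floor(gaps).astype(np.int64)
        start = 0
        for g, l in zip(gaps[:-1], ls):
            start += int(g)
            intervals.append(
                GenomicInterval(chrom, start, start + int(l), f"{tspec.label}_{idx}")
            )
            idx += 1
            start += int(l)
    return RegionSet(tspec.label, intervals, role="annotation")


def _track_arrays(track: RegionSet, genome) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, _ in genome:
        ivs = sorted(
            (iv for iv in track if iv.chrom == chrom), key=lambda iv: iv.start
        )
        if ivs:
            out[chrom] = (
                np.array([iv.start for iv in ivs], dtype=np.int64),
                np.array([iv.end for iv in ivs], dtype=np.int64),
            )
    return out


def _gap_table(track: RegionSet, genome) -> tuple[np.ndarray, list[str], np.ndarray, np.ndarray]:
    """Complement of a (non-self-overlapping) track: gap start/length arrays."""
    chrom_names: list[str] = []
    g_start: list[int] = []
    g_len: list[int] = []
    arrays = _track_arrays(track, genome)
    for chrom, L in genome:
        if chrom not in arrays:
            chrom_names.append(chrom)
            g_start.append(0)
            g_len.append(int(L))
            continue
        starts, ends = arrays[chrom]
        edges = [0] + [int(e) for e in ends]
        nexts = [int(s) for s in starts] + [int(L)]
        for s, e in zip(edges, nexts):
            if e > s:
                chrom_names.append(chrom)
                g_start.append(s)
                g_len.append(e - s)
    return (
        np.arange(len(g_len)),
        chrom_names,
        np.array(g_start, dtype=np.int64),
        np.array(g_len, dtype=np.int64),
    )


def _place_uniform(
    n: int, lengths: np.ndarray, genome, rng: np.random.Generator
) -> list[tuple[str, int, int]]:
    chroms = [c for c, _ in genome]
    lens = np.array([l for _, l in genome], dtype=np.int64)
    which = rng.choice(len(chroms), size=n, p=lens / lens.sum())
    out = []
    for i in range(n):
        L = int(lens[which[i]])
        l = int(min(lengths[i], L))
        start = int(rng.integers(0, L - l + 1))
        out.append((chroms[which[i]], start, start + l))
    return out


def generate_class(
    cspec: ClassSpec,
    genome: tuple[tuple[str, int], ...],
    rng: np.random.Generator,
    effect: tuple[RegionSet, float] | None = None,
) -> RegionSet:
    """Generate one query class, optionally with a planted overlap rate.

    With ``effect = (track, multiplier)``, each member independently
    overlaps the track with probability ``clip(multiplier x coverage, 0, 1)``
    (a warning is issued when clipping occurs): designated members start
    uniformly inside a length-weighted random track interval; the rest are
    placed wholly inside the complement.  Without an effect, members are
    placed uniformly over the genome.
    """
    lengths = _lognormal_lengths(
        cspec.size, cspec.min_length, cspec.mean_length, cspec.max_length, rng
    )
    chrom_len = dict(genome)
    if effect is None:
        placed = _place_uniform(cspec.size, lengths, genome, rng)
    else:
        track, mult = effect
        G = sum(l for _, l in genome)
        coverage = track.total_span() / G
        rate = mult * coverage
        if rate > 1.0:
            warnings.warn(
                f"class {cspec.label}: requested overlap rate {rate:.3f} > 1; clipped",
                stacklevel=2,
            )
            rate = 1.0
        hit = rng.random(cspec.size) < rate
        iv_chrom = [iv.chrom for iv in track]
        iv_start = np.array([iv.start for iv in track], dtype=np.int64)
        iv_len = np.array([iv.length for iv in track], dtype=np.int64)
        _, gap_chrom, gap_start, gap_len = _gap_table(track, genome)
        placed = [("", 0, 0)] * cspec.size
        hit_idx = np.flatnonzero(hit)
        if hit_idx.size:
            if iv_len.size == 0:
                raise ValueError(
                    f"class {cspec.label}: planted effect on an empty track"
                )
            choice = rng.choice(iv_len.size, size=hit_idx.size, p=iv_len / iv_len.sum())
            offs = np.floor(rng.random(hit_idx.size) * iv_len[choice]).astype(np.int64)
            for j, (c, o) in enumerate(zip(choice, offs)):
                i = int(hit_idx[j])
                chrom = iv_chrom[int(c)]
                L = int(chrom_len[chrom])
                start = int(iv_start[int(c)] + o)
                end = min(start + int(lengths[i]), L)
                placed[i] = (chrom, start, end)
        miss_idx = np.flatnonzero(~hit)
        if miss_idx.size:
            choice = rng.choice(gap_len.size, size=miss_idx.size, p=gap_len / gap_len.sum())
            u = rng.random(miss_idx.size)
            for j, (g, uu) in enumerate(zip(choice, u)):
                i = int(miss_idx[j])
                glen = int(gap_len[int(g)])
                l_eff = int(min(lengths[i], glen))
                start = int(gap_start[int(g)] + np.floor(uu * (glen - l_eff + 1)))
                placed[i] = (gap_chrom[int(g)], start, start + l_eff)
    intervals = [
        GenomicInterval(chrom, s, e, f"{cspec.label}_{i}")
        for i, (chrom, s, e) in enumerate(placed)
    ]
    return RegionSet(cspec.label, intervals, role="query")


def generate_study(
    spec: SyntheticStudySpec, out_dir: str | Path | None = None
) -> SyntheticStudy:
    """Generate a full study plus its truth manifest, with a self-audit.

    Regeneration with the same spec (seed included) is byte-identical.  The
    audit recomputes each planted pair's realized overlap rate from the
    emitted intervals and requires it within 4 binomial SDs of the target;
    failure raises ``RuntimeError``.  When ``out_dir`` is given, one BED per
    class (``queries/``) and per track (``annotations/``) plus
    ``truth.tsv`` are written.
    """
    tracks: dict[str, RegionSet] = {}
    for tspec in spec.tracks:
        tracks[tspec.label] = generate_track(
            tspec, spec.genome, _component_rng(spec.seed, 1, tspec.label)
        )
    effect_by_class = {cl: (tr, m) for (cl, tr), m in spec.effects.items()}
    classes: dict[str, RegionSet] = {}
    for cspec in spec.classes:
        eff = effect_by_class.get(cspec.label)
        effect = (tracks[eff[0]], eff[1]) if eff is not None else None
        classes[cspec.label] = generate_class(
            cspec, spec.genome, _component_rng(spec.seed, 2, cspec.label), effect=effect
        )
    G = sum(l for _, l in spec.genome)
    rows = []
    for t_label, track in tracks.items():
        index = IntervalIndex(track)
        coverage = track.total_span() / G
        for c_label, cls in classes.items():
            realized = float(index.incidence(cls).mean()) if cls.size else 0.0
            mult = spec.effects.get((c_label, t_label), 1.0)
            target = (
                min(mult * coverage, 1.0)
                if (c_label, t_label) in spec.effects
                else np.nan
            )
            rows.append((c_label, t_label, mult, target, realized))
    truth = pd.DataFrame(
        rows, columns=["class", "track", "multiplier", "target_rate", "realized_rate"]
    )
    study = SyntheticStudy(spec=spec, classes=classes, tracks=tracks, truth=truth)
    _audit(study)
    if out_dir is not None:
        out_dir = Path(out_dir)
        (out_dir / "queries").mkdir(parents=True, exist_ok=True)
        (out_dir / "annotations").mkdir(parents=True, exist_ok=True)
        for label, rs in classes.items():
            write_bed(rs, out_dir / "queries" / f"{label}.bed")
        for label, rs in tracks.items():
            write_bed(rs, out_dir / "annotations" / f"{label}.bed")
        truth.to_csv(out_dir / "truth.tsv", sep="\t", index=False)
    return study


def _audit(study: SyntheticStudy, n_sd: float = 4.0) -> None:
    """Check realized rates of planted pairs against their targets."""
    planted = study.truth.dropna(subset=["target_rate"])
    for _, row in planted.iterrows():
        size = study.classes[row["class"]].size
        target = float(row["target_rate"])
        sd = np.sqrt(max(target * (1 - target), 1e-12) / size)
        if abs(float(row["realized_rate"]) - target) > n_sd * sd + 1e-9:
            raise RuntimeError(
                f"generator self-audit failed for ({row['class']}, {row['track']}): "
                f"realized {row['realized_rate']:.4f} vs target {target:.4f} "
                f"(tolerance {n_sd} binomial SD = {n_sd * sd:.4f})"
            )


def ncrna_study_spec(
    n_tracks: int = 40,
    seed: int = 0,
    genome: tuple[tuple[str, int], ...] = (("chr1", 60_000_000), ("chr2", 40_000_000)),
    effects: dict[tuple[str, str], float] | None = None,
) -> SyntheticStudySpec:
    """Default study emulating the real inputs' statistical shape.

    15 query classes with the member counts and length ranges of the ncRNA
    families (52–3,024 members, 15–8,302 nt), and ``n_tracks`` annotation
    tracks whose coverages sweep 0.02–0.40 of the genome with varying
    interval counts.  The default effect map plants a few strong
    enrichments/depletions so that every downstream stage has structure to
    find; pass ``effects={}`` for a fully null study.
    """
    classes = tuple(ClassSpec(*row) for row in NCRNA_CLASS_PANEL)
    tracks = []
    for i in range(n_tracks):
        frac = i / max(n_tracks - 1, 1)
        coverage = 0.02 + 0.38 * frac
        n_intervals = 200 + 37 * i % 800
        tracks.append(TrackSpec(f"track_{i + 1:02d}", n_intervals, round(coverage, 4)))
    if effects is None:
        # two classes deviate per planted track so tracks carry differential
        # (not flat) signal across classes, as in real epigenomic panels
        defaults = {
            ("tRNA", "track_05"): 4.0,
            ("CD_box", "track_05"): 3.0,
            ("miRNA", "track_10"): 2.5,
            ("pri_miRNA", "track_10"): 2.0,
            ("piRNA", "track_15"): 0.25,
            ("rRNA", "track_15"): 0.4,
            ("snRNA", "track_20"): 0.4,
            ("spliceosomal", "track_20"): 0.5,
            ("snoRNA", "track_25"): 2.2,
            ("HACA_box", "track_25"): 1.8,
            ("Y_RNA", "track_30"): 0.4,
            ("SRP_RNA", "track_30"): 0.5,
        }
        present = {t.label for t in tracks}
        effects = {k: v for k, v in defaults.items() if k[1] in present}
    return SyntheticStudySpec(
        genome=genome,
        classes=classes,
        tracks=tuple(tracks),
        effects=dict(effects),
        seed=seed,
    )


def generate_shared_state_study(
    seed: int = 0,
    n_classes_per_group: int = 3,
    class_size: int = 300,
    n_tracks_per_group: int = 6,
    track_coverage: float = 0.08,
    state_coverage: float = 0.5,
    inside_rate: float = 0.85,
    genome: tuple[tuple[str, int], ...] = (("chr1", 10_000_000),),
    n_state_segments: int = 200,
    track_n_intervals: int = 150,
) -> tuple[SyntheticStudy, dict[str, str], dict[str, str]]:
    """Correlated-track study driven by one latent genomic partition.

    A latent "state" track splits the genome into state-A segments (covering
    ``state_coverage``) and their complement (state B).  Group-A annotation
    tracks live inside state-A segments, group-B tracks inside the
    complement, so tracks within a group are correlated.  Group-A classes
    place ``inside_rate`` of their members in state A (group-B classes the
    mirror image), making the two class groups prefer opposite track groups.

    Returns ``(study, class_groups, track_groups)`` with group maps
    ``label -> "A" | "B"``.
    """
    rng0 = _component_rng(seed, 3, "state")
    state = generate_track(
        TrackSpec("state", n_state_segments, state_coverage), genome, rng0
    )
    _, gap_chrom, gap_start, gap_len = _gap_table(state, genome)
    a_chrom = [iv.chrom for iv in state]
    a_start = np.array([iv.start for iv in state], dtype=np.int64)
    a_len = np.array([iv.length for iv in state], dtype=np.int64)
    G = sum(l for _, l in genome)

    def _fill(
        label: str,
        n: int,
        seg_chrom: list[str],
        seg_start: np.ndarray,
        seg_len: np.ndarray,
        total_target: float,
        rng: np.random.Generator,
        role: str,
        lengths: np.ndarray | None = None,
    ) -> RegionSet:
        """Place n intervals inside the given segments (length-weighted)."""
        if lengths is None:
            mean_iv = max(total_target / n, 1.0)
            raw = np.exp(rng.normal(np.log(mean_iv) - 0.125, 0.5, size=n))
            lengths = np.maximum(1, np.round(raw * total_target / raw.sum())).astype(
                np.int64
            )
        choice = rng.choice(seg_len.size, size=n, p=seg_len / seg_len.sum())
        u = rng.random(n)
        ivs = []
        for i, (c, uu) in enumerate(zip(choice, u)):
            glen = int(seg_len[int(c)])
            l_eff = int(min(int(lengths[i]), glen))
            start = int(seg_start[int(c)] + np.floor(uu * (glen - l_eff + 1)))
            ivs.append(
                GenomicInterval(seg_chrom[int(c)], start, start + l_eff, f"{label}_{i}")
            )
        return RegionSet(label, ivs, role=role)

    tracks: dict[str, RegionSet] = {}
    track_groups: dict[str, str] = {}
    for g, (seg_c, seg_s, seg_l) in (
        ("A", (a_chrom, a_start, a_len)),
        ("B", (gap_chrom, gap_start, gap_len)),
    ):
        for i in range(n_tracks_per_group):
            label = f"track{g}_{i + 1:02d}"
            rng = _component_rng(seed, 4, label)
            tracks[label] = _fill(
                label,
                track_n_intervals,
                seg_c,
                seg_s,
                seg_l,
                track_coverage * G,
                rng,
                "annotation",
            )
            track_groups[label] = g

    classes: dict[str, RegionSet] = {}
    class_groups: dict[str, str] = {}
    for g in ("A", "B"):
        p_inside = inside_rate if g == "A" else 1.0 - inside_rate
        for i in range(n_classes_per_group):
            label = f"class{g}_{i + 1}"
            rng = _component_rng(seed, 5, label)
            lengths = _lognormal_lengths(class_size, 60, 120, 400, rng)
            inside = rng.random(class_size) < p_inside
            ivs: list[GenomicInterval] = []
            in_idx = np.flatnonzero(inside)
            out_idx = np.flatnonzero(~inside)
            parts: list[tuple[np.ndarray, list[str], np.ndarray, np.ndarray]] = [
                (in_idx, a_chrom, a_start, a_len),
                (out_idx, gap_chrom, gap_start, gap_len),
            ]
            placed: list[tuple[str, int, int] | None] = [None] * class_size
            for idxs, seg_c, seg_s, seg_l in parts:
                if idxs.size == 0:
                    continue
                choice = rng.choice(seg_l.size, size=idxs.size, p=seg_l / seg_l.sum())
                u = rng.random(idxs.size)
                for j, (c, uu) in enumerate(zip(choice, u)):
                    k = int(idxs[j])
                    glen = int(seg_l[int(c)])
                    l_eff = int(min(int(lengths[k]), glen))
                    start = int(seg_s[int(c)] + np.floor(uu * (glen - l_eff + 1)))
                    placed[k] = (seg_c[int(c)], start, start + l_eff)
            for k, p in enumerate(placed):
                assert p is not None
                ivs.append(GenomicInterval(p[0], p[1], p[2], f"{label}_{k}"))
            classes[label] = RegionSet(label, ivs, role="query")
            class_groups[label] = g

    rows = []
    for t_label, track in tracks.items():
        index = IntervalIndex(track)
        for c_label, cls in classes.items():
            rows.append(
                (c_label, t_label, np.nan, np.nan, float(index.incidence(cls).mean()))
            )
    truth = pd.DataFrame(
        rows, columns=["class", "track", "multiplier", "target_rate", "realized_rate"]
    )
    spec = SyntheticStudySpec(
        genome=genome,
        classes=tuple(
            ClassSpec(label, class_size, 60, 120, 400) for label in classes
        ),
        tracks=tuple(
            TrackSpec(label, track_n_intervals, track_coverage) for label in tracks
        ),
        effects={},
        seed=seed,
    )
    study = SyntheticStudy(spec=spec, classes=classes, tracks=tracks, truth=truth)
    return study, class_groups, track_groups
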