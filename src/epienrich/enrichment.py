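"""Member-centric overlap counting, the pooled sampled null, and the
chi-square enrichment/depletion test with BH correction and signed scores.

The statistic asks, for one query class and one annotation track: do more
(or fewer) class members touch the track than random pseudo-classes of the
same size drawn from the pooled universe of all classes?  Counting is
member-centric — a member touching three track intervals still counts once —
and the null is estimated empirically by repeated sampling without
replacement from the pool.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .regions import IntervalIndex, RegionSet

__all__ = [
    "OverlapCount",
    "NullDistribution",
    "EnrichmentResult",
    "count_overlapping_members",
    "member_incidence",
    "sample_background",
    "estimate_null",
    "chi_square_test",
    "adjust_bh",
    "signed_score",
    "pair_rng",
]

#: Floor applied to adjusted p-values before -log10 so scores stay finite.
MIN_P = 1e-300


@dataclass(frozen=True, slots=True)
class OverlapCount:
    """Number of class members sharing >= 1 nt with >= 1 track interval."""

    class_label: str
    track_label: str
    observed: int
    class_size: int

    def __post_init__(self) -> None:
        if not 0 <= self.observed <= self.class_size:
            raise ValueError(
                f"observed={self.observed} outside [0, class_size={self.class_size}]"
            )


@dataclass(frozen=True, slots=True)
class NullDistribution:
    """Empirical null of the overlap count under pooled-universe sampling.

    ``mean`` and ``variance`` are estimated over ``n_samplings`` independent
    draws of pseudo-classes; ``sample_counts`` optionally retains the raw
    per-draw counts for diagnostics.
    """

    mean: float
    variance: float
    n_samplings: int
    sample_counts: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.n_samplings < 1:
            raise ValueError("n_samplings must be >= 1")
        if self.variance < 0:
            raise ValueError("variance must be >= 0")


@dataclass(slots=True)
class EnrichmentResult:
    """One class-by-track test: counts, chi-square, BH-adjusted p, score."""

    class_label: str
    track_label: str
    observed: int
    class_size: int
    expected: float
    variance: float
    chi2: float
    p_raw: float
    direction: str  # enriched | depleted | none
    p_adj: float = np.nan
    score: float = np.nan


def count_overlapping_members(query: RegionSet, index: IntervalIndex) -> OverlapCount:
    """Member-centric overlap count of a query class against one track.

    Each member contributes 0 or 1 regardless of how many track intervals it
    touches.  An empty query yields ``observed = 0``.
    """
    observed = int(index.incidence(query).sum())
    return OverlapCount(query.label, index.label, observed, query.size)


def member_incidence(pool: RegionSet, index: IntervalIndex) -> np.ndarray:
    """Boolean overlap status of every pool member against one track.

    Precomputing this once per track makes the 1000-sampling null a sum of
    Booleans instead of repeated interval queries; the two routes are
    identical because a sampled pseudo-class's count is exactly the sum of
    its members' statuses.
    """
    return index.incidence(pool)


def sample_background(pool: RegionSet, k: int, rng: np.random.Generator) -> RegionSet:
    """Draw ``k`` distinct pool members uniformly without replacement."""
    if not 1 <= k <= pool.size:
        raise ValueError(f"k={k} outside [1, pool size {pool.size}]")
    idx = rng.choice(pool.size, size=k, replace=False)
    return pool.subset(idx.tolist(), label=f"{pool.label}_sample{k}")


def _sample_hit_counts(
    incidence: np.ndarray, k: int, n_samplings: int, rng: np.random.Generator
) -> np.ndarray:
    """Overlap counts of ``n_samplings`` uniform k-subsets of the pool.

    Each row of uniform variates is arg-partitioned so that its k smallest
    positions form a uniform random k-subset; the count is the sum of the
    subset's Boolean statuses.  Chunked to bound memory at ~O(8e6) floats.
    """
    incidence = np.asarray(incidence, dtype=bool)
    n_pool = incidence.size
    if not 1 <= k <= n_pool:
        raise ValueError(f"k={k} outside [1, pool size {n_pool}]")
    if k == n_pool:
        return np.full(n_samplings, int(incidence.sum()), dtype=np.int64)
    counts = np.empty(n_samplings, dtype=np.int64)
    chunk = max(1, int(8_000_000 // n_pool))
    for lo in range(0, n_samplings, chunk):
        m = min(chunk, n_samplings - lo)
        u = rng.random((m, n_pool))
        idx = np.argpartition(u, k - 1, axis=1)[:, :k]
        counts[lo : lo + m] = incidence[idx].sum(axis=1)
    return counts


def estimate_null(
    pool: RegionSet | None,
    index: IntervalIndex | None,
    k: int,
    n_samplings: int = 1000,
    rng: np.random.Generator | None = None,
    *,
    incidence: np.ndarray | None = None,
    keep_samples: bool = False,
) -> NullDistribution:
    """Empirical mean/variance of the overlap count of random pseudo-classes.

    Draws ``n_samplings`` pseudo-classes of size ``k`` without replacement
    from the pool and counts, for each, how many members hit the track.
    ``incidence`` may be supplied to reuse a precomputed per-member status
    vector (see :func:`member_incidence`); otherwise it is computed from
    ``pool`` and ``index``.  Variance uses the n-1 denominator (0.0 when
    ``n_samplings == 1``).
    """
    if n_samplings < 1:
        raise ValueError("n_samplings must be >= 1")
    if rng is None:
        rng = np.random.default_rng()
    if incidence is None:
        if pool is None or index is None:
            raise ValueError("need either incidence or (pool, index)")
        incidence = member_incidence(pool, index)
    counts = _sample_hit_counts(np.asarray(incidence), k, n_samplings, rng)
    mean = float(counts.mean())
    variance = float(counts.var(ddof=1)) if n_samplings > 1 else 0.0
    return NullDistribution(
        mean=mean,
        variance=variance,
        n_samplings=n_samplings,
        sample_counts=counts if keep_samples else None,
    )


def chi_square_test(
    observed: int,
    class_size: int,
    null: NullDistribution | float,
    *,
    continuity: bool = False,
    statistic: str = "gof",
) -> tuple[float, float, str]:
    """Chi-square test of the observed overlap count against the null mean.

    The default is the one-sample goodness-of-fit form (df = 1, no continuity
    correction unless ``continuity=True``)::

        chi2 = (observed - expected)^2 / (n * p0 * (1 - p0)),  p0 = expected/n

    which treats the sampled null mean as a known expectation and is close to
    nominally calibrated under the pooled sampling null (see the methods
    note).  ``statistic="contingency"`` instead computes the Pearson
    chi-square on the 2x2 table ``[[observed, n - observed],
    [expected, n - expected]]``; that form treats the expectation as a second
    observed sample and is markedly conservative under the sampling null.

    Returns ``(chi2, p_raw, direction)``; ``direction`` is ``enriched`` when
    observed exceeds expected, ``depleted`` below, ``none`` on an exact tie
    (then ``chi2 = 0, p = 1``).
    """
    expected = float(null.mean) if isinstance(null, NullDistribution) else float(null)
    n = int(class_size)
    if not 0 <= observed <= n:
        raise ValueError(f"observed={observed} outside [0, {n}]")
    if not 0.0 <= expected <= n:
        raise ValueError(f"expected={expected} outside [0, {n}]")
    if observed > expected:
        direction = "enriched"
    elif observed < expected:
        direction = "depleted"
    else:
        return 0.0, 1.0, "none"

    if statistic == "gof":
        p0 = expected / n
        # boundary null probabilities: clamp half a member into the open interval
        p0 = min(max(p0, 0.5 / n), 1.0 - 0.5 / n)
        diff = abs(observed - expected)
        if continuity:
            diff = max(diff - 0.5, 0.0)
        chi2 = diff**2 / (n * p0 * (1.0 - p0))
    elif statistic == "contingency":
        table = np.array(
            [[observed, n - observed], [expected, n - expected]], dtype=float
        )
        col = table.sum(axis=0)
        if (col == 0).any():  # degenerate margin; only reachable near ties
            return 0.0, 1.0, direction
        exp_cells = np.outer(table.sum(axis=1), col) / table.sum()
        diff = np.abs(table - exp_cells)
        if continuity:
            diff = np.maximum(diff - 0.5, 0.0)
        chi2 = float((diff**2 / exp_cells).sum())
    else:
        raise ValueError(f"unknown statistic {statistic!r}")
    p_raw = float(stats.chi2.sf(chi2, df=1))
    return float(chi2), p_raw, direction


def adjust_bh(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def signed_score(p_adj: float, direction: str, min_p: float = MIN_P) -> float:
    """Signed -log10 of an adjusted p-value.

    Positive for enriched, negative for depleted, 0.0 for ``none`` or
    ``p_adj >= 1``.  ``p_adj`` is floored at ``min_p`` before the log so
    underflowed p-values map to a finite score.
    """
    if not 0.0 <= p_adj <= 1.0:
        raise ValueError(f"p_adj={p_adj} outside [0, 1]")
    if direction == "none" or p_adj >= 1.0:
        return 0.0
    magnitude = -np.log10(max(p_adj, min_p))
    return float(-magnitude if direction == "depleted" else magnitude)


def pair_rng(seed: int, class_label: str, track_label: str) -> np.random.Generator:
    """Deterministic per-(class, track) random substream.

    Keyed on stable CRC32 hashes of the labels so results are independent of
    evaluation order and of the number of workers.
    """
    ss = np.random.SeedSequence(
        [
            int(seed) & 0x7FFFFFFF,
            zlib.crc32(class_label.encode("utf-8")),
            zlib.crc32(track_label.encode("utf-8")),
        ]
    )
    return np.random.default_rng(ss)
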