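import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from epienrich import (
    GenomicInterval,
    NullDistribution,
    RegionSet,
    adjust_bh,
    build_index,
    chi_square_test,
    count_overlapping_members,
    estimate_null,
    sample_background,
    signed_score,
)
from epienrich.enrichment import member_incidence, pair_rng
from _oracles import bh_oracle, hypergeometric_moments
from conftest import random_region_set


def _simple_track():
    return build_index(
        RegionSet("t", [GenomicInterval("chr1", 5, 25, "a")], role="annotation")
    )


def test_member_centric_counting_counts_each_member_once():
    """A member touching three track intervals still contributes exactly 1."""
    track = RegionSet(
        "nfkb",
        [
            GenomicInterval("chr1", 10, 20, "s1"),
            GenomicInterval("chr1", 30, 40, "s2"),
            GenomicInterval("chr1", 50, 60, "s3"),
        ],
        role="annotation",
    )
    trna = RegionSet("trna", [GenomicInterval("chr1", 0, 100, "m")])
    oc = count_overlapping_members(trna, build_index(track))
    assert oc.observed == 1


def test_overlap_count_example_and_empty_query():
    query = RegionSet(
        "q",
        [
            GenomicInterval("chr1", 0, 10),
            GenomicInterval("chr1", 20, 30),
            GenomicInterval("chr1", 40, 50),
        ],
    )
    assert count_overlapping_members(query, _simple_track()).observed == 2
    empty = RegionSet("e", [])
    assert count_overlapping_members(empty, _simple_track()).observed == 0


def test_sample_background_contracts():
    rng = np.random.default_rng(3)
    pool = random_region_set(rng, 10, "pool")
    # exhaustive draw returns the whole pool (any order)
    full = sample_background(pool, 10, np.random.default_rng(0))
    assert sorted(iv.name for iv in full) == sorted(iv.name for iv in pool)
    # same seed -> identical member multisets
    a = sample_background(pool, 4, np.random.default_rng(9))
    b = sample_background(pool, 4, np.random.default_rng(9))
    assert [iv.name for iv in a] == [iv.name for iv in b]
    with pytest.raises(ValueError):
        sample_background(pool, 11, rng)


def test_sample_background_is_uniform():
    """Over 10,000 k=1 draws from 10 members, each frequency is within 4 SD
    of 1/10 (binomial bound)."""
    rng = np.random.default_rng(17)
    pool = random_region_set(np.random.default_rng(0), 10, "pool")
    counts = {iv.name: 0 for iv in pool}
    for _ in range(10_000):
        counts[sample_background(pool, 1, rng)[0].name] += 1
    sd = np.sqrt(10_000 * 0.1 * 0.9)
    for c in counts.values():
        assert abs(c - 1000) < 4 * sd


def test_estimate_null_matches_hypergeometric_moments():
    """Sampling without replacement from a pool with fixed member statuses
    is hypergeometric; the empirical null must match its closed form."""
    inc = np.zeros(1000, dtype=bool)
    inc[:300] = True
    mean, var = hypergeometric_moments(1000, 300, 100)
    nulls = [
        estimate_null(
            None, None, k=100, n_samplings=1000,
            rng=np.random.default_rng(seed), incidence=inc,
        )
        for seed in range(5)
    ]
    pooled_mean = np.mean([n.mean for n in nulls])
    assert abs(pooled_mean - mean) <= 3 * np.sqrt(var / 5000)
    for n in nulls:
        assert abs(n.variance - var) / var <= 0.25


def test_estimate_null_empty_track_and_sample_retention():
    inc = np.zeros(50, dtype=bool)
    null = estimate_null(
        None, None, k=10, n_samplings=20, rng=np.random.default_rng(0),
        incidence=inc, keep_samples=True,
    )
    assert null.mean == 0.0 and null.variance == 0.0
    assert null.sample_counts is not None and len(null.sample_counts) == 20


def test_estimate_null_equals_explicit_resampling_of_members():
    """Summing precomputed member statuses is the same count as re-querying
    the intervals of an explicitly sampled pseudo-class."""
    rng = np.random.default_rng(8)
    pool = random_region_set(rng, 200, "pool")
    track = random_region_set(rng, 50, "t", role="annotation")
    idx = build_index(track)
    inc = member_incidence(pool, idx)
    for _ in range(20):
        sub = sample_background(pool, 30, rng)
        names = {iv.name for iv in sub}
        via_inc = sum(
            int(inc[i]) for i, iv in enumerate(pool) if iv.name in names
        )
        assert count_overlapping_members(sub, idx).observed == via_inc


def test_chi_square_contingency_worked_example():
    """2x2 observed-vs-expected Pearson chi-square, df=1, no correction."""
    chi2, p, d = chi_square_test(50, 100, 25.0, statistic="contingency")
    assert chi2 == pytest.approx(13.333, abs=0.01)
    assert p == pytest.approx(2.6e-4, rel=0.05)
    assert d == "enriched"
    # table symmetry: swapping observed and expected flips only the direction
    chi2b, pb, db = chi_square_test(25, 100, 50.0, statistic="contingency")
    assert chi2b == pytest.approx(chi2) and pb == pytest.approx(p) and db == "depleted"


def test_chi_square_gof_matches_scipy_chisquare():
    """Default statistic equals scipy's one-sample chi-square on the
    two-cell table with expected proportions from the null mean."""
    from scipy.stats import chisquare

    for obs, n, exp in [(50, 100, 25.0), (130, 400, 160.0), (3, 50, 7.5)]:
        chi2, p, _ = chi_square_test(obs, n, exp)
        ref = chisquare([obs, n - obs], [exp, n - exp])
        assert chi2 == pytest.approx(float(ref.statistic), rel=1e-12)
        assert p == pytest.approx(float(ref.pvalue), rel=1e-9)


def test_chi_square_ties_and_degenerate_tables():
    assert chi_square_test(30, 100, 30.0) == (0.0, 1.0, "none")
    assert chi_square_test(0, 100, 0.0) == (0.0, 1.0, "none")
    assert chi_square_test(100, 100, 100.0) == (0.0, 1.0, "none")
    with pytest.raises(ValueError):
        chi_square_test(101, 100, 30.0)


def test_chi_square_continuity_correction_reduces_statistic():
    chi2, _, _ = chi_square_test(50, 100, 40.0, statistic="contingency")
    chi2c, _, _ = chi_square_test(50, 100, 40.0, statistic="contingency", continuity=True)
    assert chi2c < chi2


def test_adjust_bh_examples():
    assert adjust_bh([0.03]) == pytest.approx([0.03])
    assert adjust_bh([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])
    assert adjust_bh([1.0, 1.0]) == pytest.approx([1.0, 1.0])
    with pytest.raises(ValueError):
        adjust_bh([0.5, 1.5])


@settings(deadline=None, max_examples=100, derandomize=True)
@given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
def test_adjust_bh_matches_brute_force_definition(p):
    adj = adjust_bh(p)
    assert np.allclose(adj, bh_oracle(np.array(p)), atol=1e-12)
    assert np.all(adj >= np.asarray(p) - 1e-15)  # monotone: adjusted >= raw
    assert np.all(adj <= 1.0)


def test_signed_score_examples_and_antisymmetry():
    assert signed_score(0.01, "enriched") == pytest.approx(2.0)
    assert signed_score(0.01, "depleted") == pytest.approx(-2.0)
    assert signed_score(1.0, "enriched") == 0.0
    assert signed_score(0.5, "none") == 0.0
    for p in (0.3, 1e-5, 1e-320):
        assert signed_score(p, "enriched") == -signed_score(p, "depleted")
    # underflow floor keeps scores finite
    assert signed_score(0.0, "enriched") == pytest.approx(300.0)


def test_pair_rng_is_order_independent():
    a1 = pair_rng(5, "classA", "track1").random(3)
    b = pair_rng(5, "classB", "track9").random(3)
    a2 = pair_rng(5, "classA", "track1").random(3)
    assert np.array_equal(a1, a2)
    assert not np.array_equal(a1, b)


def test_null_distribution_validation():
    with pytest.raises(ValueError):
        NullDistribution(mean=1.0, variance=-0.1, n_samplings=10)
    with pytest.raises(ValueError):
        NullDistribution(mean=1.0, variance=0.1, n_samplings=0)
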