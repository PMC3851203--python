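import numpy as np
import pytest

from epienrich import (
    best_partners,
    chebyshev_distances,
    pearson_profiles,
    ward_linkage,
    heatmap_export,
)
from epienrich.similarity import CorrelationMatrix
from _oracles import chebyshev_oracle, pearson_oracle, ward_oracle

from test_matrixops import _make_matrix


# ---------------------------------------------------------------- pearson

def test_pearson_profiles_textbook_values():
    m = _make_matrix({"t1": [1.0, 1.0], "t2": [2.0, 2.0], "t3": [3.0, 4.0]})
    corr = pearson_profiles(m, tracks=["t1", "t2", "t3"])
    # profiles (1,2,3) vs (1,2,4)
    assert corr.r[0, 1] == pytest.approx(0.982, abs=0.001)
    assert corr.r[0, 0] == 1.0 and corr.r[1, 1] == 1.0
    assert np.allclose(corr.r, corr.r.T)


def test_pearson_profiles_anticorrelated_and_constant_flagging():
    m = _make_matrix({"t1": [1.0, -1.0, 5.0], "t2": [2.0, -2.0, 5.0], "t3": [4.0, -4.0, 5.0]})
    corr = pearson_profiles(m, tracks=["t1", "t2", "t3"])
    assert corr.r[0, 1] == pytest.approx(-1.0)
    assert corr.constant == ("C",)  # constant profile -> flagged, not zero-filled
    assert np.isnan(corr.r[2, 0]) and np.isnan(corr.r[0, 2])


def test_pearson_profiles_default_track_rule_and_min_tracks(small_results):
    corr = small_results.correlations()
    sig = [
        t
        for t in small_results.matrix.track_labels
        if (small_results.matrix.p_adj[t] < 0.01).any()
    ]
    assert len(sig) >= 3
    explicit = pearson_profiles(small_results.matrix, tracks=sig)
    assert np.allclose(corr.r, explicit.r, equal_nan=True)
    with pytest.raises(ValueError):
        pearson_profiles(small_results.matrix, tracks=sig[:2])


@pytest.mark.parametrize("trial", range(5))
def test_pearson_matches_direct_formula_on_random_profiles(trial):
    rng = np.random.default_rng(60 + trial)
    n, m = int(rng.integers(2, 10)), int(rng.integers(3, 11))
    scores = {f"t{j}": list(rng.normal(size=n)) for j in range(m)}
    mat = _make_matrix(scores)
    corr = pearson_profiles(mat, tracks=list(scores))
    X = mat.scores.to_numpy()
    for i in range(n):
        for j in range(n):
            assert corr.r[i, j] == pytest.approx(pearson_oracle(X[i], X[j]), abs=1e-9)


def test_pearson_invariant_under_column_permutation(small_results):
    corr = small_results.correlations()
    tracks = [
        t
        for t in small_results.matrix.track_labels
        if (small_results.matrix.p_adj[t] < 0.01).any()
    ]
    rng = np.random.default_rng(1)
    shuffled = [tracks[i] for i in rng.permutation(len(tracks))]
    corr2 = pearson_profiles(small_results.matrix, tracks=shuffled)
    assert np.allclose(corr.r, corr2.r, equal_nan=True)


# ---------------------------------------------------------------- partners

def test_best_partners_examples_and_tie_break():
    labels = ("A", "B", "C")
    r = np.array([[1.0, 0.9, -0.5], [0.9, 1.0, 0.1], [-0.5, 0.1, 1.0]])
    t = best_partners(CorrelationMatrix(labels, r)).set_index("class")
    assert t.loc["A", "best_partner"] == "B" and t.loc["A", "worst_partner"] == "C"
    # two classes: best = worst = the other
    r2 = np.array([[1.0, 0.4], [0.4, 1.0]])
    t2 = best_partners(CorrelationMatrix(("A", "B"), r2)).set_index("class")
    assert t2.loc["A", "best_partner"] == "B" and t2.loc["A", "worst_partner"] == "B"
    # tie r(A,B) == r(A,C): earlier label wins
    r3 = np.array([[1.0, 0.5, 0.5], [0.5, 1.0, 0.0], [0.5, 0.0, 1.0]])
    t3 = best_partners(CorrelationMatrix(labels, r3)).set_index("class")
    assert t3.loc["A", "best_partner"] == "B"


def test_best_partners_excludes_undefined_entries():
    labels = ("A", "B", "C")
    r = np.array([[1.0, np.nan, -0.2], [np.nan, 1.0, 0.3], [-0.2, 0.3, 1.0]])
    t = best_partners(CorrelationMatrix(labels, r)).set_index("class")
    assert t.loc["A", "best_partner"] == "C"  # NaN partner skipped


# ---------------------------------------------------------------- chebyshev

def test_chebyshev_examples():
    X = np.array([[0.0, 0.0], [3.0, -4.0], [0.0, 0.0]])
    D = chebyshev_distances(X)
    assert D[0, 1] == 4.0  # max(|3|, |-4|)
    assert D[0, 2] == 0.0  # identical vectors
    Dc = chebyshev_distances(X, axis="columns")
    assert Dc.shape == (2, 2)
    assert np.allclose(Dc, chebyshev_distances(X.T))


@pytest.mark.parametrize("trial", range(5))
def test_chebyshev_matches_direct_formula_and_triangle(trial):
    rng = np.random.default_rng(80 + trial)
    X = rng.normal(size=(int(rng.integers(3, 10)), int(rng.integers(2, 10))))
    D = chebyshev_distances(X)
    n = len(X)
    for i in range(n):
        for j in range(n):
            expect = 0.0 if i == j else chebyshev_oracle(X[i], X[j])
            assert D[i, j] == pytest.approx(expect, abs=1e-12)
    for i in range(n):
        for j in range(n):
            for k in range(n):
                assert D[i, j] <= D[i, k] + D[k, j] + 1e-12


# ---------------------------------------------------------------- ward

def test_ward_two_leaves_and_merge_count():
    D = np.array([[0.0, 3.5], [3.5, 0.0]])
    d = ward_linkage(D, ["a", "b"])
    assert len(d.merges) == 1 and d.merges[0][2] == pytest.approx(3.5)
    rng = np.random.default_rng(4)
    n = 7
    A = rng.random((n, n))
    D = (A + A.T) / 2
    np.fill_diagonal(D, 0)
    assert len(ward_linkage(D).merges) == n - 1


def test_ward_first_merge_on_line_points():
    # points {0, 1, 10} on a line: nearest pair {0, 1} merges first
    from scipy.spatial.distance import pdist, squareform

    D = squareform(pdist(np.array([[0.0], [1.0], [10.0]])))
    d = ward_linkage(D, ["p0", "p1", "p10"])
    left, right = d.first_bipartition()
    assert {left, right} == {frozenset({"p10"}), frozenset({"p0", "p1"})}
    assert set(d.leaves_of(3)) == {0, 1}


@pytest.mark.parametrize("squared", [False, True])
@pytest.mark.parametrize("trial", range(6))
def test_ward_matches_exhaustive_oracle(trial, squared):
    """Lance-Williams agglomeration equals an exhaustive search that
    recomputes the Ward objective from scratch at every step."""
    rng = np.random.default_rng(200 + trial)
    n = int(rng.integers(2, 9))
    A = rng.random((n, n)) * 5
    D = (A + A.T) / 2
    np.fill_diagonal(D, 0)
    dend = ward_linkage(D, squared=squared)
    impl = sorted(
        (frozenset(dend.leaves_of(a)) | frozenset(dend.leaves_of(b)), h)
        for a, b, h, _ in dend.merges
    )
    oracle = sorted((a | b, h) for a, b, h in ward_oracle(D, squared=squared))
    for (s1, h1), (s2, h2) in zip(impl, oracle):
        assert s1 == s2
        assert h1 == pytest.approx(h2, abs=1e-9)


def test_ward_squared_variant_matches_scipy_on_euclidean_points():
    from scipy.cluster.hierarchy import linkage
    from scipy.spatial.distance import pdist, squareform

    rng = np.random.default_rng(9)
    X = rng.normal(size=(8, 3))
    dend = ward_linkage(squareform(pdist(X)), squared=True)
    Z = linkage(pdist(X), method="ward")
    assert np.allclose(sorted(dend.heights()), sorted(Z[:, 2]), atol=1e-8)


def test_ward_heights_monotone_and_permutation_equivariant():
    rng = np.random.default_rng(12)
    n = 7
    A = rng.random((n, n))
    D = (A + A.T) / 2
    np.fill_diagonal(D, 0)
    labels = [f"L{i}" for i in range(n)]
    d1 = ward_linkage(D, labels)
    h = d1.heights()
    assert all(h[i] <= h[i + 1] + 1e-12 for i in range(len(h) - 1))
    perm = rng.permutation(n)
    d2 = ward_linkage(D[np.ix_(perm, perm)], [labels[i] for i in perm])
    assert np.allclose(sorted(d1.heights()), sorted(d2.heights()), atol=1e-9)
    parts1 = sorted(map(sorted, d1.first_bipartition()))
    parts2 = sorted(map(sorted, d2.first_bipartition()))
    assert parts1 == parts2


def test_ward_rejects_invalid_input():
    with pytest.raises(ValueError):
        ward_linkage(np.array([[0.0, 1.0], [2.0, 0.0]]))  # asymmetric
    with pytest.raises(ValueError):
        ward_linkage(np.array([[1.0]]))


def test_newick_round_trips_heights_through_dendropy():
    import dendropy

    rng = np.random.default_rng(21)
    n = 6
    A = rng.random((n, n)) * 3
    D = (A + A.T) / 2
    np.fill_diagonal(D, 0)
    labels = [f"x{i}" for i in range(n)]
    dend = ward_linkage(D, labels)
    tree = dendropy.Tree.get(data=dend.to_newick(), schema="newick")
    assert sorted(t.label for t in tree.taxon_namespace) == sorted(labels)
    # root-to-leaf distance equals the root merge height for every leaf
    root_h = dend.heights()[-1]
    for leaf in tree.leaf_node_iter():
        assert leaf.distance_from_root() == pytest.approx(root_h, rel=1e-6)


# ---------------------------------------------------------------- heatmap

def test_heatmap_export_files_and_leaf_order(tmp_path, small_results):
    filtered = small_results.filtered_matrix()
    rows = small_results.cluster_classes(on="scores")
    cols = small_results.cluster_tracks()
    out = heatmap_export(
        filtered, rows, cols, tmp_path / "h.png", table_path=tmp_path / "h.tsv"
    )
    assert (tmp_path / "h.png").exists() and (tmp_path / "h.tsv").exists()
    assert list(out.index) == rows.leaf_order()
    assert list(out.columns) == cols.leaf_order()


def test_heatmap_cap_clips_export_but_not_analysis_matrix(tmp_path, small_results):
    filtered = small_results.filtered_matrix()
    before = filtered.scores.copy()
    out = heatmap_export(filtered, None, None, tmp_path / "h.png", cap=5.0)
    assert out.to_numpy().max() <= 5.0 and out.to_numpy().min() >= -5.0
    assert filtered.scores.equals(before)  # analysis matrix untouched


def test_heatmap_all_zero_matrix(tmp_path):
    m = _make_matrix({"t1": [0.0, 0.0], "t2": [0.0, 0.0]})
    out = heatmap_export(m, None, None, tmp_path / "z.png", table_path=tmp_path / "z.tsv")
    assert (out.to_numpy() == 0).all()
    assert (tmp_path / "z.png").exists()
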