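import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import pdist, squareform

from rankbank.beta_structure import (
    DistanceMatrix,
    distance_matrix,
    jaccard_stability,
    pairwise_to_dataframe,
    permanova,
    permanova_pairwise,
    upgma,
)
from rankbank.otu_io import OtuTable
from rankbank.synthetic_communities import block_dataset
from conftest import random_table


# -- distances ---------------------------------------------------------------


def test_bray_curtis_hand_example():
    t = OtuTable(["x", "y"], ["a", "b", "c"], np.array([[10, 0, 5], [5, 5, 5]]))
    dm = distance_matrix(t, "bray_curtis", normalize=False)
    assert dm.values[0, 1] == pytest.approx(1 - 20 / 30, abs=1e-12)


def test_bray_curtis_identical_and_disjoint():
    t = OtuTable(
        ["a", "b", "c"],
        ["o1", "o2", "o3", "o4"],
        np.array([[3, 1, 0, 0], [3, 1, 0, 0], [0, 0, 2, 2]]),
    )
    dm = distance_matrix(t, "bray_curtis")
    assert dm.values[0, 1] == pytest.approx(0.0, abs=1e-12)
    assert dm.values[0, 2] == pytest.approx(1.0, abs=1e-12)


def test_bray_curtis_scipy_oracle(rng):
    t = random_table(rng, n_samples=8, n_otus=25)
    dm = distance_matrix(t, "bray_curtis", normalize=False)
    want = squareform(pdist(t.counts.astype(float), metric="braycurtis"))
    np.testing.assert_allclose(dm.values, want, atol=1e-12)


@pytest.mark.parametrize("metric", ["euclidean", "manhattan", "canberra"])
def test_other_metrics_match_scipy(rng, metric):
    t = random_table(rng, n_samples=6, n_otus=15)
    dm = distance_matrix(t, metric, normalize=True)
    x = t.counts / t.counts.sum(axis=1, keepdims=True)
    scipy_name = {"manhattan": "cityblock"}.get(metric, metric)
    np.testing.assert_allclose(dm.values, squareform(pdist(x, scipy_name)),
                               atol=1e-12)


def test_unknown_metric():
    t = OtuTable(["a", "b"], ["o"], np.array([[1], [2]]))
    with pytest.raises(ValueError, match="unknown metric"):
        distance_matrix(t, "chebyshev")


@settings(max_examples=50, deadline=None)
@given(st.integers(0, 2**31 - 1))
def test_bray_curtis_properties(seed):
    rng = np.random.default_rng(seed)
    t = random_table(rng, n_samples=4, n_otus=10, depth=100)
    dm = distance_matrix(t, "bray_curtis")
    assert np.all(dm.values >= -1e-12) and np.all(dm.values <= 1 + 1e-12)
    np.testing.assert_allclose(dm.values, dm.values.T, atol=1e-12)
    assert np.all(np.diag(dm.values) == 0)


# -- UPGMA -------------------------------------------------------------------


def test_upgma_hand_example():
    d = np.array([[0, 1, 4], [1, 0, 4], [4, 4, 0]], float)
    tree = upgma(DistanceMatrix(["A", "B", "C"], d, "euclidean"))
    nodes = sorted(tree.internal_nodes(), key=lambda n: n.height)
    assert nodes[0].leaves == frozenset({"A", "B"})
    assert nodes[0].height == pytest.approx(1.0)
    assert nodes[1].height == pytest.approx(4.0)


def test_upgma_identical_samples_merge_at_zero():
    t = OtuTable(["a", "b", "c"], ["o1", "o2"],
                 np.array([[4, 6], [2, 3], [9, 1]]))
    tree = upgma(distance_matrix(t))
    merged = min(tree.internal_nodes(), key=lambda n: n.height)
    assert merged.leaves == frozenset({"a", "b"})
    assert merged.height == pytest.approx(0.0, abs=1e-12)


def test_upgma_matches_scipy_linkage(rng):
    from scipy.cluster.hierarchy import average, cophenet

    t = random_table(rng, n_samples=10, n_otus=30)
    dm = distance_matrix(t)
    tree = upgma(dm)
    cond = squareform(dm.values, checks=False)
    z = average(cond)
    ours = tree.cophenetic()
    # scipy cophenetic distances use the original id order
    order = [ours.sample_ids.index(s) for s in dm.sample_ids]
    got = ours.values[np.ix_(order, order)]
    np.testing.assert_allclose(got, squareform(cophenet(z)), atol=1e-9)


def test_upgma_heights_equal_cophenetic_at_merges():
    d = np.array([[0, 1, 4], [1, 0, 4], [4, 4, 0]], float)
    tree = upgma(DistanceMatrix(["A", "B", "C"], d, "euclidean"))
    coph = tree.cophenetic().to_dataframe()
    assert coph.loc["A", "B"] == pytest.approx(1.0)
    assert coph.loc["A", "C"] == pytest.approx(4.0)


def test_upgma_separates_blocks():
    from sklearn.metrics import adjusted_rand_score

    table, labels = block_dataset(seasons=("March", "September"),
                                  depth_zones=("shallow",), samples_per_block=6,
                                  seed=11)
    tree = upgma(distance_matrix(table))
    cut = tree.cut(2)
    truth = labels.set_index("sample_id")["block"]
    got = [cut[s] for s in truth.index]
    assert adjusted_rand_score(truth.tolist(), got) == pytest.approx(1.0)


def test_newick_round_trip_leaf_set():
    d = np.array([[0, 1, 4], [1, 0, 4], [4, 4, 0]], float)
    tree = upgma(DistanceMatrix(["A", "B", "C"], d, "euclidean"))
    nwk = tree.to_newick()
    assert nwk.endswith(";")
    for leaf in "ABC":
        assert leaf in nwk


# -- Jaccard stability -------------------------------------------------------


def test_jaccard_stability_deterministic():
    table, _ = block_dataset(samples_per_block=4, seed=3)
    a = jaccard_stability(table, B=10, seed=7)
    b = jaccard_stability(table, B=10, seed=7)
    sa = [n.stability for n in a.internal_nodes()]
    sb = [n.stability for n in b.internal_nodes()]
    assert sa == sb


def test_jaccard_stability_tight_blocks_high():
    table, labels = block_dataset(seasons=("March", "September"),
                                  depth_zones=("shallow",),
                                  samples_per_block=8, seed=5)
    tree = jaccard_stability(table, B=50, seed=1)
    blocks = labels.groupby("block")["sample_id"].apply(frozenset)
    for members in blocks:
        node = next(n for n in tree.internal_nodes() if n.leaves == members)
        assert node.stability > 75


def test_jaccard_stability_discriminates_noise_from_blocks(rng):
    # i.i.d. abundances carry no block structure.  Because bootstrap
    # resampling preserves pairwise distances, tight 2-sample nodes stay
    # reproducible even in noise, but multi-sample noise nodes are far
    # less supported than real blocks (which sit at ~100).
    t = random_table(rng, n_samples=16, n_otus=40, depth=300)
    noise_tree = jaccard_stability(t, B=40, seed=2)
    noise = np.array([
        n.stability for n in noise_tree.internal_nodes()
        if n.stability is not None and 3 <= len(n.leaves) < 16
    ])
    table, labels = block_dataset(samples_per_block=4, seed=9)
    block_tree = jaccard_stability(table, B=40, seed=2)
    block_sets = labels.groupby("block")["sample_id"].apply(frozenset)
    block_vals = np.array([
        next(n.stability for n in block_tree.internal_nodes()
             if n.leaves == members)
        for members in block_sets
    ])
    assert block_vals.min() > np.median(noise)
    assert (noise < 75).mean() >= 0.4
    assert (block_vals > 90).all()


def test_jaccard_stability_b_zero():
    table, _ = block_dataset(samples_per_block=3, seed=0)
    with pytest.raises(ValueError):
        jaccard_stability(table, B=0)


# -- PERMANOVA ---------------------------------------------------------------


def exact_permanova_p(dm_values, groups):
    """Oracle: complete enumeration of label assignments."""
    groups = np.asarray(groups)
    d2 = dm_values**2
    n = len(groups)

    def pseudo_f(codes):
        levels = sorted(set(codes))
        ss_t = d2[np.triu_indices(n, 1)].sum() / n
        ss_w = 0.0
        for lv in levels:
            m = np.flatnonzero(np.asarray(codes) == lv)
            sub = d2[np.ix_(m, m)]
            ss_w += sub[np.triu_indices(m.size, 1)].sum() / m.size
        a = len(levels)
        return ((ss_t - ss_w) / (a - 1)) / (ss_w / (n - a))

    f_obs = pseudo_f(groups)
    hits = total = 0
    for perm in itertools.permutations(groups):
        total += 1
        if pseudo_f(perm) >= f_obs - 1e-12:
            hits += 1
    return f_obs, hits / total


def two_block_dm():
    pts = np.array([0.0, 1.0, 10.0, 11.0])[:, None]
    return DistanceMatrix(
        ["a", "b", "c", "d"], squareform(pdist(pts)), "euclidean"
    )


def test_permanova_hand_f_200():
    res = permanova(two_block_dm(), ["g1", "g1", "g2", "g2"],
                    n_permutations=999, seed=0)
    assert res.f == pytest.approx(200.0, abs=1e-9)
    assert res.df_among == 1 and res.df_within == 2


def test_permanova_exact_enumeration_oracle(rng):
    t = random_table(rng, n_samples=8, n_otus=12, depth=200)
    groups = ["x"] * 4 + ["y"] * 4
    dm = distance_matrix(t)
    f_obs, p_exact = exact_permanova_p(dm.values, groups)
    res = permanova(dm, groups, n_permutations=9999, seed=1)
    assert res.f == pytest.approx(f_obs, abs=1e-9)
    se = np.sqrt(p_exact * (1 - p_exact) / 9999)
    assert abs(res.p - p_exact) <= 4 * se + 2e-4


def test_permanova_matches_scikit_bio(rng):
    skbio = pytest.importorskip("skbio")
    from skbio.stats.distance import permanova as skbio_permanova

    t = random_table(rng, n_samples=12, n_otus=20)
    dm = distance_matrix(t)
    groups = ["a"] * 6 + ["b"] * 6
    ours = permanova(dm, groups, n_permutations=99, seed=0)
    theirs = skbio_permanova(
        skbio.DistanceMatrix(dm.values, ids=dm.sample_ids),
        grouping=groups, permutations=99,
    )
    assert ours.f == pytest.approx(float(theirs["test statistic"]), abs=1e-9)


def test_permanova_reorder_invariance(rng):
    t = random_table(rng, n_samples=10, n_otus=15)
    groups = dict(zip(t.sample_ids, ["a"] * 5 + ["b"] * 5))
    dm = distance_matrix(t)
    res1 = permanova(dm, groups, n_permutations=49, seed=0)
    order = list(reversed(t.sample_ids))
    res2 = permanova(dm.submatrix(order), groups, n_permutations=49, seed=0)
    assert res1.f == pytest.approx(res2.f, abs=1e-9)


def test_permanova_degenerate_and_errors():
    t = OtuTable(["a", "b", "c", "d"], ["o1", "o2"],
                 np.array([[1, 2]] * 4))
    dm = distance_matrix(t)
    with pytest.warns(UserWarning, match="undefined"):
        res = permanova(dm, ["x", "x", "y", "y"], n_permutations=9, seed=0)
    assert np.isnan(res.f)
    with pytest.raises(ValueError, match="singleton"):
        permanova(two_block_dm(), ["g1", "g1", "g1", "g2"])
    with pytest.raises(ValueError, match="2 groups"):
        permanova(two_block_dm(), ["g1"] * 4)


def test_permanova_p_floor():
    res = permanova(two_block_dm(), ["g1", "g1", "g2", "g2"],
                    n_permutations=99, seed=3)
    assert res.p >= 1 / 100


def test_pairwise_three_levels(rng):
    t = random_table(rng, n_samples=9, n_otus=12)
    groups = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
    results = permanova_pairwise(distance_matrix(t), groups,
                                 n_permutations=49, seed=0)
    assert len(results) == 3
    assert {r.levels for r in results} == {("a", "b"), ("a", "c"), ("b", "c")}
    df = pairwise_to_dataframe(results, adjust="bh")
    assert "p_bh" in df.columns
    assert (df["p_bh"] >= df["p"] - 1e-12).all()


def test_pairwise_singleton_skipped(rng):
    t = random_table(rng, n_samples=5, n_otus=10)
    groups = ["a", "a", "b", "b", "c"]
    with pytest.warns(UserWarning, match="singleton"):
        results = permanova_pairwise(distance_matrix(t), groups,
                                     n_permutations=49, seed=0)
    assert {r.levels for r in results} == {("a", "b")}


def test_pairwise_gradient_structure():
    # surface block far from deep blocks: surface-vs-deep F dominates
    rng = np.random.default_rng(0)
    base_surface = np.array([200, 100, 5, 5, 5])
    base_mid = np.array([20, 30, 150, 80, 10])
    base_deep = np.array([5, 5, 90, 100, 110])
    counts, groups = [], []
    for name, base in (("surface", base_surface), ("mid", base_mid),
                       ("deep", base_deep)):
        for _ in range(4):
            counts.append(rng.poisson(base) + 1)
            groups.append(name)
    t = OtuTable([f"s{i}" for i in range(12)],
                 [f"o{j}" for j in range(5)], np.array(counts))
    results = permanova_pairwise(distance_matrix(t), groups,
                                 n_permutations=99, seed=1)
    f = {r.levels: r.f for r in results}
    assert f[("deep", "surface")] > f[("deep", "mid")]
    assert f[("deep", "surface")] > f[("mid", "surface")]
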