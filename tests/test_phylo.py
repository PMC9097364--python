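import numpy as np
import pandas as pd
import pytest

from avidiet import phylo, synth
from avidiet.errors import (DegenerateDataError, GroupError, NewickParseError,
                            SingularMatrixError, TreeError)

from conftest import random_tree


# ---------------------------------------------------------------------------
# Newick I/O


def test_read_minimal_tree():
    t = phylo.read_newick("(A:1,B:1):0;")
    assert sorted(t.tip_labels) == ["A", "B"]
    assert t.tip_depths() == {"A": 1.0, "B": 1.0}


def test_shared_path_definition(small_tree):
    C = phylo.phylo_vcv(small_tree).to_frame()
    assert C.loc["A", "B"] == 1.0
    assert C.loc["A", "C"] == 0.0


def test_round_trip_64_tips():
    t = random_tree(seed=9, n_taxa=64)
    t2 = phylo.read_newick(phylo.write_newick(t))
    assert sorted(t2.tip_labels) == sorted(t.tip_labels)
    f1 = phylo.phylo_vcv(t).to_frame()
    f2 = phylo.phylo_vcv(t2).to_frame().loc[f1.index, f1.columns]
    np.testing.assert_allclose(f1.to_numpy(), f2.to_numpy(), atol=1e-9)


def test_malformed_newick_raises():
    with pytest.raises(NewickParseError):
        phylo.read_newick("((A:1,B:1:0;")


def test_duplicate_tip_labels_raise():
    with pytest.raises(TreeError, match="duplicate"):
        phylo.read_newick("(A:1,A:1):0;")


# ---------------------------------------------------------------------------
# Scaling


def test_scale_doubles_each_branch():
    t = phylo.read_newick("((A:10,B:10):37,C:47):0;")
    assert t.max_depth() == 47
    s = phylo.scale_tree_depth(t, 94.0)
    assert s.max_depth() == pytest.approx(94.0, abs=1e-9)
    assert s.tip_depths()["A"] == pytest.approx(94.0)


def test_scale_identity():
    t = random_tree(seed=1, n_taxa=10)
    s = phylo.scale_tree_depth(t, t.max_depth())
    np.testing.assert_allclose(
        phylo.phylo_vcv(s).to_frame().to_numpy(),
        phylo.phylo_vcv(t).to_frame().to_numpy(), rtol=1e-12)


def test_scale_preserves_branch_ratios():
    t = random_tree(seed=2, n_taxa=16)
    s = phylo.scale_tree_depth(t, 131.0)
    assert s.max_depth() == pytest.approx(131.0, abs=1e-9)
    c1 = phylo.phylo_vcv(t).matrix
    c2 = phylo.phylo_vcv(s).matrix
    mask = c1 > 0
    ratios = c2[mask] / c1[mask]
    np.testing.assert_allclose(ratios, ratios[0], rtol=1e-10)


def test_scale_zero_depth_errors():
    t = phylo.read_newick("(A:0,B:0):0;")
    with pytest.raises(TreeError):
        phylo.scale_tree_depth(t, 94.0)


# ---------------------------------------------------------------------------
# Grafting


def test_graft_single_fossil_branch_length():
    host = random_tree(seed=3, n_taxa=8)
    host = phylo.scale_tree_depth(host, 94.0)
    sub = phylo.read_newick("Fossil:0;")
    g = phylo.graft_clade(host, "root", sub, stem_age=131.0,
                          tip_ages={"Fossil": 122.0})
    depths = g.tip_depths()
    assert depths["Fossil"] == pytest.approx(9.0)
    # host tips now reach 131 Ma from the new root
    assert depths["t1"] == pytest.approx(131.0)


def test_graft_polytomy_equal_ages_equal_terminals():
    host = phylo.scale_tree_depth(random_tree(seed=4, n_taxa=6), 94.0)
    sub = phylo.read_newick("(F1:1,F2:1):0;")
    g = phylo.graft_clade(host, "root", sub, stem_age=131.0,
                          tip_ages={"F1": 120.0, "F2": 120.0})
    d = g.tip_depths()
    assert d["F1"] == pytest.approx(d["F2"])
    assert d["F1"] == pytest.approx(131.0 - 120.0)


def test_graft_six_tip_fossil_clade_constraints():
    """Longipterygid-style topology: all branch lengths positive, only fossil
    tips break ultrametricity."""
    host = phylo.scale_tree_depth(random_tree(seed=5, n_taxa=12), 94.0)
    sub = phylo.read_newick(
        "((LxL:1,LxS:1):1,(Sw:1,(Sj:1,(Rp:1,Lr:1):1):1):1):0;")
    ages = {"LxL": 120.0, "LxS": 120.0, "Sw": 122.0, "Sj": 120.0,
            "Rp": 120.0, "Lr": 120.0}
    g = phylo.graft_clade(host, "root", sub, stem_age=131.0, tip_ages=ages)
    d = g.tip_depths()
    for tip, age in ages.items():
        assert d[tip] == pytest.approx(131.0 - age, abs=1e-9)
    for tip in host.tip_labels:
        assert d[tip] == pytest.approx(131.0, abs=1e-9)
    C = phylo.phylo_vcv(g)
    assert np.all(np.diag(C.matrix) > 0)


def test_graft_negative_branch_errors():
    host = phylo.scale_tree_depth(random_tree(seed=6, n_taxa=6), 94.0)
    sub = phylo.read_newick("F:0;")
    with pytest.raises(TreeError):
        phylo.graft_clade(host, "root", sub, stem_age=100.0,
                          tip_ages={"F": 122.0})


# ---------------------------------------------------------------------------
# Covariance


def test_vcv_star_tree():
    t = phylo.read_newick("(" + ",".join(f"t{i}:3" for i in range(6)) + "):0;")
    C = phylo.phylo_vcv(t).matrix
    np.testing.assert_allclose(C, 3.0 * np.eye(6))


def test_vcv_small_tree(small_tree):
    C = phylo.phylo_vcv(small_tree).to_frame()
    assert C.loc["A", "A"] == 2.0
    assert C.loc["A", "B"] == 1.0


def _brute_force_vcv(tree):
    """Independent oracle: pairwise MRCA depth by ancestor-path walking."""
    dt = tree._tree
    depths = {}
    ancestry = {}
    for nd in dt.preorder_node_iter():
        if nd.parent_node is None:
            depths[nd] = nd.edge.length or 0.0
            ancestry[nd] = [nd]
        else:
            depths[nd] = depths[nd.parent_node] + (nd.edge.length or 0.0)
            ancestry[nd] = ancestry[nd.parent_node] + [nd]
    leaves = list(dt.leaf_node_iter())
    n = len(leaves)
    C = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            common = set(ancestry[leaves[i]]) & set(ancestry[leaves[j]])
            C[i, j] = max(depths[nd] for nd in common)
    labels = [lf.taxon.label for lf in leaves]
    return pd.DataFrame(C, index=labels, columns=labels)


@pytest.mark.parametrize("seed", range(10))
def test_vcv_matches_path_walk_oracle(seed):
    n = 4 + (seed * 7) % 61  # up to 64 tips
    t = random_tree(seed=seed + 100, n_taxa=n)
    got = phylo.phylo_vcv(t).to_frame()
    want = _brute_force_vcv(t).loc[got.index, got.columns]
    np.testing.assert_allclose(got.to_numpy(), want.to_numpy(), rtol=1e-10)


def test_vcv_oracle_sweep_many_trees():
    # 100 random trees of <= 64 tips
    for seed in range(90):
        n = 4 + (seed * 13) % 61
        t = random_tree(seed=seed + 500, n_taxa=min(n, 16))
        got = phylo.phylo_vcv(t).to_frame()
        want = _brute_force_vcv(t).loc[got.index, got.columns]
        np.testing.assert_allclose(got.to_numpy(), want.to_numpy(), rtol=1e-10)


# ---------------------------------------------------------------------------
# GLS mean


def test_gls_mean_star_equals_arithmetic(rng):
    C = phylo.PhyloCov(2.5 * np.eye(8), tuple(f"t{i}" for i in range(8)))
    Y = rng.normal(size=(8, 3))
    np.testing.assert_allclose(phylo.phylo_gls_mean(C, Y), Y.mean(axis=0), rtol=1e-10)


def test_gls_mean_constant_trait(tree32):
    C = phylo.phylo_vcv(tree32)
    y = np.full(32, 7.25)
    np.testing.assert_allclose(phylo.phylo_gls_mean(C, y), [7.25], rtol=1e-10)


def test_gls_mean_matches_direct_solve(tree32, rng):
    C = phylo.phylo_vcv(tree32)
    Y = rng.normal(size=(32, 2))
    Ci = np.linalg.inv(C.matrix)
    ones = np.ones(32)
    want = (ones @ Ci @ Y) / (ones @ Ci @ ones)
    np.testing.assert_allclose(phylo.phylo_gls_mean(C, Y), want, rtol=1e-8)


def test_gls_singular_reports_condition_number():
    C = phylo.PhyloCov(np.ones((4, 4)), ("a", "b", "c", "d"))
    with pytest.raises(SingularMatrixError):
        phylo.phylo_gls_mean(C, np.arange(4.0))


# ---------------------------------------------------------------------------
# K / K_mult


def _oracle_k(C, y):
    """Spec formula computed independently with dense inverses."""
    n = len(y)
    Ci = np.linalg.inv(C)
    ones = np.ones(n)
    a = (ones @ Ci @ y) / (ones @ Ci @ ones)
    r = y - a
    mse0 = (r @ r) / (n - 1)
    mse = (r @ Ci @ r) / (n - 1)
    expected = (np.trace(C) - n / (ones @ Ci @ ones)) / (n - 1)
    return (mse0 / mse) / expected


def test_k_exactly_one_on_equal_branch_star(rng):
    t = phylo.read_newick("(" + ",".join(f"t{i}:2" for i in range(10)) + "):0;")
    y = pd.Series(rng.normal(size=10), index=t.tip_labels)
    res = phylo.blomberg_k(t, y, nperm=19, seed=0)
    assert res.statistic == pytest.approx(1.0, abs=1e-12)


def test_k_matches_independent_formula(tree32, rng):
    y = rng.normal(size=32)
    C = phylo.phylo_vcv(tree32).matrix
    res = phylo.blomberg_k(tree32, y, nperm=19, seed=0)
    assert res.statistic == pytest.approx(_oracle_k(C, y), rel=1e-10)


def test_k_constant_trait_errors(tree32):
    with pytest.raises(DegenerateDataError):
        phylo.blomberg_k(tree32, np.ones(32), nperm=19, seed=0)


def test_p_floor_respected(tree32):
    """Strong signal drives p to exactly 1/(nperm+1)."""
    y = synth.simulate_bm_traits(tree32, 5.0, seed=11).data.iloc[:, 0]
    res = phylo.blomberg_k(tree32, y, nperm=999, seed=2)
    assert res.p >= 0.001
    assert res.p == pytest.approx(0.001)


def test_kmult_equals_k_for_one_column():
    for seed in range(50):
        t = random_tree(seed=seed + 900, n_taxa=8 + seed % 9)
        rng = np.random.default_rng(seed)
        y = rng.normal(size=t.n_tips)
        C = phylo.phylo_vcv(t).matrix
        res = phylo.k_mult(t, y[:, None], nperm=0, seed=0)
        assert res.statistic == pytest.approx(_oracle_k(C, y), rel=1e-10)


def test_kmult_duplicated_column_invariant(tree32, rng):
    Y = rng.normal(size=(32, 2))
    a = phylo.k_mult(tree32, Y, nperm=0, seed=0).statistic
    b = phylo.k_mult(tree32, np.hstack([Y, Y]), nperm=0, seed=0).statistic
    assert a == pytest.approx(b, rel=1e-12)


def test_mean_k_near_one_under_bm(tree32):
    ks = []
    for i in range(100):
        y = synth.simulate_bm_traits(tree32, 1.0, seed=3000 + i).data.iloc[:, 0]
        ks.append(phylo.k_mult(tree32, y.to_numpy()[:, None], nperm=0, seed=0).statistic)
    assert 0.8 < np.mean(ks) < 1.2


# ---------------------------------------------------------------------------
# Phylogenetic HSD


def _hsd_groups(tree, k=2):
    return pd.Series({t: chr(65 + i % k) for i, t in enumerate(tree.tip_labels)})


def test_hsd_distance_invariant_under_relabeling(tree32):
    g = _hsd_groups(tree32)
    Y = synth.simulate_bm_traits(tree32, 1.0, seed=21, n_traits=2).data
    res1 = phylo.phylo_hsd(tree32, Y, g, nperm=49, seed=0)
    swapped = g.map({"A": "B", "B": "A"})
    res2 = phylo.phylo_hsd(tree32, Y, swapped, nperm=49, seed=0)
    np.testing.assert_allclose(res1.distances, res2.distances, rtol=1e-10)


def test_hsd_singleton_group_named():
    t = random_tree(seed=31, n_taxa=8)
    g = pd.Series({tip: ("solo" if i == 0 else "rest")
                   for i, tip in enumerate(t.tip_labels)})
    Y = synth.simulate_bm_traits(t, 1.0, seed=1).data
    with pytest.raises(GroupError, match="solo"):
        phylo.phylo_hsd(t, Y, g, nperm=19, seed=0)


def test_hsd_saturates_at_floor(tree32):
    g = _hsd_groups(tree32)
    tm = synth.simulate_bm_traits(tree32, 1.0, seed=8, n_traits=2,
                                  group_map=g.to_dict(),
                                  effects={"B": np.array([100.0, 0.0])})
    res = phylo.phylo_hsd(tree32, tm.data, g, nperm=999, seed=1)
    assert res.p_values[0, 1] == pytest.approx(1.0 / 1000.0)


def test_hsd_p_values_bounded_below(tree32):
    g = _hsd_groups(tree32, k=3)
    Y = synth.simulate_bm_traits(tree32, 1.0, seed=13, n_traits=2).data
    res = phylo.phylo_hsd(tree32, Y, g, nperm=99, seed=3)
    off = res.p_values[~np.eye(3, dtype=bool)]
    assert np.all(off >= 1.0 / 100.0 - 1e-12)
    assert np.allclose(res.p_values, res.p_values.T)
    assert np.all(res.distances >= 0)
    assert np.allclose(np.diag(res.distances), 0)


def test_hsd_power_monotone_in_effect_size(tree32):
    g = _hsd_groups(tree32)
    rates = []
    for effect in (0.0, 1.0, 4.0):
        rej = 0
        for i in range(30):
            tm = synth.simulate_bm_traits(
                tree32, 1.0, seed=7000 + i, n_traits=2, group_map=g.to_dict(),
                effects={"B": np.array([effect, 0.0])})
            res = phylo.phylo_hsd(tree32, tm.data, g, nperm=99, seed=i)
            rej += res.p_values[0, 1] <= 0.05
        rates.append(rej / 30)
    assert rates[0] <= rates[1] <= rates[2]
    assert rates[2] > 0.8
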