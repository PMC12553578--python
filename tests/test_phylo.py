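"""Trees, Grafen lengths, Brownian simulation, phylANOVA, Welch's t."""

import numpy as np
import pytest
from scipy import stats

from obsbias.phylo import (
    bm_simulate,
    estimate_bm_rate,
    grafen_brlen,
    phyl_anova,
    read_newick,
    tip_labels,
    tree_vcv,
    welch_t,
    write_newick,
)


def _star(n, length=1.0):
    return read_newick("(" + ",".join(f"T{i}:{length}" for i in range(n)) + ");")


def _grafen_oracle_heights(newick):
    """Independent recursive computation of Grafen node heights."""
    tree = read_newick(newick)
    n = len(tip_labels(tree))
    heights = {}
    for node in tree.postorder_node_iter():
        tips = 1 if node.is_leaf() else sum(1 for _ in node.leaf_iter())
        heights[node] = (tips - 1) / (n - 1)
    return tree, heights


def test_read_newick_topology():
    t = read_newick("((A,B),(C,D));")
    assert sorted(tip_labels(t)) == ["A", "B", "C", "D"]
    internal = sum(1 for n in t.preorder_node_iter() if not n.is_leaf())
    assert internal == 3


def test_newick_round_trip_preserves_lengths():
    s = "((A:0.1,B:0.2):0.3,(C:0.4,D:0.5):0.6);"
    t = read_newick(s)
    t2 = read_newick(write_newick(t))
    c1, l1 = tree_vcv(t)
    c2, l2 = tree_vcv(t2)
    assert l1 == l2
    np.testing.assert_allclose(c1, c2, atol=1e-9)


def test_duplicate_tips_rejected():
    with pytest.raises(ValueError):
        read_newick("((A,B),A);")


def test_malformed_newick_rejected():
    with pytest.raises(ValueError):
        read_newick("((A,B,(C;")


def test_grafen_star_tree_unit_edges():
    t = grafen_brlen(_star(6))
    for leaf in t.leaf_node_iter():
        assert leaf.edge.length == pytest.approx(1.0)


@pytest.mark.parametrize("power, tip_len, root_len", [(1.0, 1 / 3, 2 / 3), (2.0, 1 / 9, 8 / 9)])
def test_grafen_balanced_quartet(power, tip_len, root_len):
    t = grafen_brlen(read_newick("((A,B),(C,D));"), power=power)
    lengths = sorted(
        (n.edge.length for n in t.preorder_node_iter() if n.parent_node is not None)
    )
    np.testing.assert_allclose(lengths, [tip_len] * 4 + [root_len] * 2, atol=1e-12)


def test_grafen_matches_recursive_oracle_on_asymmetric_tree():
    newick = "(((A,B),C),(D,(E,(F,G))));"
    t = grafen_brlen(read_newick(newick))
    oracle_tree, oracle_h = _grafen_oracle_heights(newick)
    # edge length above each node = parent's height - node's height
    mine = sorted(
        n.edge.length for n in t.preorder_node_iter() if n.parent_node is not None
    )
    ref = sorted(
        oracle_h[n.parent_node] - oracle_h[n]
        for n in oracle_tree.preorder_node_iter()
        if n.parent_node is not None
    )
    np.testing.assert_allclose(mine, ref, atol=1e-12)
    assert min(mine) >= 0


def test_grafen_heights_monotone_lengths_nonnegative():
    import random

    import dendropy

    for seed in range(5):
        t = dendropy.simulate.treesim.birth_death_tree(
            birth_rate=1.0, death_rate=0.0, num_extant_tips=12, rng=random.Random(seed),
        )
        g = grafen_brlen(t)
        for n in g.preorder_node_iter():
            if n.parent_node is not None:
                assert n.edge.length >= 0


def test_bm_zero_rate_gives_constant_tips():
    vals, _ = bm_simulate(_star(5), 0.0, seed=1, nsim=3)
    np.testing.assert_array_equal(vals, 0.0)


def test_bm_tip_variance_matches_closed_form():
    vals, _ = bm_simulate(read_newick("(A:2.0,B:2.0);"), 1.5, seed=2, nsim=10000)
    assert vals[:, 0].var() == pytest.approx(3.0, rel=0.05)


def test_bm_covariance_matches_shared_path_matrix():
    t = grafen_brlen(read_newick("((A,B),(C,(D,E)));"))
    sigma2 = 2.0
    cov, _ = tree_vcv(t)
    vals, _ = bm_simulate(t, sigma2, seed=3, nsim=20000)
    emp = np.cov(vals, rowvar=False)
    err = np.linalg.norm(emp - sigma2 * cov) / np.linalg.norm(sigma2 * cov)
    assert err < 0.05


def test_bm_star_tree_tips_uncorrelated():
    vals, _ = bm_simulate(_star(4), 1.0, seed=4, nsim=20000)
    corr = np.corrcoef(vals, rowvar=False)
    off = corr[~np.eye(4, dtype=bool)]
    assert np.max(np.abs(off)) < 0.05


def test_rate_recovery_on_balanced_tree():
    rng = np.random.default_rng(5)
    t = grafen_brlen(read_newick("(" + ",".join(
        f"({i}a,{i}b)" for i in range(32)) + ");"))
    # build a 64-tip balanced-ish tree instead: use bm data on it
    ests = []
    for rep in range(200):
        vals, labels = bm_simulate(t, 2.0, seed=1000 + rep)
        ests.append(estimate_bm_rate(t, dict(zip(labels, vals[0]))))
    assert np.mean(ests) == pytest.approx(2.0, rel=0.10)


def test_rate_on_star_tree_is_biased_sample_variance():
    x = {"T0": 1.0, "T1": 2.0, "T2": 3.0, "T3": 4.0, "T4": 10.0}
    est = estimate_bm_rate(_star(5), x)
    assert est == pytest.approx(np.var(list(x.values())), abs=1e-10)


def test_rate_constant_tips_zero():
    est = estimate_bm_rate(_star(4), {f"T{i}": 3.3 for i in range(4)})
    assert est == pytest.approx(0.0, abs=1e-12)


def test_phyl_anova_star_tree_matches_parametric_p():
    # iid limit: on a star tree the BM null is an iid Gaussian null, so
    # the simulation p must agree with the F-test p within Monte-Carlo error
    rng = np.random.default_rng(6)
    n = 40
    tree = _star(n)
    x = rng.normal(0, 1, n)
    x[:20] += 0.6
    values = {f"T{i}": float(x[i]) for i in range(n)}
    groups = {f"T{i}": ("a" if i < 20 else "b") for i in range(n)}
    nsim = 2000
    res = phyl_anova(tree, values, groups, nsim=nsim, seed=7)
    f_ref, p_ref = stats.f_oneway(x[:20], x[20:])
    assert res.f_obs == pytest.approx(f_ref, abs=1e-9)
    se = np.sqrt(p_ref * (1 - p_ref) / nsim)
    assert abs(res.p_phyl - p_ref) <= 3 * se + 1 / (nsim + 1)


def test_phyl_anova_f_matches_brute_force_decomposition():
    rng = np.random.default_rng(8)
    n = 24
    tree = grafen_brlen(read_newick("(" + ",".join(
        f"(T{2*i},T{2*i+1})" for i in range(n // 2)) + ");"))
    vals, labels = bm_simulate(tree, 1.0, seed=9)
    groups = {l: i % 3 for i, l in enumerate(labels)}
    res = phyl_anova(tree, dict(zip(labels, vals[0])), groups, nsim=99, seed=10)
    x = vals[0]
    g = np.array([groups[l] for l in labels])
    grand = x.mean()
    ssb = sum((x[g == k].mean() - grand) ** 2 * (g == k).sum() for k in range(3))
    ssw = sum(((x[g == k] - x[g == k].mean()) ** 2).sum() for k in range(3))
    f_ref = (ssb / 2) / (ssw / (n - 3))
    assert res.f_obs == pytest.approx(f_ref, abs=1e-9)


def test_phyl_anova_invariant_to_group_relabeling():
    vals, labels = bm_simulate(grafen_brlen(read_newick("((A,B),(C,(D,(E,F))));")), 1.0, seed=11)
    tree = grafen_brlen(read_newick("((A,B),(C,(D,(E,F))));"))
    tip_vals = dict(zip(labels, vals[0]))
    g1 = {l: ("x" if i % 2 else "y") for i, l in enumerate(labels)}
    g2 = {l: ("y" if i % 2 else "x") for i, l in enumerate(labels)}
    r1 = phyl_anova(tree, tip_vals, g1, nsim=199, seed=12)
    r2 = phyl_anova(tree, tip_vals, g2, nsim=199, seed=12)
    assert r1.p_phyl == r2.p_phyl
    assert r1.f_obs == pytest.approx(r2.f_obs, abs=1e-12)


def test_phyl_anova_type_one_error_calibrated():
    # random labels on BM data: rejection at alpha=0.05 within 2 s.e.
    reps, nsim = 200, 999
    tree = grafen_brlen(read_newick("(" + ",".join(
        f"(T{2*i},T{2*i+1})" for i in range(16)) + ");"))
    labels = tip_labels(tree)
    rng = np.random.default_rng(13)
    rejections = 0
    for rep in range(reps):
        vals, vlabels = bm_simulate(tree, 1.0, seed=20000 + rep)
        perm = rng.permutation(len(labels))
        groups = {vlabels[i]: ("a" if perm[i] < 16 else "b") for i in range(len(labels))}
        res = phyl_anova(tree, dict(zip(vlabels, vals[0])), groups, nsim=nsim, seed=30000 + rep)
        rejections += res.p_phyl <= 0.05
    rate = rejections / reps
    se = np.sqrt(0.05 * 0.95 / reps)
    assert abs(rate - 0.05) <= 2 * se + 1e-12


def test_phyl_anova_small_group_error():
    tree = _star(5)
    vals = {f"T{i}": float(i) for i in range(5)}
    groups = {"T0": "a", "T1": "a", "T2": "a", "T3": "a", "T4": "b"}
    with pytest.raises(ValueError):
        phyl_anova(tree, vals, groups, nsim=10, seed=0)


def test_welch_identical_samples():
    res = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert res.t == pytest.approx(0.0)
    assert res.p_value == pytest.approx(1.0)


def test_welch_formula_oracle_and_scipy():
    res = welch_t([1, 2, 3], [2, 4, 6])
    assert res.t == pytest.approx(-1.5492, abs=1e-4)
    assert res.df == pytest.approx(2.9412, abs=1e-4)
    ref = stats.ttest_ind([1, 2, 3], [2, 4, 6], equal_var=False)
    assert res.t == pytest.approx(ref.statistic, abs=1e-12)
    assert res.p_value == pytest.approx(ref.pvalue, abs=1e-12)


def test_welch_antisymmetry():
    rng = np.random.default_rng(14)
    a, b = rng.normal(0, 1, 10), rng.normal(1, 2, 14)
    r1, r2 = welch_t(a, b), welch_t(b, a)
    assert r1.t == pytest.approx(-r2.t, abs=1e-12)
    assert r1.p_value == pytest.approx(r2.p_value, abs=1e-12)
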