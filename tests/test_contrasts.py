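import math

import numpy as np
import pytest

from phylodiet.contrasts import (
    DEFAULT_TRANSFORM_GRID,
    contrast_correlation,
    nonphylo_correlation,
    pic,
    standardization_diagnostics,
    standardize_branches,
)
from phylodiet.errors import NotBinaryError, ValidationError
from phylodiet.simulate import simulate_tree, simulate_traits
from phylodiet.trees import parse_newick
from test_signal import R_TREE, R_X

# ape::pic on the same 8-tip fixture (ape 5.8-1), keyed by contrast clade
R_PIC = {
    frozenset({"t2", "t3"}): -0.8964588,
    frozenset({"t2", "t3", "t7"}): -0.7032861,
    frozenset({"t2", "t3", "t6", "t7"}): -0.458453,
    frozenset({"t1", "t4"}): -0.5143091,
    frozenset({"t1", "t4", "t8"}): 0.1547294,
    frozenset({"t1", "t2", "t3", "t4", "t6", "t7", "t8"}): -0.20829,
    frozenset({"t1", "t2", "t3", "t4", "t5", "t6", "t7", "t8"}): 0.2615615,
}


class TestPic:
    def test_two_tip_formula(self, tree2):
        cs = pic({"A": 0.0, "B": 2.0}, tree2)
        assert cs.contrasts[0] == pytest.approx(-2 / math.sqrt(2))
        assert cs.sds[0] == pytest.approx(math.sqrt(2))

    def test_three_tip_hand_recursion(self, tree3):
        cs = pic({"A": 0.0, "B": 2.0, "C": 1.0}, tree3)
        by_clade = dict(zip(map(frozenset, cs.node_clades), cs.contrasts))
        sd_by_clade = dict(zip(map(frozenset, cs.node_clades), cs.sds))
        assert by_clade[frozenset("AB")] == pytest.approx(-math.sqrt(2))
        # node value 1, adjusted branch 1 + 0.5, contrast (1-1)/sqrt(3.5)
        assert by_clade[frozenset("ABC")] == pytest.approx(0.0)
        assert sd_by_clade[frozenset("ABC")] == pytest.approx(math.sqrt(3.5))

    def test_matches_independent_r_pic(self):
        cs = pic(R_X, parse_newick(R_TREE))
        got = dict(zip(map(frozenset, cs.node_clades), cs.contrasts))
        for clade, expected in R_PIC.items():
            assert got[clade] == pytest.approx(expected, abs=1e-6)

    @pytest.mark.parametrize("n", [5, 17, 40])
    def test_n_minus_one_contrasts(self, n):
        rng = np.random.default_rng(n)
        tree = simulate_tree(n, rng)
        cs = pic(simulate_traits(tree, rng), tree)
        assert len(cs) == n - 1
        assert (cs.sds > 0).all()

    def test_sum_of_squares_equals_gls_residual_quadratic(self):
        """Parsimony-free identity: sum of squared standardized contrasts
        equals the GLS residual quadratic form (dense-matrix oracle)."""
        for seed in (70, 71, 72):
            rng = np.random.default_rng(seed)
            tree = simulate_tree(6, rng)
            x = simulate_traits(tree, rng)
            cs = pic(x, tree)
            C = tree.covariance().matrix
            xv = tree.align_trait(dict(x.items()))
            Ci = np.linalg.inv(C)
            one = np.ones(len(xv))
            mu = float(one @ Ci @ xv) / float(one @ Ci @ one)
            q = float((xv - mu) @ Ci @ (xv - mu))
            assert float(np.sum(cs.contrasts**2)) == pytest.approx(q, rel=1e-9)

    def test_shift_invariance_and_scaling(self):
        rng = np.random.default_rng(73)
        tree = simulate_tree(12, rng)
        x = simulate_traits(tree, rng)
        base = pic(x, tree)
        shifted = pic({k: v + 9.0 for k, v in x.items()}, tree)
        scaled = pic({k: -2.0 * v for k, v in x.items()}, tree)
        assert np.allclose(shifted.contrasts, base.contrasts)
        assert np.allclose(scaled.contrasts, -2.0 * base.contrasts)

    def test_child_order_sign_convention(self):
        """(first child - second child): swapping children in the Newick
        flips the contrast sign, so the convention must be deterministic."""
        t_ab = parse_newick("((A:1,B:1):1,C:2);")
        t_ba = parse_newick("((B:1,A:1):1,C:2);")
        x = {"A": 0.0, "B": 2.0, "C": 1.0}
        c_ab = dict(zip(map(frozenset, pic(x, t_ab).node_clades), pic(x, t_ab).contrasts))
        c_ba = dict(zip(map(frozenset, pic(x, t_ba).node_clades), pic(x, t_ba).contrasts))
        assert c_ab[frozenset("AB")] == pytest.approx(-c_ba[frozenset("AB")])

    def test_polytomy_rejected(self):
        t = parse_newick("(A:1,B:1,C:1);")
        with pytest.raises(NotBinaryError):
            pic({"A": 0, "B": 1, "C": 2}, t)

    def test_zero_internal_branch_floored_with_warning(self):
        t = parse_newick("(((A:1,B:1):0,C:1):1,D:2);")
        with pytest.warns(UserWarning, match="zero-length"):
            cs = pic({"A": 0, "B": 1, "C": 2, "D": 3}, t)
        assert np.isfinite(cs.contrasts).all()

    def test_both_child_branches_zero_rejected(self):
        t = parse_newick("((A:0,B:0):1,C:2);")
        with pytest.raises(ValidationError):
            pic({"A": 0, "B": 1, "C": 2}, t)


class TestDiagnostics:
    def test_perfect_linear_trend_detected(self):
        rng = np.random.default_rng(74)
        tree = simulate_tree(30, rng)
        cs = pic(simulate_traits(tree, rng), tree)
        cs.contrasts = 2.0 * cs.sds  # |contrast| exactly linear in SD
        d = standardization_diagnostics(cs)
        assert d["pearson"].coefficient == pytest.approx(1.0)
        assert d["pearson"].p_value < 1e-6

    def test_too_few_contrasts_rejected(self, tree3):
        cs = pic({"A": 0, "B": 1, "C": 2}, tree3)
        with pytest.raises(ValidationError):
            standardization_diagnostics(cs)

    def test_constant_sds_kendall_not_applicable(self):
        t = parse_newick("(((A:1,B:1):1,(C:1,D:1):1):1,(E:2,F:2):1);")
        cs = pic({"A": 0, "B": 1, "C": 2, "D": 0, "E": 1, "F": 2}, t)
        cs.sds = np.ones_like(cs.sds)
        d = standardization_diagnostics(cs)
        assert not d["kendall"].applicable


class TestStandardizeBranches:
    def test_already_standardized_keeps_identity(self):
        rng = np.random.default_rng(75)
        tree = simulate_tree(50, rng)
        x = simulate_traits(tree, rng)
        cs, diag, trail = standardize_branches(x, tree)
        assert cs.transform == ("none", 1.0)
        assert len(trail) == 1

    def test_depth_distorted_trait_selects_transform(self):
        # evolve under a strong delta distortion: raw branch lengths are
        # mis-standardized and some non-identity transform must be chosen
        for seed in (76, 77, 78, 79):
            rng = np.random.default_rng(seed)
            tree = simulate_tree(80, rng)
            x = simulate_traits(tree, rng, model="delta", param=3.0)
            cs_raw = pic(x, tree)
            d_raw = standardization_diagnostics(cs_raw)
            if all(r.p_value > 0.05 for r in d_raw.values()):
                continue  # this replicate happens to pass raw; try next
            cs, diag, trail = standardize_branches(x, tree)
            assert cs.transform != ("none", 1.0)
            assert all((not r.applicable) or r.p_value > 0.05 for r in diag.values())
            return
        pytest.fail("no replicate produced a raw standardization failure")

    def test_empty_grid_with_failing_raw_reports_best(self):
        rng = np.random.default_rng(82)
        tree = simulate_tree(60, rng)
        x = simulate_traits(tree, rng, model="delta", param=3.0)
        d_raw = standardization_diagnostics(pic(x, tree))
        assert min(r.p_value for r in d_raw.values()) < 0.05  # precondition
        with pytest.raises(ValidationError, match="best candidate"):
            standardize_branches(x, tree, grid=[("power", 1.0)])

    def test_grid_order_identity_first(self):
        assert DEFAULT_TRANSFORM_GRID[0] == ("none", 1.0)
        kinds = [k for k, _ in DEFAULT_TRANSFORM_GRID]
        assert kinds.index("log") > max(i for i, k in enumerate(kinds) if k == "power")


class TestCorrelations:
    def test_proportional_contrasts_give_r_one(self):
        rng = np.random.default_rng(81)
        tree = simulate_tree(20, rng)
        x = simulate_traits(tree, rng)
        cs_x = pic(x, tree)
        cs_y = pic({k: 2.0 * v for k, v in x.items()}, tree)
        res = contrast_correlation(cs_x, cs_y)
        assert res["pearson"].coefficient == pytest.approx(1.0)
        assert res["kendall"].coefficient == pytest.approx(1.0)

    def test_through_origin_invariant_to_child_swap(self):
        x = {"A": 0.0, "B": 2.0, "C": 1.0, "D": 3.0}
        y = {"A": 1.0, "B": 0.5, "C": 2.0, "D": 0.0}
        t1 = parse_newick("(((A:1,B:1):1,C:2):1,D:3);")
        t2 = parse_newick("(((B:1,A:1):1,C:2):1,D:3);")  # cherry swapped
        r1 = contrast_correlation(pic(x, t1), pic(y, t1), through_origin=True)
        r2 = contrast_correlation(pic(x, t2), pic(y, t2), through_origin=True)
        assert r1["pearson"].coefficient == pytest.approx(r2["pearson"].coefficient)

    def test_node_set_mismatch_rejected(self):
        rng = np.random.default_rng(82)
        t1 = simulate_tree(10, rng)
        t2 = simulate_tree(10, rng)
        cs1 = pic(simulate_traits(t1, rng), t1)
        cs2 = pic(simulate_traits(t2, rng), t2)
        with pytest.raises(ValidationError):
            contrast_correlation(cs1, cs2)

    def test_nonphylo_identity(self):
        x = {f"s{i}": float(i) for i in range(10)}
        res = nonphylo_correlation(x, x)
        assert res.coefficient == pytest.approx(1.0)

    def test_nonphylo_genus_exclusion(self):
        x = {"Anser_a": 1.0, "Anser_b": 2.0, "Branta_a": 3.0, "Branta_b": 4.0, "Anas_a": 5.0}
        y = dict(x)
        res = nonphylo_correlation(x, y, exclude=["Anser"])
        assert res.n == 3

    def test_nonphylo_too_few_shared_rejected(self):
        with pytest.raises(ValidationError):
            nonphylo_correlation({"a": 1.0, "b": 2.0}, {"a": 1.0, "b": 2.0})
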