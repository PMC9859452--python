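"""Bray-Curtis and the UniFrac family."""

import io

import numpy as np
import pytest
from scipy.spatial.distance import braycurtis as scipy_braycurtis

from microvol.core import read_tree
from microvol.dissimilarity import (
    bray_curtis,
    generalized_unifrac,
    pairwise_dissimilarities,
    unweighted_unifrac,
    weighted_unifrac,
)
from microvol.pairing import PairingSpec, enumerate_pairs

from conftest import make_table


def star_tree(n, length=1.0):
    """Star-equivalent rooted tree: zero-length internal branches, so only
    the per-leaf branches carry length (skbio wants a bifurcating root)."""
    newick = f"L0:{length:g}"
    for j in range(1, n):
        newick = f"({newick},L{j}:{length:g}):0"
    return read_tree(io.StringIO(newick + ";"))


def random_tree(rng, n_leaves):
    """Random binary tree by successive joins, random branch lengths; the
    root carries no length (it sits above all signal)."""
    nodes = [f"L{j}:{rng.uniform(0.1, 2):.6f}" for j in range(n_leaves)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        joined = f"({a},{b})"
        if len(nodes) > 0:
            joined += f":{rng.uniform(0.1, 2):.6f}"
        nodes.append(joined)
    return read_tree(io.StringIO(nodes[0] + ";"))


THREE_LEAF = "((A:1,B:1):1,C:2);"


class TestBrayCurtis:
    def test_identical_vectors(self):
        assert bray_curtis([1, 2, 3], [1, 2, 3]) == 0.0

    def test_disjoint_supports(self):
        assert bray_curtis([5, 0, 0], [0, 3, 2]) == 1.0

    def test_worked_example(self):
        assert bray_curtis([2, 6, 2], [4, 0, 6]) == pytest.approx(0.6)

    def test_matches_scipy_on_random_vectors(self):
        rng = np.random.default_rng(4)
        for _ in range(30):
            x = rng.integers(0, 40, 10)
            y = rng.integers(0, 40, 10)
            if x.sum() == 0 or y.sum() == 0:
                continue
            assert bray_curtis(x, y) == pytest.approx(
                scipy_braycurtis(x, y), abs=1e-12
            )

    def test_symmetry(self):
        assert bray_curtis([1, 5, 2], [3, 1, 4]) == bray_curtis([3, 1, 4], [1, 5, 2])


class TestUnweightedUniFrac:
    def test_identical_presence_sets(self):
        tree = read_tree(io.StringIO(THREE_LEAF))
        assert unweighted_unifrac([1, 1, 0], [5, 9, 0], tree, ["A", "B", "C"]) == 0.0

    def test_disjoint_star_tree_leaves(self):
        tree = star_tree(4)
        taxa = [f"L{j}" for j in range(4)]
        assert unweighted_unifrac([1, 1, 0, 0], [0, 0, 1, 1], tree, taxa) == 1.0

    def test_three_leaf_branch_walk_oracle(self):
        # x present {A,B}, y present {A,C}: unique branches are B (1) and
        # C (2); shared are A (1) and the AB stem (1, on x's side the whole
        # subtree, on y's side via A). 3 / 5 by exhaustive branch listing.
        tree = read_tree(io.StringIO(THREE_LEAF))
        got = unweighted_unifrac([1, 1, 0], [1, 0, 1], tree, ["A", "B", "C"])
        assert got == pytest.approx(3 / 5)

    def test_depends_only_on_presence(self):
        tree = read_tree(io.StringIO(THREE_LEAF))
        a = unweighted_unifrac([1, 1, 0], [1, 0, 1], tree, ["A", "B", "C"])
        b = unweighted_unifrac([9, 3, 0], [2, 0, 7], tree, ["A", "B", "C"])
        assert a == b


class TestWeightedUniFrac:
    def test_identical_compositions(self):
        tree = read_tree(io.StringIO(THREE_LEAF))
        p = [0.5, 0.3, 0.2]
        assert weighted_unifrac(p, p, tree, ["A", "B", "C"]) == pytest.approx(0.0)

    def test_star_tree_raw_form_is_l1(self):
        tree = star_tree(3)
        px, py = np.array([0.5, 0.3, 0.2]), np.array([0.1, 0.6, 0.3])
        got = weighted_unifrac(px, py, tree, ["L0", "L1", "L2"], normalized=False)
        assert got == pytest.approx(np.abs(px - py).sum())

    def test_symmetric(self):
        tree = read_tree(io.StringIO(THREE_LEAF))
        px, py = [0.5, 0.3, 0.2], [0.2, 0.2, 0.6]
        assert weighted_unifrac(px, py, tree, ["A", "B", "C"]) == pytest.approx(
            weighted_unifrac(py, px, tree, ["A", "B", "C"])
        )

    def test_matches_skbio_on_integer_counts(self):
        # scikit-bio's weighted UniFrac works on integer count vectors; it
        # is the independent oracle for the branch-traversal implementation
        from skbio.diversity.beta import weighted_unifrac as skbio_weighted

        rng = np.random.default_rng(8)
        for _ in range(15):
            tree = random_tree(rng, 6)
            taxa = [f"L{j}" for j in range(6)]
            x = rng.integers(0, 50, 6)
            y = rng.integers(0, 50, 6)
            if x.sum() == 0 or y.sum() == 0:
                continue
            for normalized in (True, False):
                mine = weighted_unifrac(x, y, tree, taxa, normalized=normalized)
                ref = skbio_weighted(x, y, taxa=taxa, tree=tree, normalized=normalized)
                assert mine == pytest.approx(float(ref), abs=1e-12)


class TestGeneralizedUniFrac:
    def test_identical_compositions_zero_for_all_alpha(self):
        tree = read_tree(io.StringIO(THREE_LEAF))
        p = [0.5, 0.3, 0.2]
        for alpha in (0.0, 0.25, 0.5, 1.0):
            assert generalized_unifrac(p, p, tree, ["A", "B", "C"], alpha) == 0.0

    def test_alpha_one_equals_normalized_weighted(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            tree = random_tree(rng, 8)
            taxa = [f"L{j}" for j in range(8)]
            px = rng.dirichlet(np.ones(8))
            py = rng.dirichlet(np.ones(8))
            assert generalized_unifrac(px, py, tree, taxa, 1.0) == pytest.approx(
                weighted_unifrac(px, py, tree, taxa, normalized=True), abs=1e-12
            )

    def test_three_leaf_worked_instance_alpha_half(self):
        # exhaustive branch enumeration for ((A:1,B:1):1,C:2) with
        # px=(0.5,0.5,0), py=(0.25,0,0.75):
        # branches: A(1): A=.5,B=.25; B(1): .5,0; AB-stem(1): 1,.25; C(2): 0,.75
        tree = read_tree(io.StringIO(THREE_LEAF))
        px, py = [0.5, 0.5, 0.0], [0.25, 0.0, 0.75]
        num = den = 0.0
        for blen, a, b in [(1, 0.5, 0.25), (1, 0.5, 0.0), (1, 1.0, 0.25), (2, 0.0, 0.75)]:
            w = blen * (a + b) ** 0.5
            num += w * abs(a - b) / (a + b)
            den += w
        got = generalized_unifrac(px, py, tree, ["A", "B", "C"], 0.5)
        assert got == pytest.approx(num / den, abs=1e-12)

    def test_continuous_in_alpha(self):
        rng = np.random.default_rng(6)
        tree = random_tree(rng, 6)
        taxa = [f"L{j}" for j in range(6)]
        px, py = rng.dirichlet(np.ones(6)), rng.dirichlet(np.ones(6))
        grid = np.linspace(0, 1, 21)
        vals = [generalized_unifrac(px, py, tree, taxa, a) for a in grid]
        assert np.max(np.abs(np.diff(vals))) < 0.2

    def test_alpha_outside_unit_interval_rejected(self):
        tree = star_tree(3)
        with pytest.raises(ValueError):
            generalized_unifrac([1, 0, 0], [0, 1, 0], tree, ["L0", "L1", "L2"], 1.5)


class TestPairwise:
    def test_bray_curtis_records_in_unit_interval(self, daily_table):
        pairs = enumerate_pairs(daily_table, PairingSpec(1.0))
        out = pairwise_dissimilarities(daily_table, pairs, "bray_curtis")
        assert len(out) == len(pairs)
        assert out["value"].between(0, 1).all()

    def test_unifrac_without_tree_is_informative_error(self, daily_table):
        pairs = enumerate_pairs(daily_table, PairingSpec(1.0))
        with pytest.raises(ValueError, match="requires a phylogenetic tree"):
            pairwise_dissimilarities(daily_table, pairs, "weighted_unifrac")

    def test_identical_samples_are_zero_under_every_metric(self):
        table = make_table(
            [[3, 3], [2, 2], [5, 5]], ["A", "A"], [0, 1], taxa=["A", "B", "C"]
        )
        pairs = enumerate_pairs(table, PairingSpec(1.0))
        tree = read_tree(io.StringIO(THREE_LEAF))
        for metric in (
            "bray_curtis",
            "unweighted_unifrac",
            "generalized_unifrac",
            "weighted_unifrac",
        ):
            out = pairwise_dissimilarities(table, pairs, metric, tree=tree)
            assert out["value"].iloc[0] == pytest.approx(0.0, abs=1e-12)
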