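"""Species-tree (Yule) and multispecies-coalescent simulator tests."""

import math
from fractions import Fraction

import numpy as np
import pytest

from coalbench.treesim import (
    MSCSimulator,
    concordance_probability,
    is_ultrametric,
    node_ages,
    pairwise_mrca_times,
    simulate_msc_gene_tree,
    simulate_species_tree,
    topology_key,
    tree_depth,
)
from helpers import parse_tree, shape_key


@pytest.mark.parametrize("depth", [1.0, 10.0])
def test_species_tree_invariants(depth, rng):
    """Simulated species trees are binary, ultrametric, exactly at depth."""
    for _ in range(5):
        tree = simulate_species_tree(8, depth, rng)
        leaves = [l.taxon.label for l in tree.leaf_node_iter()]
        assert sorted(leaves) == [f"s{i}" for i in range(1, 9)] or len(set(leaves)) == 8
        assert all(len(n.child_nodes()) == 2 for n in tree.preorder_internal_node_iter())
        assert is_ultrametric(tree)
        assert tree_depth(tree) == pytest.approx(depth, rel=1e-9)
        for edge in tree.preorder_edge_iter():
            if edge.length is not None:
                assert edge.length > 0


def test_two_taxon_cherry(rng):
    tree = simulate_species_tree(2, 5.0, rng)
    lengths = [l.edge.length for l in tree.leaf_node_iter()]
    assert lengths == pytest.approx([5.0, 5.0])


def test_invalid_parameters(rng):
    with pytest.raises(ValueError):
        simulate_species_tree(1, 1.0, rng)
    with pytest.raises(ValueError):
        simulate_species_tree(8, 0.0, rng)
    with pytest.raises(ValueError):
        simulate_species_tree(8, -2.0, rng)


def test_species_tree_determinism():
    t1 = simulate_species_tree(8, 1.0, np.random.default_rng(42))
    t2 = simulate_species_tree(8, 1.0, np.random.default_rng(42))
    assert t1.as_string(schema="newick") == t2.as_string(schema="newick")


def _yule_shape_probs(n):
    """Exact shape distribution of the Yule growth process by enumeration:
    starting from a cherry, repeatedly replace a uniformly chosen leaf with
    a cherry (each choice has probability 1/k at k leaves)."""

    def leaves(t):
        return 1 if t == "L" else sum(leaves(c) for c in t)

    def replace(t, target):
        # new tree with preorder leaf #target expanded into a cherry

        def rec(t, idx):
            if t == "L":
                new = ("L", "L") if idx[0] == target else "L"
                idx[0] += 1
                return new
            return tuple(rec(c, idx) for c in t)

        return rec(t, [0])

    def canon(t):
        if t == "L":
            return "L"
        return tuple(sorted((canon(c) for c in t), key=repr))

    probs = {}

    def grow(tree, p):
        k = leaves(tree)
        if k == n:
            key = canon(tree)
            probs[key] = probs.get(key, Fraction(0)) + p
            return
        for target in range(k):
            grow(replace(tree, target), p * Fraction(1, k))

    grow(("L", "L"), Fraction(1))
    return probs


def test_yule_topology_distribution_matches_enumeration(rng):
    """The fraction of balanced 4-taxon shapes matches the exact Yule
    probability from brute-force enumeration of growth histories."""
    probs = _yule_shape_probs(4)
    balanced = (("L", "L"), ("L", "L"))
    p_bal = float(probs[balanced])
    assert sum(probs.values()) == 1
    n_rep = 10_000
    hits = sum(
        shape_key(simulate_species_tree(4, 1.0, rng)) == balanced for _ in range(n_rep)
    )
    se = math.sqrt(p_bal * (1 - p_bal) / n_rep)
    assert abs(hits / n_rep - p_bal) < 3 * se


def test_msc_invariants(rng):
    """Every gene tree is ultrametric with tmrca at or above the species root."""
    sp = simulate_species_tree(8, 1.0, rng)
    sim = MSCSimulator(sp)
    for _ in range(50):
        gt = sim.simulate(rng)
        assert is_ultrametric(gt)
        assert gt.tmrca >= 1.0 - 1e-12
        assert sorted(l.taxon.label for l in gt.leaf_node_iter()) == sorted(
            l.taxon.label for l in sp.leaf_node_iter()
        )


def test_msc_rejects_malformed_species_trees(rng):
    bad = parse_tree("((a:1,b:2):1,c:2);")  # not ultrametric
    with pytest.raises(ValueError):
        simulate_msc_gene_tree(bad, rng)
    poly = parse_tree("(a:1,b:1,c:1);")  # not binary
    with pytest.raises(ValueError):
        simulate_msc_gene_tree(poly, rng)


def test_msc_three_taxon_concordance(rng):
    """Concordant-topology fraction matches 1 - (2/3) e^(-t) (t = 1)."""
    sp = parse_tree("((A:1.0,B:1.0):1.0,C:2.0);")
    sim = MSCSimulator(sp)
    match = frozenset([frozenset(["A", "B"])])
    n_rep = 5_000
    hits = 0
    for _ in range(n_rep):
        key, _ = sim.simulate_topology(rng)
        hits += key == match
    p = concordance_probability(1.0)
    se = math.sqrt(p * (1 - p) / n_rep)
    assert abs(hits / n_rep - p) < 3 * se


def test_msc_two_species_mean_coalescence(rng):
    """Mean pairwise coalescence time is divergence + 1 (Exp(1) above the split)."""
    sp = parse_tree("(A:2.0,B:2.0);")
    sim = MSCSimulator(sp)
    n_rep = 5_000
    times = np.array([sim.simulate_topology(rng)[1] for _ in range(n_rep)])
    se = times.std(ddof=1) / math.sqrt(n_rep)
    assert abs(times.mean() - 3.0) < 3 * se


def test_deeper_trees_give_more_concordant_gene_trees(rng):
    """At depth 10N the gene tree matches the species tree more often than
    at depth 1N (paired across the same base topologies)."""
    wins_10, wins_1 = 0, 0
    for _ in range(20):
        base = simulate_species_tree(8, 1.0, rng)
        sims = {}
        for depth in (1.0, 10.0):
            scaled = base.clone(depth=1)
            for e in scaled.preorder_edge_iter():
                if e.length is not None:
                    e.length *= depth
            sims[depth] = MSCSimulator(scaled)
        truth = topology_key(base)
        for _ in range(50):
            wins_1 += sims[1.0].simulate_topology(rng)[0] == truth
            wins_10 += sims[10.0].simulate_topology(rng)[0] == truth
    assert wins_10 > wins_1


def test_msc_determinism():
    sp = simulate_species_tree(8, 10.0, np.random.default_rng(7))
    g1 = simulate_msc_gene_tree(sp, np.random.default_rng(9))
    g2 = simulate_msc_gene_tree(sp, np.random.default_rng(9))
    assert g1.as_string(schema="newick") == g2.as_string(schema="newick")


def test_concordance_probability_values():
    assert concordance_probability(0.0) == pytest.approx(1 / 3)
    assert concordance_probability(math.inf) == pytest.approx(1.0)
    assert concordance_probability(1.0) == pytest.approx(1 - (2 / 3) * math.exp(-1), abs=1e-12)
    assert concordance_probability(1.0) == pytest.approx(0.754747, abs=1e-6)
    with pytest.raises(ValueError):
        concordance_probability(-0.1)


def test_pairwise_mrca_times(rng):
    sp = parse_tree("((A:1.0,B:1.0):1.0,C:2.0);")
    labels, mat = pairwise_mrca_times(sp)
    assert labels == ["A", "B", "C"]
    assert mat[0, 1] == pytest.approx(1.0)
    assert mat[0, 2] == pytest.approx(2.0)
    assert mat[1, 2] == pytest.approx(2.0)
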