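"""GLASS and MDC species-tree estimator tests."""

import itertools

import numpy as np
import pytest

from coalbench.speciestree import (
    count_extra_lineages,
    glass_species_tree,
    mdc_species_tree,
    min_coalescence_matrix,
)
from coalbench.treesim import (
    MSCSimulator,
    is_ultrametric,
    pairwise_mrca_times,
    simulate_species_tree,
    topology_key,
    tree_depth,
)
from helpers import parse_tree


# ---------------------------------------------------------------------------
# GLASS
# ---------------------------------------------------------------------------

def test_glass_single_gene_tree_reproduces_it(rng):
    """Single-linkage on one ultrametric tree's own MRCA matrix gives back
    that tree."""
    sp = simulate_species_tree(8, 10.0, rng)
    gt = MSCSimulator(sp).simulate(rng)
    est = glass_species_tree([gt])
    assert topology_key(est) == topology_key(gt)
    assert is_ultrametric(est, rtol=1e-6)


def test_glass_two_species_minimum_join():
    """Across loci with coalescence times {3.1, 2.4, 2.8} the two species
    join at the minimum, 2.4."""
    gts = [parse_tree(f"(A:{t},B:{t});") for t in (3.1, 2.4, 2.8)]
    est = glass_species_tree(gts)
    assert tree_depth(est) == pytest.approx(2.4)


def test_glass_join_heights_bounded_by_min_times(rng):
    """Single-linkage contract: every MRCA age of the estimate is at most
    the corresponding minimum coalescence time."""
    sp = simulate_species_tree(6, 5.0, rng)
    sim = MSCSimulator(sp)
    gts = [sim.simulate(rng) for _ in range(10)]
    labels, dmin = min_coalescence_matrix(gts)
    est = glass_species_tree(gts)
    est_labels, est_times = pairwise_mrca_times(est)
    assert est_labels == labels
    assert (est_times <= dmin + 1e-9).all()


def test_glass_recovers_truth_from_true_gene_trees(rng):
    """With 200 true gene trees from a depth-10 species tree, the minimum
    coalescence times hug the speciation times and the topology is
    recovered in >= 95 of 100 replicates."""
    hits = 0
    for _ in range(100):
        sp = simulate_species_tree(8, 10.0, rng)
        sim = MSCSimulator(sp)
        gts = [sim.simulate(rng) for _ in range(200)]
        hits += topology_key(glass_species_tree(gts)) == topology_key(sp)
    assert hits >= 95


def test_glass_rejects_nonultrametric():
    with pytest.raises(ValueError):
        glass_species_tree([parse_tree("((A:1,B:3):1,C:2);")])
    with pytest.raises(ValueError):
        glass_species_tree([])


def test_glass_deterministic(rng):
    sp = simulate_species_tree(8, 10.0, rng)
    sim = MSCSimulator(sp)
    gts = [sim.simulate(rng) for _ in range(5)]
    t1 = glass_species_tree(gts).as_string(schema="newick")
    t2 = glass_species_tree(gts).as_string(schema="newick")
    assert t1 == t2


# ---------------------------------------------------------------------------
# MDC
# ---------------------------------------------------------------------------

def test_extra_lineages_concordant_is_zero(rng):
    sp = simulate_species_tree(8, 10.0, rng)
    assert count_extra_lineages(sp, sp) == 0


def test_extra_lineages_three_taxon_example():
    sp = parse_tree("((A,B),C);")
    gt = parse_tree("((B,C),A);")
    assert count_extra_lineages(sp, gt) == 1


def _oracle_extra_lineages(species, gene):
    """Independent embedding oracle: each leaf climbs the gene tree while
    its ancestor's leaf set stays inside the species cluster; the number of
    distinct stopping points is the lineage count exiting that branch."""
    sp_leafsets = {}
    for node in species.postorder_node_iter():
        sp_leafsets[node] = (
            frozenset([node.taxon.label])
            if node.is_leaf()
            else frozenset().union(*(sp_leafsets[c] for c in node.child_nodes()))
        )
    g_leafsets = {}
    for node in gene.postorder_node_iter():
        g_leafsets[node] = (
            frozenset([node.taxon.label])
            if node.is_leaf()
            else frozenset().union(*(g_leafsets[c] for c in node.child_nodes()))
        )
    leaves = {l.taxon.label: l for l in gene.leaf_node_iter()}
    root_set = sp_leafsets[species.seed_node]
    total = 0
    for node, cluster in sp_leafsets.items():
        if node.is_leaf() or cluster == root_set:
            continue
        endpoints = set()
        for lab in cluster:
            g = leaves[lab]
            while g.parent_node is not None and g_leafsets[g.parent_node] <= cluster:
                g = g.parent_node
            endpoints.add(g)
        total += len(endpoints) - 1
    return total


def test_extra_lineages_matches_embedding_oracle(rng):
    """Caterpillar vs mirrored caterpillar, plus random pairs, agree with an
    independent lineage-climbing embedding."""
    cat = parse_tree("(A,(B,(C,(D,(E,(F,(G,H)))))));")
    mirror = parse_tree("(A,(H,(B,(G,(C,(F,(D,E)))))));")
    assert count_extra_lineages(cat, mirror) == _oracle_extra_lineages(cat, mirror)
    for _ in range(20):
        sp = simulate_species_tree(6, 1.0, rng)
        gt = MSCSimulator(sp).simulate(rng)
        assert count_extra_lineages(sp, gt) == _oracle_extra_lineages(sp, gt)


def test_extra_lineages_taxon_mismatch():
    with pytest.raises(ValueError):
        count_extra_lineages(parse_tree("((A,B),C);"), parse_tree("((A,B),D);"))


def test_mdc_worked_three_taxon_example():
    """Gene-tree counts {7, 2, 1} over the three triplet topologies give
    minimizer ((A,B),C) with total score 3 (the alternatives score 8 and 9)."""
    gts = (
        [parse_tree("((A,B),C);")] * 7
        + [parse_tree("((B,C),A);")] * 2
        + [parse_tree("((A,C),B);")] * 1
    )
    res = mdc_species_tree(gts)
    assert res.newick == "((A,B),C);"
    assert res.score == 3
    assert not res.tied
    # brute force over the three rooted topologies
    scores = {
        nwk: sum(count_extra_lineages(parse_tree(nwk), g) for g in gts)
        for nwk in ("((A,B),C);", "((B,C),A);", "((A,C),B);")
    }
    assert scores == {"((A,B),C);": 3, "((B,C),A);": 8, "((A,C),B);": 9}


def test_mdc_concordant_input_scores_zero(rng):
    sp = simulate_species_tree(8, 10.0, rng)
    res = mdc_species_tree([sp, sp, sp])
    assert res.score == 0
    assert topology_key(res.tree) == topology_key(sp)


def test_mdc_matches_full_enumeration_small(rng):
    """The subset DP equals brute-force scoring of every rooted 5-taxon
    topology (score, and the number of optima)."""
    from test_inference_ml import _all_rooted_topologies, _to_newick

    labels = ["A", "B", "C", "D", "E"]
    sp = parse_tree("(((A:1,B:1):1,C:2):1,(D:1.5,E:1.5):1.5);")
    sim = MSCSimulator(sp)
    gts = [sim.simulate(rng) for _ in range(8)]
    res = mdc_species_tree(gts)
    scores = {}
    for t in _all_rooted_topologies(labels):
        nwk = _to_newick(t) + ";"
        scores[nwk] = sum(count_extra_lineages(parse_tree(nwk), g) for g in gts)
    best = min(scores.values())
    assert res.score == best
    # the DP's count of optima matches enumeration over distinct topologies
    optima = {
        topology_key(parse_tree(nwk)) for nwk, sc in scores.items() if sc == best
    }
    assert res.n_optima == len(optima)
    assert topology_key(res.tree) in optima


def test_mdc_truth_not_beaten_on_concordant_input(rng):
    """When every gene tree equals the species topology, no other topology
    scores lower (checked by full enumeration at n = 5)."""
    from test_inference_ml import _all_rooted_topologies, _to_newick

    labels = ["A", "B", "C", "D", "E"]
    truth = parse_tree("(((A,B),C),(D,E));")
    gts = [parse_tree("(((A,B),C),(D,E));")] * 4
    truth_score = sum(count_extra_lineages(truth, g) for g in gts)
    assert truth_score == 0
    for t in _all_rooted_topologies(labels):
        nwk = _to_newick(t) + ";"
        assert sum(count_extra_lineages(parse_tree(nwk), g) for g in gts) >= truth_score


def test_mdc_size_limit():
    labels = [f"t{i}" for i in range(11)]
    nwk = labels[0]  # caterpillar over 11 taxa
    for lab in labels[1:]:
        nwk = f"({nwk},{lab})"
    with pytest.raises(ValueError, match="10"):
        mdc_species_tree([parse_tree(nwk + ";")])
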