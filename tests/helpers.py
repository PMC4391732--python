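"""Shared test utilities: tree parsing, independent oracles, sample builders."""

from collections import Counter

import dendropy
import numpy as np

from coalbench.inference import Draw, TreeSample


def parse_tree(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=newick, schema="newick", rooting="force-rooted")


def shape_key(tree: dendropy.Tree):
    """Canonical label-free shape of a rooted tree (nested sorted tuples)."""

    def rec(node):
        if node.is_leaf():
            return "L"
        return tuple(sorted((rec(c) for c in node.child_nodes()), key=repr))

    return rec(tree.seed_node)


def brute_force_splits(tree: dendropy.Tree) -> set:
    """Independent unrooted-bipartition enumerator (label-frozenset pairs)."""
    labels = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    splits = set()
    leafsets = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            leafsets[node] = frozenset([node.taxon.label])
        else:
            leafsets[node] = frozenset().union(*(leafsets[c] for c in node.child_nodes()))
        side = leafsets[node]
        other = labels - side
        if len(side) >= 2 and len(other) >= 2:
            splits.add(frozenset([side, other]))
    return splits


def random_resolved_tree(labels, rng: np.random.Generator) -> dendropy.Tree:
    """Uniform-ish random rooted binary tree by sequential random joins."""
    nodes = []
    tns = dendropy.TaxonNamespace()
    for lab in labels:
        n = dendropy.Node()
        n.taxon = tns.require_taxon(label=lab)
        n.edge.length = 1.0
        nodes.append(n)
    while len(nodes) > 1:
        i = int(rng.integers(len(nodes)))
        a = nodes.pop(i)
        j = int(rng.integers(len(nodes)))
        b = nodes.pop(j)
        parent = dendropy.Node()
        parent.add_child(a)
        parent.add_child(b)
        parent.edge.length = 1.0
        nodes.append(parent)
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = nodes[0]
    return tree


def masks_from_newick(newick: str, labels):
    """(clusters, splits) bitmask sets over sorted ``labels`` for one tree."""
    tree = parse_tree(newick)
    index = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    full = (1 << n) - 1
    clusters, splits = set(), set()
    masks = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            masks[node] = 1 << index[node.taxon.label]
        else:
            m = 0
            for c in node.child_nodes():
                m |= masks[c]
            masks[node] = m
            if m != full and bin(m).count("1") >= 2:
                clusters.add(m)
                s = (full & ~m) if (m & 1) else m
                if bin(s).count("1") >= 2 and bin(full & ~s).count("1") >= 2:
                    splits.add(s)
    return frozenset(clusters), frozenset(splits)


def make_tree_sample(newicks, labels) -> TreeSample:
    """Build a TreeSample by hand from newick strings (for consensus tests)."""
    draws = []
    for i, nwk in enumerate(newicks):
        clusters, splits = masks_from_newick(nwk, labels)
        draws.append(
            Draw(
                newick=nwk,
                clusters=clusters,
                splits=splits,
                generation=i,
                lnl=0.0,
                kappa=1.0,
                alpha=1.0,
                pi=(0.25, 0.25, 0.25, 0.25),
                height=1.0,
            )
        )
    counts = Counter()
    for d in draws:
        counts.update(d.splits)
    return TreeSample(
        draws=draws,
        split_counts=counts,
        n_runs=2,
        generation_stride=1,
        labels=list(labels),
        converged=True,
        n_generations=len(draws),
        asdsf=0.0,
        run_draws=[draws[: len(draws) // 2], draws[len(draws) // 2 :]],
    )
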