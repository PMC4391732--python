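"""Species-tree and gene-tree simulation.

Species trees are generated under a uniform-speciation (pure-birth/Yule)
model conditioned on the number of extant tips, then rescaled to a target
root-to-tip depth in coalescent units (1 unit = N generations).  Gene trees
are simulated within a species tree under the neutral multispecies
coalescent: constant population size on every branch (including the root
stem), no migration, pairwise coalescence rate ``C(k, 2)`` per unit time.
"""

from __future__ import annotations

import math
from typing import Sequence

import dendropy
import numpy as np

__all__ = [
    "simulate_species_tree",
    "simulate_msc_gene_tree",
    "MSCSimulator",
    "concordance_probability",
    "node_ages",
    "tree_depth",
    "is_ultrametric",
    "topology_key",
    "pairwise_mrca_times",
    "read_trees",
    "write_trees",
]

ULTRAMETRIC_RTOL = 1e-9


# ---------------------------------------------------------------------------
# generic rooted-tree helpers
# ---------------------------------------------------------------------------

def node_ages(tree: dendropy.Tree) -> dict:
    """Map each node to its age (time above the most distant tip).

    Assumes an ultrametric tree; for non-ultrametric trees ages are measured
    from the deepest tip and may be negative for shallower tips.
    """
    dists = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            dists[node] = 0.0
        else:
            dists[node] = dists[node.parent_node] + (node.edge.length or 0.0)
    height = max(dists[leaf] for leaf in tree.leaf_node_iter())
    return {node: height - d for node, d in dists.items()}


def tree_depth(tree: dendropy.Tree) -> float:
    """Root-to-tip height of an (ultrametric) rooted tree."""
    ages = node_ages(tree)
    return ages[tree.seed_node]


def is_ultrametric(tree: dendropy.Tree, rtol: float = ULTRAMETRIC_RTOL) -> bool:
    dists = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            dists[node] = 0.0
        else:
            dists[node] = dists[node.parent_node] + (node.edge.length or 0.0)
    tip_dists = [dists[leaf] for leaf in tree.leaf_node_iter()]
    hi, lo = max(tip_dists), min(tip_dists)
    return hi - lo <= rtol * max(hi, 1e-300)


def is_binary(tree: dendropy.Tree) -> bool:
    return all(
        len(node.child_nodes()) == 2
        for node in tree.preorder_internal_node_iter()
    )


def topology_key(tree: dendropy.Tree) -> frozenset:
    """Canonical rooted-topology key: the set of non-trivial, non-root
    leaf clusters."""
    clusters = []
    leafsets = {}
    n_leaves = sum(1 for _ in tree.leaf_node_iter())
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            leafsets[node] = frozenset([node.taxon.label])
        else:
            s = frozenset().union(*(leafsets[c] for c in node.child_nodes()))
            leafsets[node] = s
            if 1 < len(s) < n_leaves:
                clusters.append(s)
    return frozenset(clusters)


def pairwise_mrca_times(tree: dendropy.Tree):
    """Return (sorted labels, symmetric matrix of MRCA ages) for tree tips."""
    ages = node_ages(tree)
    labels = sorted(leaf.taxon.label for leaf in tree.leaf_node_iter())
    index = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    mat = np.zeros((n, n))
    leafsets = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            leafsets[node] = [index[node.taxon.label]]
        else:
            kids = node.child_nodes()
            sets = [leafsets[c] for c in kids]
            for a in range(len(sets)):
                for b in range(a + 1, len(sets)):
                    for i in sets[a]:
                        for j in sets[b]:
                            mat[i, j] = mat[j, i] = ages[node]
            leafsets[node] = [i for s in sets for i in s]
    return labels, mat


def read_trees(path) -> list:
    """Read newline-separated Newick trees (rooted, with branch lengths)."""
    trees = dendropy.TreeList.get(path=str(path), schema="newick", rooting="force-rooted")
    return list(trees)


def write_trees(trees: Sequence[dendropy.Tree], path) -> None:
    with open(path, "w") as fh:
        for t in trees:
            fh.write(t.as_string(schema="newick", suppress_rooting=True).strip() + "\n")


# ---------------------------------------------------------------------------
# uniform-speciation species trees
# ---------------------------------------------------------------------------

class _SimNode:
    __slots__ = ("t", "left", "right", "label")

    def __init__(self, t=None):
        self.t = t          # forward time of the split at this node (None = tip)
        self.left = None
        self.right = None
        self.label = None


def _to_dendropy(root: _SimNode, present: float, scale: float,
                 taxon_namespace: dendropy.TaxonNamespace) -> dendropy.Tree:
    """Convert a forward-time simulation node structure to a dendropy tree.

    Node ages are ``(present - t) * scale``; tips sit at age 0.
    """
    tree = dendropy.Tree(taxon_namespace=taxon_namespace)

    def build(sim: _SimNode, parent_age: float, dnode: dendropy.Node):
        if sim.left is None:  # tip
            age = 0.0
            dnode.taxon = taxon_namespace.require_taxon(label=sim.label)
        else:
            age = (present - sim.t) * scale
            for child in (sim.left, sim.right):
                cnode = dendropy.Node()
                dnode.add_child(cnode)
                build(child, age, cnode)
        dnode.edge.length = parent_age - age if parent_age is not None else None
        return dnode

    build(root, None, tree.seed_node)
    return tree


def simulate_species_tree(
    n_taxa: int,
    depth: float,
    rng: np.random.Generator,
    labels: Sequence[str] | None = None,
) -> dendropy.Tree:
    """Simulate a rooted ultrametric species tree under uniform speciation.

    A pure-birth (Yule) process is run forward in time -- every extant
    lineage splits at rate 1, the splitting lineage chosen uniformly --
    until ``n_taxa`` tips exist; the simulation then runs one further
    exponential waiting time to place the present.  Node times are linearly
    rescaled so the root-to-tip height equals ``depth`` exactly.

    Parameters
    ----------
    n_taxa : number of extant species (>= 2).
    depth : root-to-tip height in coalescent units (> 0).
    rng : numpy random generator.
    labels : optional tip labels; defaults to ``s1..s<n>``.
    """
    if n_taxa < 2:
        raise ValueError(f"n_taxa must be >= 2, got {n_taxa}")
    if not (depth > 0) or not math.isfinite(depth):
        raise ValueError(f"depth must be positive and finite, got {depth}")
    if labels is None:
        labels = [f"s{i + 1}" for i in range(n_taxa)]
    elif len(set(labels)) != n_taxa:
        raise ValueError("labels must be unique and match n_taxa")

    root = _SimNode(t=0.0)
    root.left, root.right = _SimNode(), _SimNode()
    active = [root.left, root.right]
    t = 0.0
    while len(active) < n_taxa:
        k = len(active)
        t += rng.exponential(1.0 / k)
        i = int(rng.integers(k))
        node = active[i]
        node.t = t
        node.left, node.right = _SimNode(), _SimNode()
        active[i] = node.left
        active.append(node.right)
    present = t + rng.exponential(1.0 / n_taxa)

    for lab, node in zip(labels, active):
        node.label = lab

    tns = dendropy.TaxonNamespace()
    return _to_dendropy(root, present, depth / present, tns)


# ---------------------------------------------------------------------------
# multispecies coalescent
# ---------------------------------------------------------------------------

class _GNode:
    __slots__ = ("age", "left", "right", "label")

    def __init__(self, age=0.0, left=None, right=None, label=None):
        self.age = age
        self.left = left
        self.right = right
        self.label = label


class MSCSimulator:
    """Coalescent gene-tree simulator bound to one species tree.

    Precomputes the species-tree branch structure once so that repeated
    draws (e.g. the 540 loci of one replicate) are cheap.
    """

    def __init__(self, species_tree: dendropy.Tree, alleles_per_species: int = 1):
        if alleles_per_species < 1:
            raise ValueError("alleles_per_species must be >= 1")
        if not is_binary(species_tree):
            raise ValueError("species tree must be strictly binary")
        if not is_ultrametric(species_tree):
            raise ValueError("species tree must be ultrametric")
        self.alleles_per_species = alleles_per_species
        ages = node_ages(species_tree)
        # postorder encoding: children before parents
        self._nodes = []  # (age, child indices or None, leaf label or None, parent idx)
        index = {}
        for node in species_tree.postorder_node_iter():
            idx = len(self._nodes)
            index[node] = idx
            kids = node.child_nodes()
            self._nodes.append(
                [
                    ages[node],
                    [index[c] for c in kids] if kids else None,
                    node.taxon.label if node.is_leaf() else None,
                    -1,
                ]
            )
        for node in species_tree.postorder_node_iter():
            for c in node.child_nodes():
                self._nodes[index[c]][3] = index[node]
        self.depth = self._nodes[-1][0]
        self.taxon_namespace = dendropy.TaxonNamespace()
        for age, kids, label, _ in self._nodes:
            if label is not None:
                for a in range(alleles_per_species):
                    self.taxon_namespace.require_taxon(label=self._allele_label(label, a))

    def _allele_label(self, species: str, allele: int) -> str:
        return species if self.alleles_per_species == 1 else f"{species}_{allele + 1}"

    def _simulate_root(self, rng: np.random.Generator) -> _GNode:
        lineages_top: list[list[_GNode]] = [None] * len(self._nodes)
        for idx, (age, kids, label, parent) in enumerate(self._nodes):
            if kids is None:
                lin = [
                    _GNode(age=0.0, label=self._allele_label(label, a))
                    for a in range(self.alleles_per_species)
                ]
                t = age
            else:
                lin = lineages_top[kids[0]] + lineages_top[kids[1]]
                for k in kids:
                    lineages_top[k] = None
                t = age
            t1 = self._nodes[parent][0] if parent >= 0 else math.inf
            while len(lin) > 1:
                k = len(lin)
                t += rng.exponential(2.0 / (k * (k - 1)))
                if t >= t1:
                    break
                i = int(rng.integers(k))
                j = int(rng.integers(k - 1))
                if j >= i:
                    j += 1
                merged = _GNode(age=t, left=lin[i], right=lin[j])
                lin = [x for m, x in enumerate(lin) if m not in (i, j)]
                lin.append(merged)
            lineages_top[idx] = lin
        return lineages_top[-1][0]

    def simulate(self, rng: np.random.Generator) -> dendropy.Tree:
        """Draw one gene tree; returns a rooted ultrametric dendropy tree."""
        root = self._simulate_root(rng)
        tree = dendropy.Tree(taxon_namespace=self.taxon_namespace)

        def build(g: _GNode, parent_age, dnode):
            if g.left is None:
                dnode.taxon = self.taxon_namespace.require_taxon(label=g.label)
            else:
                for child in (g.left, g.right):
                    cnode = dendropy.Node()
                    dnode.add_child(cnode)
                    build(child, g.age, cnode)
            dnode.edge.length = (parent_age - g.age) if parent_age is not None else None

        build(root, None, tree.seed_node)
        tree.tmrca = root.age
        return tree

    def simulate_topology(self, rng: np.random.Generator):
        """Fast path: draw one gene tree and return only ``(topology_key, tmrca)``."""
        root = self._simulate_root(rng)
        clusters = []
        n_leaves = len(self.taxon_namespace)

        def leafset(g: _GNode) -> frozenset:
            if g.left is None:
                return frozenset([g.label])
            s = leafset(g.left) | leafset(g.right)
            if 1 < len(s) < n_leaves:
                clusters.append(s)
            return s

        leafset(root)
        return frozenset(clusters), root.age


def simulate_msc_gene_tree(
    species_tree: dendropy.Tree,
    rng: np.random.Generator,
    alleles_per_species: int = 1,
) -> dendropy.Tree:
    """Simulate one coalescent gene tree within ``species_tree``.

    Convenience wrapper around :class:`MSCSimulator` for single draws; the
    returned tree carries its root age as the attribute ``tmrca``.
    """
    return MSCSimulator(species_tree, alleles_per_species).simulate(rng)


def concordance_probability(internal_branch: float) -> float:
    """Probability that a 3-taxon gene tree matches its species tree.

    For a rooted species triplet with internal branch ``t`` (coalescent
    units), the matching-topology probability is ``1 - (2/3) exp(-t)``:
    with probability ``1 - exp(-t)`` the two closest species coalesce within
    the internal branch (always concordant), otherwise all three topologies
    are equiprobable.
    """
    if internal_branch < 0:
        raise ValueError(f"internal branch must be >= 0, got {internal_branch}")
    return 1.0 - (2.0 / 3.0) * math.exp(-internal_branch)
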