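"""Coalescent-aware species-tree estimators: GLASS/STEM-style clustering
and exact minimize-deep-coalescences (MDC).

GLASS estimates the species tree by single-linkage clustering on the
matrix of minimum (over loci) interspecific coalescence times; for a single
allele per species and equal population sizes this clustering topology
coincides with the STEM maximum-likelihood species tree, so it stands in
for both methods here.

MDC scores a candidate species topology by the total number of "extra
lineages" the gene trees imply and returns the topology minimizing that
total.  Instead of a heuristic search, the minimization is exact: a
dynamic program over taxon subsets visits every rooted binary topology
implicitly (the per-branch cost depends only on the branch's leaf cluster),
which is feasible for the <= 10-species regime this benchmark targets.
"""

from __future__ import annotations

from dataclasses import dataclass
import dendropy
import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from coalbench import _clocktree
from coalbench.treesim import is_ultrametric, pairwise_mrca_times

__all__ = [
    "min_coalescence_matrix",
    "glass_species_tree",
    "count_extra_lineages",
    "mdc_species_tree",
    "MdcResult",
]

MDC_MAX_SPECIES = 10


def _check_common_taxa(trees) -> list:
    taxa = None
    for t in trees:
        labels = sorted(leaf.taxon.label for leaf in t.leaf_node_iter())
        if taxa is None:
            taxa = labels
        elif labels != taxa:
            raise ValueError("gene trees must share one species set")
    if taxa is None:
        raise ValueError("need at least one gene tree")
    return taxa


def min_coalescence_matrix(gene_trees):
    """(labels, matrix) of the minimum over loci of pairwise MRCA times."""
    labels = _check_common_taxa(gene_trees)
    n = len(labels)
    best = np.full((n, n), np.inf)
    for gt in gene_trees:
        if not is_ultrametric(gt, rtol=1e-6):
            raise ValueError("GLASS requires ultrametric gene trees")
        gl, gm = pairwise_mrca_times(gt)
        assert gl == labels
        best = np.minimum(best, gm)
    np.fill_diagonal(best, 0.0)
    return labels, best


def glass_species_tree(gene_trees) -> dendropy.Tree:
    """GLASS estimate: single-linkage clustering on minimum coalescence times.

    The output is a rooted ultrametric species tree whose node heights are
    the single-linkage merge heights (coalescent units).  Taxa are sorted
    lexicographically before clustering, which makes equal-distance
    tie-breaking deterministic.
    """
    labels, dmat = min_coalescence_matrix(gene_trees)
    n = len(labels)
    if n < 2:
        raise ValueError("need at least 2 species")
    z = linkage(squareform(dmat, checks=False), method="single")
    children = np.full((2 * n - 1, 2), -1, dtype=int)
    heights = np.zeros(2 * n - 1)
    for i in range(n - 1):
        a, b, dist, _ = z[i]
        children[n + i] = (int(a), int(b))
        heights[n + i] = dist  # join height = minimum coalescence time
    return _clocktree.to_dendropy(children, 2 * n - 2, labels, heights=heights)


# ---------------------------------------------------------------------------
# minimize deep coalescences
# ---------------------------------------------------------------------------

def _clade_masks(tree: dendropy.Tree, index: dict):
    """Bitmask leaf sets of every node of ``tree`` (children before parents)."""
    masks, order = {}, []
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            masks[node] = 1 << index[node.taxon.label]
        else:
            masks[node] = 0
            for c in node.child_nodes():
                masks[node] |= masks[c]
        order.append(node)
    return masks, order


def _lineage_counts_all_subsets(tree: dendropy.Tree, index: dict) -> np.ndarray:
    """For every taxon subset A (bitmask), the number of lineages the gene
    tree leaves in a species-tree branch with cluster A: the count of
    maximal gene-tree clades whose leaf set is contained in A."""
    n = len(index)
    masks, order = _clade_masks(tree, index)
    lin = np.zeros(1 << n, dtype=np.int64)
    for a_mask in range(1, 1 << n):
        count = 0
        stack = [tree.seed_node]
        while stack:
            node = stack.pop()
            m = masks[node]
            if m & a_mask == m:
                count += 1
            elif m & a_mask:
                stack.extend(node.child_nodes())
        lin[a_mask] = count
    return lin


def count_extra_lineages(species_topology: dendropy.Tree, gene_tree: dendropy.Tree) -> int:
    """Extra lineages implied by one gene tree on one species topology.

    Each gene-tree node is assigned to the most recent species-tree branch
    containing its full descendant species set (the branch-length-free MDC
    convention); the score sums, over species-tree branches, the number of
    lineages exiting the branch minus one.  Equivalently, the lineages
    exiting the branch above cluster A are the maximal gene-tree clades
    contained in A.
    """
    sp_labels = sorted(leaf.taxon.label for leaf in species_topology.leaf_node_iter())
    gt_labels = sorted(leaf.taxon.label for leaf in gene_tree.leaf_node_iter())
    if sp_labels != gt_labels:
        raise ValueError("species tree and gene tree must share one taxon set")
    index = {lab: i for i, lab in enumerate(sp_labels)}
    gmasks, _ = _clade_masks(gene_tree, index)

    def lineages_in(a_mask: int) -> int:
        count = 0
        stack = [gene_tree.seed_node]
        while stack:
            node = stack.pop()
            m = gmasks[node]
            if m & a_mask == m:
                count += 1
            elif m & a_mask:
                stack.extend(node.child_nodes())
        return count

    smasks, _ = _clade_masks(species_topology, index)
    root_mask = smasks[species_topology.seed_node]
    total = 0
    for node, mask in smasks.items():
        if node.is_leaf() or mask == root_mask:
            continue
        total += lineages_in(mask) - 1
    return total


@dataclass(frozen=True)
class MdcResult:
    """Exact MDC solution: optimal topology, its score, and tie information."""

    tree: dendropy.Tree
    score: int
    newick: str
    n_optima: int

    @property
    def tied(self) -> bool:
        return self.n_optima > 1


def mdc_species_tree(gene_trees) -> MdcResult:
    """Exact MDC species-tree estimate over all rooted binary topologies.

    Minimizes the total extra-lineage count summed over gene trees.  The
    per-branch cost depends only on the branch's species cluster, so the
    optimum over all rooted binary topologies (135,135 at 8 taxa) is found
    exactly by dynamic programming over taxon subsets.  Ties are broken by
    lexicographic Newick order and flagged via ``n_optima``.
    """
    gene_trees = list(gene_trees)
    labels = _check_common_taxa(gene_trees)
    n = len(labels)
    if n > MDC_MAX_SPECIES:
        raise ValueError(
            f"exhaustive MDC supports at most {MDC_MAX_SPECIES} species, got {n}"
        )
    if n < 2:
        raise ValueError("need at least 2 species")
    index = {lab: i for i, lab in enumerate(labels)}
    full = (1 << n) - 1

    cost = np.zeros(1 << n, dtype=np.int64)  # f(A) = sum_g (lineages_g(A) - 1)
    for gt in gene_trees:
        cost += _lineage_counts_all_subsets(gt, index)
    cost -= len(gene_trees)

    # DP over subsets: best[S] = min over bipartitions {S1, S2} of S of
    # best'(S1) + best'(S2), where best'(X) adds cost[X] for internal
    # (non-root) clusters; singletons and the root cluster cost nothing.
    best = np.zeros(1 << n, dtype=np.int64)
    best_nwk = [""] * (1 << n)
    n_opt = np.zeros(1 << n, dtype=np.int64)
    for i, lab in enumerate(labels):
        best_nwk[1 << i] = lab
        n_opt[1 << i] = 1

    subsets_by_size = sorted(range(1, full + 1), key=lambda m: bin(m).count("1"))

    def sub_cost(x: int) -> int:
        return 0 if x & (x - 1) == 0 else best[x] + cost[x]

    for s in subsets_by_size:
        if s & (s - 1) == 0:
            continue
        lowest = s & -s  # fix the lowest bit in S1 to visit each split once
        rest = s & ~lowest
        best_score, best_string, count = None, None, 0
        s1 = 0
        # iterate over all subsets of `rest`, adding `lowest` to each
        sub = rest
        while True:
            s1 = sub | lowest
            s2 = s & ~s1
            if s2:
                sc = sub_cost(s1) + sub_cost(s2)
                if best_score is None or sc < best_score:
                    best_score = sc
                    a, b = sorted((best_nwk[s1], best_nwk[s2]))
                    best_string = f"({a},{b})"
                    count = n_opt[s1] * n_opt[s2]
                elif sc == best_score:
                    count += n_opt[s1] * n_opt[s2]
                    a, b = sorted((best_nwk[s1], best_nwk[s2]))
                    best_string = min(best_string, f"({a},{b})")
            if sub == 0:
                break
            sub = (sub - 1) & rest
        best[s] = best_score
        best_nwk[s] = best_string
        n_opt[s] = count

    newick = best_nwk[full] + ";"
    tree = dendropy.Tree.get(data=newick, schema="newick", rooting="force-rooted")
    return MdcResult(tree=tree, score=int(best[full]), newick=newick, n_optima=int(n_opt[full]))
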