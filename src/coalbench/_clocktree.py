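"""Array representation of rooted binary trees used by the tree searchers.

Nodes are integers: tips ``0..n-1`` (mapping to a fixed sorted label list),
internal nodes ``n..2n-2``.  ``children`` is a ``(2n-1, 2)`` int array with
``-1`` for tips.  Clock trees additionally carry a ``heights`` vector
(tips at height 0); generic trees carry per-node edge lengths instead.
"""

from __future__ import annotations

import numpy as np
import dendropy

__all__ = [
    "bottom_up_order",
    "parent_array",
    "edge_lengths_from_heights",
    "from_dendropy",
    "to_dendropy",
    "newick",
    "clusters_bitmasks",
    "splits_bitmasks",
    "from_linkage",
]


def bottom_up_order(children: np.ndarray, root: int) -> list:
    """Node order with every child before its parent (reversed preorder)."""
    order, stack = [], [root]
    while stack:
        node = stack.pop()
        order.append(node)
        if children[node, 0] >= 0:
            stack.append(int(children[node, 0]))
            stack.append(int(children[node, 1]))
    order.reverse()
    return order


def parent_array(children: np.ndarray) -> np.ndarray:
    parent = np.full(children.shape[0], -1, dtype=int)
    for node in range(children.shape[0]):
        for c in children[node]:
            if c >= 0:
                parent[c] = node
    return parent


def edge_lengths_from_heights(children: np.ndarray, heights: np.ndarray, root: int) -> np.ndarray:
    parent = parent_array(children)
    el = np.zeros(children.shape[0])
    mask = parent >= 0
    el[mask] = heights[parent[mask]] - heights[np.nonzero(mask)[0]]
    return el


def from_linkage(linkage_matrix: np.ndarray, n: int):
    """Convert a scipy hierarchical-clustering linkage to (children, heights).

    Merge heights are cophenetic distances; node height = distance / 2
    (tips at 0).  Heights are nudged to be strictly increasing along every
    path so the result is a valid clock tree even for tied/zero merges.
    """
    total = 2 * n - 1
    children = np.full((total, 2), -1, dtype=int)
    heights = np.zeros(total)
    for i in range(n - 1):
        a, b, dist, _ = linkage_matrix[i]
        node = n + i
        children[node] = (int(a), int(b))
        floor = max(heights[int(a)], heights[int(b)])
        heights[node] = max(dist / 2.0, floor * (1 + 1e-9) + 1e-12)
    return children, heights


def from_dendropy(tree: dendropy.Tree, labels: list):
    """Encode a rooted binary dendropy tree as (children, edge_lengths, root)."""
    index = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    children = np.full((2 * n - 1, 2), -1, dtype=int)
    edgelen = np.zeros(2 * n - 1)
    next_internal = [n]

    def encode(node) -> int:
        if node.is_leaf():
            idx = index[node.taxon.label]
        else:
            kids = node.child_nodes()
            if len(kids) != 2:
                raise ValueError("tree must be strictly binary")
            a, b = (encode(k) for k in kids)
            idx = next_internal[0]
            next_internal[0] += 1
            children[idx] = (a, b)
        edgelen[idx] = node.edge.length or 0.0
        return idx

    root = encode(tree.seed_node)
    return children, edgelen, root


def to_dendropy(
    children: np.ndarray,
    root: int,
    labels: list,
    heights: np.ndarray | None = None,
    edge_lengths: np.ndarray | None = None,
    taxon_namespace: dendropy.TaxonNamespace | None = None,
) -> dendropy.Tree:
    if (heights is None) == (edge_lengths is None):
        raise ValueError("provide exactly one of heights / edge_lengths")
    if edge_lengths is None:
        edge_lengths = edge_lengths_from_heights(children, heights, root)
    tns = taxon_namespace or dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns)

    def build(idx: int, dnode: dendropy.Node):
        if children[idx, 0] < 0:
            dnode.taxon = tns.require_taxon(label=labels[idx])
        else:
            for c in children[idx]:
                cnode = dendropy.Node()
                dnode.add_child(cnode)
                build(int(c), cnode)
        dnode.edge.length = float(edge_lengths[idx]) if idx != root else None

    build(root, tree.seed_node)
    return tree


def newick(
    children: np.ndarray,
    root: int,
    labels: list,
    heights: np.ndarray | None = None,
    canonical: bool = False,
) -> str:
    """Newick string; ``canonical=True`` sorts children lexicographically."""
    el = None if heights is None else edge_lengths_from_heights(children, heights, root)

    def render(idx: int) -> str:
        if children[idx, 0] < 0:
            s = labels[idx]
        else:
            parts = [render(int(c)) for c in children[idx]]
            if canonical:
                parts.sort()
            s = "(" + ",".join(parts) + ")"
        if el is not None and idx != root:
            s += f":{el[idx]:.10g}"
        return s

    return render(root) + ";"


def _leafset_masks(children: np.ndarray, root: int) -> np.ndarray:
    masks = np.zeros(children.shape[0], dtype=np.int64)
    for node in bottom_up_order(children, root):
        if children[node, 0] < 0:
            masks[node] = 1 << node
        else:
            masks[node] = masks[children[node, 0]] | masks[children[node, 1]]
    return masks


def clusters_bitmasks(children: np.ndarray, root: int) -> frozenset:
    """Non-trivial rooted clusters (internal, non-root leaf-set bitmasks)."""
    masks = _leafset_masks(children, root)
    return frozenset(
        int(masks[node])
        for node in range(children.shape[0])
        if children[node, 0] >= 0 and node != root
    )


def splits_bitmasks(children: np.ndarray, root: int, n: int) -> frozenset:
    """Non-trivial unrooted splits, canonicalized to the side without tip 0."""
    full = (1 << n) - 1
    masks = _leafset_masks(children, root)
    out = set()
    for node in range(children.shape[0]):
        if children[node, 0] < 0 or node == root:
            continue
        m = int(masks[node])
        if m & 1:
            m = full & ~m
        if bin(m).count("1") >= 2:
            out.add(m)
    return frozenset(out)
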