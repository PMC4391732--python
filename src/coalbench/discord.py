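"""Topological discord scoring and the ANOVA comparisons.

Robinson-Foulds distances are computed on unrooted trees (estimated trees
are unrooted before scoring, so consensus root placement is irrelevant);
the raw, unnormalized count is used.  Mean discord is a two-stage average:
RF is first averaged within each true species tree, then across species
trees, which treats the species tree as the experimental unit.  Method
comparisons use fixed-effects one-way ANOVA on those per-species-tree
means, with significance at alpha = 0.05 and no multiple-testing
correction (an optional Bonferroni flag is provided for users who want
one).
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "unrooted_splits",
    "robinson_foulds",
    "mean_discord",
    "one_way_anova",
    "AnovaResult",
    "anova_table",
]

ALPHA = 0.05


def unrooted_splits(tree: dendropy.Tree) -> set:
    """Non-trivial unrooted bipartitions as frozensets of taxon labels.

    Each split is represented by the side not containing the
    lexicographically smallest taxon; polytomies simply yield fewer splits.
    """
    labels = sorted(leaf.taxon.label for leaf in tree.leaf_node_iter())
    all_taxa = frozenset(labels)
    ref = labels[0]
    splits = set()
    leafsets = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            leafsets[node] = frozenset([node.taxon.label])
        else:
            s = frozenset().union(*(leafsets[c] for c in node.child_nodes()))
            leafsets[node] = s
            side = all_taxa - s if ref in s else s
            if 2 <= len(side) <= len(labels) - 2:
                splits.add(side)
    return splits


def robinson_foulds(t1: dendropy.Tree, t2: dendropy.Tree) -> int:
    """Robinson-Foulds distance between two trees over the same taxa.

    The symmetric difference of the non-trivial unrooted bipartition sets:
    splits unique to the first tree plus splits unique to the second.
    For binary trees on n taxa the maximum is ``2 (n - 3)``.
    """
    l1 = sorted(leaf.taxon.label for leaf in t1.leaf_node_iter())
    l2 = sorted(leaf.taxon.label for leaf in t2.leaf_node_iter())
    if l1 != l2:
        raise ValueError("trees must share one taxon set")
    if len(l1) < 4:
        raise ValueError("Robinson-Foulds needs at least 4 taxa")
    s1, s2 = unrooted_splits(t1), unrooted_splits(t2)
    return len(s1 ^ s2)


REQUIRED_COLUMNS = ["species_tree_id", "depth", "n_loci", "method", "matrix_index", "rf"]


def mean_discord(records: pd.DataFrame) -> pd.DataFrame:
    """Two-stage mean RF per (depth, n_loci, method) cell.

    Within each cell, RF values are first averaged per species tree, then
    those per-tree means are averaged; the dispersion column is the
    standard deviation across species-tree means.  Cells with no records
    for some species tree present in other cells are flagged
    (``complete = False``) rather than silently zero-filled.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"records missing columns: {missing}")
    if records.empty:
        raise ValueError("empty discord table")
    all_ids = set(records["species_tree_id"].unique())
    per_tree = (
        records.groupby(["depth", "n_loci", "method", "species_tree_id"], sort=True)["rf"]
        .agg(["mean", "count"])
        .reset_index()
    )
    rows = []
    for (depth, n_loci, method), grp in per_tree.groupby(["depth", "n_loci", "method"], sort=True):
        rows.append(
            {
                "depth": depth,
                "n_loci": n_loci,
                "method": method,
                "mean_rf": grp["mean"].mean(),
                "sd_rf": grp["mean"].std(ddof=1) if len(grp) > 1 else 0.0,
                "n_species_trees": len(grp),
                "n_analyses": int(grp["count"].sum()),
                "complete": set(grp["species_tree_id"]) == all_ids,
            }
        )
    return pd.DataFrame(rows)


def per_tree_means(records: pd.DataFrame, depth, n_loci, method) -> np.ndarray:
    """Per-species-tree mean RF values for one design cell (ANOVA unit)."""
    sel = records[
        (records["depth"] == depth)
        & (records["n_loci"] == n_loci)
        & (records["method"] == method)
    ]
    if sel.empty:
        raise ValueError(f"no records for cell ({depth}, {n_loci}, {method})")
    return sel.groupby("species_tree_id")["rf"].mean().sort_index().to_numpy()


@dataclass(frozen=True)
class AnovaResult:
    f_statistic: float
    p_value: float
    df_between: int
    df_within: int
    groups: tuple
    degenerate: bool = False

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA


def one_way_anova(groups, labels=None) -> AnovaResult:
    """Fixed-effects one-way ANOVA: F = MS_between / MS_within.

    ``groups`` is a list of >= 2 arrays with >= 2 values each.  With zero
    within-group variance and unequal means, F is infinite; p is reported
    as 0 with the ``degenerate`` flag set instead of failing.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 values each")
    labels = tuple(labels) if labels is not None else tuple(range(len(groups)))
    k = len(groups)
    n = sum(len(g) for g in groups)
    df_between, df_within = k - 1, n - k
    grand = np.concatenate(groups).mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    if ssw == 0.0:
        if ssb == 0.0:
            return AnovaResult(0.0, 1.0, df_between, df_within, labels, degenerate=True)
        return AnovaResult(np.inf, 0.0, df_between, df_within, labels, degenerate=True)
    f = (ssb / df_between) / (ssw / df_within)
    p = float(stats.f.sf(f, df_between, df_within))
    return AnovaResult(float(f), p, df_between, df_within, labels)


def anova_table(
    records: pd.DataFrame,
    methods=("concatenation", "stem", "mdc"),
    bonferroni: bool = False,
) -> pd.DataFrame:
    """Method and locus-number comparisons per depth, one row per test.

    Mirrors the benchmark's summary layout: at each depth, an across-method
    ANOVA for every locus count, and an across-locus-count ANOVA for every
    method.  Observations are per-species-tree mean RF values.
    """
    rows = []
    depths = sorted(records["depth"].unique())
    loci_counts = sorted(records["n_loci"].unique())
    n_tests = len(depths) * (len(loci_counts) + len(methods))
    for depth in depths:
        for n_loci in loci_counts if len(methods) >= 2 else []:
            groups = [per_tree_means(records, depth, n_loci, m) for m in methods]
            res = one_way_anova(groups, labels=methods)
            rows.append(
                {
                    "depth": depth,
                    "comparison": f"{n_loci} loci (across methods)",
                    "f": res.f_statistic,
                    "p": res.p_value,
                    "significant": res.significant,
                }
            )
        for method in methods if len(loci_counts) >= 2 else []:
            groups = [per_tree_means(records, depth, nl, method) for nl in loci_counts]
            res = one_way_anova(groups, labels=loci_counts)
            rows.append(
                {
                    "depth": depth,
                    "comparison": f"{method} (across loci counts)",
                    "f": res.f_statistic,
                    "p": res.p_value,
                    "significant": res.significant,
                }
            )
    table = pd.DataFrame(rows)
    if bonferroni:
        table["p_bonferroni"] = np.minimum(table["p"] * n_tests, 1.0)
        table["significant"] = table["p_bonferroni"] < ALPHA
    return table
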