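"""Distance-based ortholog nomenclature and clustering.

Family members are named after their closest reference-species ortholog in a
pairwise p-distance matrix; members sharing a reference receive ``.1``,
``.2``, ... suffixes in ascending distance order (ties broken
lexicographically by query id and flagged).  A neighbor-joining tree built
on the same matrix provides the cluster memberships.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import DistanceMatrix
from skbio.tree import TreeNode, nj

__all__ = [
    "p_distance",
    "assign_names",
    "NamingMap",
    "nj_tree",
    "tree_clusters",
]


def p_distance(aligned: dict[str, str]) -> DistanceMatrix:
    """Pairwise p-distance over aligned sequences, gap columns excluded.

    d(i,j) = mismatches / compared columns, where columns holding a gap
    ('-' or '.') in either row are excluded from the comparison.
    """
    ids = list(aligned)
    lengths = {len(s) for s in aligned.values()}
    if len(lengths) != 1:
        raise ValueError(f"aligned rows must share one length, got {sorted(lengths)}")
    arr = np.array([list(aligned[i].upper()) for i in ids])
    gap = (arr == "-") | (arr == ".")
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~(gap[i] | gap[j])
            m = int(ok.sum())
            if m == 0:
                raise ValueError(
                    f"no comparable columns between {ids[i]} and {ids[j]}")
            d[i, j] = d[j, i] = np.count_nonzero(arr[i][ok] != arr[j][ok]) / m
    return DistanceMatrix(d, ids)


@dataclass
class NamingMap:
    table: pd.DataFrame  # query_id, assigned_name, reference_id, distance, tie_flag

    def as_dict(self) -> dict[str, str]:
        return dict(zip(self.table.query_id, self.table.assigned_name))


def assign_names(
    d: DistanceMatrix,
    reference_ids: list[str],
    query_ids: list[str],
    stems: dict[str, str] | None = None,
) -> NamingMap:
    """Name each query after its argmin-distance reference.

    Queries sharing a reference get suffixes ``.1``, ``.2``, ... in ascending
    distance order.  A query equidistant to two or more references is
    assigned to the lexicographically first and flagged.  ``stems`` maps a
    reference id to a naming stem (defaults to the reference id itself).
    """
    if set(reference_ids) & set(query_ids):
        raise ValueError("reference and query ids must be disjoint")
    stems = stems or {}
    rows = []
    for q in query_ids:
        dists = {r: d[q, r] for r in reference_ids}
        best = min(dists.values())
        winners = sorted(r for r, v in dists.items() if v == best)
        rows.append({
            "query_id": q,
            "reference_id": winners[0],
            "distance": best,
            "tie_flag": len(winners) > 1,
        })
    tab = pd.DataFrame(rows)
    names = {}
    for ref, grp in tab.groupby("reference_id"):
        ordered = grp.sort_values(["distance", "query_id"])
        stem = stems.get(ref, ref)
        for rank, q in enumerate(ordered.query_id, start=1):
            names[q] = f"{stem}.{rank}"
    tab["assigned_name"] = tab.query_id.map(names)
    tab = tab[["query_id", "assigned_name", "reference_id", "distance", "tie_flag"]]
    return NamingMap(tab)


def nj_tree(d: DistanceMatrix) -> TreeNode:
    """Neighbor-joining tree with negative branch lengths clamped to zero.

    Taxon input order does not affect the topology: ids are sorted before
    agglomeration.
    """
    if d.shape[0] < 3:
        raise ValueError("neighbor joining needs >= 3 taxa")
    ordered = d.filter(sorted(d.ids))
    tree = nj(ordered)
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    return tree


def tree_clusters(tree: TreeNode, n_clusters: int = 2) -> dict[str, int]:
    """Cluster labels from cutting the deepest splits of the rooted tree.

    The unrooted NJ tree is midpoint-rooted, then the longest internal
    branches are cut until ``n_clusters`` connected groups of tips remain.
    """
    rooted = tree.root_at_midpoint()
    clusters: list[set[str]] = [set(t.name for t in rooted.tips())]
    internal = sorted(
        (n for n in rooted.non_tips() if n.length is not None),
        key=lambda n: -n.length,
    )
    for node in internal:
        if len(clusters) >= n_clusters:
            break
        tips = set(t.name for t in node.tips())
        for grp in clusters:
            if tips < grp:
                clusters.remove(grp)
                clusters.extend([tips, grp - tips])
                break
    labels = {}
    for k, grp in enumerate(sorted(clusters, key=lambda g: sorted(g)[0]), start=1):
        for t in grp:
            labels[t] = k
    return labels
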