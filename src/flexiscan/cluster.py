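"""Co-enrichment clustering of RBP binding profiles.

Each row RBP (those bound to >= 30 FLEXIs, with an optional core-spliceosome
exclusion list) defines the subset of introns carrying its site.  For every
column RBP, a two-sided Fisher test with BH adjustment and a >= 2% abundance
gate compares the column RBP's binding-site frequency in the subset against
the background, and the outcome is key-coded over / under / ns.  Gower's
distance on the all-categorical key codes (the fraction of mismatching
columns) feeds complete-linkage hierarchical clustering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from flexiscan.rbp import BindingProfile
from flexiscan.stats import binding_abundance_table, fisher_bh

KEY_CODES = ("over", "under", "ns")


@dataclass
class ClusterAssignment:
    labels: list          # row names
    linkage: np.ndarray   # scipy linkage matrix
    clusters: Optional[dict] = None  # label -> cluster id for the last cut


def build_keycode_matrix(
    profiles: dict[str, BindingProfile],
    row_rbps: Sequence[str],
    all_rbps: Optional[Sequence[str]] = None,
    alpha: float = 0.05,
    min_pct: float = 2.0,
    background: str = "complement",
) -> pd.DataFrame:
    """Ternary over/under/ns matrix: rows = subset-defining RBPs, columns =
    all RBPs with >= 1 bound intron.

    For row RBP r, the subset is the introns bound by r; the comparison group
    is the complement (default) or all profiled introns
    (``background='all'``).  Cells inherit the collapsed-presence counting of
    the profiles.  Rows whose subset has < 2 introns are dropped with a
    warning.
    """
    if all_rbps is None:
        all_rbps = sorted({r for p in profiles.values() for r in p.rbps})
    rows = {}
    for r in row_rbps:
        subset = {iid: p for iid, p in profiles.items() if r in p.rbps}
        if len(subset) < 2:
            warnings.warn(f"row RBP {r} has a subset of {len(subset)} introns; dropped")
            continue
        if background == "complement":
            other = {iid: p for iid, p in profiles.items() if r not in p.rbps}
        elif background == "all":
            other = profiles
        else:
            raise ValueError(f"unknown background {background!r}")
        if not other:
            warnings.warn(f"row RBP {r} has an empty comparison group; dropped")
            continue
        table = binding_abundance_table(subset, other)
        res = fisher_bh(table, alpha=alpha, min_pct=min_pct)
        keyed = dict(zip(res["rbp"], res["key"]))
        rows[r] = [keyed.get(j, "ns") for j in all_rbps]
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(all_rbps))


def gower_distance(matrix: pd.DataFrame) -> np.ndarray:
    """Gower distance on all-categorical codes: pairwise fraction of
    mismatching columns.  Symmetric, zero diagonal, values in [0, 1]."""
    if matrix.shape[0] < 2:
        raise ValueError("need >= 2 rows")
    codes = matrix.to_numpy()
    n = codes.shape[0]
    dist = np.zeros((n, n))
    for i in range(n):
        neq = (codes[i] != codes[i + 1 :]).mean(axis=1)
        dist[i, i + 1 :] = neq
        dist[i + 1 :, i] = neq
    return dist


def complete_linkage(dist: np.ndarray, labels: Sequence[str]) -> ClusterAssignment:
    """Complete-linkage agglomeration of a symmetric distance matrix."""
    dist = np.asarray(dist, dtype=float)
    if dist.ndim != 2 or dist.shape[0] != dist.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(dist, dist.T):
        raise ValueError("distance matrix must be symmetric")
    Z = hierarchy.linkage(squareform(dist, checks=False), method="complete")
    return ClusterAssignment(labels=list(labels), linkage=Z)


def cut_clusters(assignment: ClusterAssignment, k: int) -> dict:
    """Partition the dendrogram into k clusters (cluster ids 1..k)."""
    n = len(assignment.labels)
    if not 1 <= k <= n:
        raise ValueError(f"k={k} out of range 1..{n}")
    flat = hierarchy.fcluster(assignment.linkage, t=k, criterion="maxclust")
    assignment.clusters = dict(zip(assignment.labels, (int(c) for c in flat)))
    return assignment.clusters


def cluster_keycode_matrix(matrix: pd.DataFrame, k: int = 6) -> ClusterAssignment:
    dist = gower_distance(matrix)
    assignment = complete_linkage(dist, list(matrix.index))
    cut_clusters(assignment, min(k, len(matrix)))
    return assignment


def linkage_to_newick(assignment: ClusterAssignment) -> str:
    """Dendrogram as a Newick string (heights as branch lengths)."""
    tree = hierarchy.to_tree(assignment.linkage)

    def _walk(node, parent_height):
        bl = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{assignment.labels[node.id]}:{bl:.6g}"
        left = _walk(node.left, node.dist)
        right = _walk(node.right, node.dist)
        return f"({left},{right}):{bl:.6g}"

    return _walk(tree, tree.dist) + ";"


def random_subset_clustering(
    profiles: dict[str, BindingProfile],
    row_rbps: Sequence[str],
    subset_size: int = 2000,
    n_repeats: int = 10,
    k: int = 6,
    alpha: float = 0.05,
    min_pct: float = 2.0,
    seed: int = 0,
) -> list[tuple[pd.DataFrame, ClusterAssignment]]:
    """Re-cluster random intron subsets (for the other-short / long intron
    analyses): each repeat samples ``subset_size`` introns without
    replacement, builds the key-code matrix, and clusters it.  Seeded.

    When the population is smaller than ``subset_size``, a single repeat runs
    on the full set (with a warning).
    """
    ids = sorted(profiles)
    rng = np.random.default_rng(seed)
    if len(ids) < subset_size:
        warnings.warn(
            f"population {len(ids)} < subset size {subset_size}; single repeat on full set"
        )
        matrix = build_keycode_matrix(profiles, row_rbps, alpha=alpha, min_pct=min_pct)
        return [(matrix, cluster_keycode_matrix(matrix, k=k))]
    out = []
    for _ in range(n_repeats):
        chosen = rng.choice(len(ids), size=subset_size, replace=False)
        sub = {ids[i]: profiles[ids[i]] for i in chosen}
        matrix = build_keycode_matrix(sub, row_rbps, alpha=alpha, min_pct=min_pct)
        out.append((matrix, cluster_keycode_matrix(matrix, k=k)))
    return out
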