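"""Multi-region clonal-evolution analysis of dual-histology skin masses.

Regions dissected from a single mass (plus an optional bulk cross-
section) are summarized as a binary gene x region incidence matrix: a
cell is 1 when the region carries at least one genic insertion with read
depth strictly above the regional clonal cutoff (200 reads by default,
reflecting the shallower multi-region libraries). Two-dimensional
agglomerative clustering with the Hamming distance and Ward's linkage
groups regions by clonal ancestry; insertions shared at the identical
TA nucleotide address across all regions mark the trunk of the mass.

Ward's update formula is applied to Hamming distances even though Ward
presumes Euclidean geometry; this mirrors the analysis the package
models and is flagged as a caveat in the methods note.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .insertion_io import GenomeModel, assign_insertions_to_genes

__all__ = [
    "build_region_matrix",
    "CladeResult",
    "cluster_binary_matrix",
    "shared_address_trunk",
    "linkage_to_newick",
]


def build_region_matrix(
    regions: dict[str, pd.DataFrame],
    model: GenomeModel,
    depth_cutoff: int = 200,
    min_regions: int = 1,
) -> pd.DataFrame:
    """Binary gene x region incidence matrix at a regional depth cutoff.

    ``regions`` maps region label -> insertion table. Cell (g, r) is 1
    iff region r has at least one insertion in gene g with read_count
    strictly above ``depth_cutoff``. Genes qualifying in fewer than
    ``min_regions`` regions are dropped (all-zero rows never appear).
    Region columns are kept in input order; empty regions are retained
    as all-zero columns.
    """
    if len(regions) < 2:
        raise ValueError("need at least two regions")
    cols = {}
    for label, table in regions.items():
        ann = assign_insertions_to_genes(table, model)
        hit = ann[(ann["read_count"] > depth_cutoff) & ann["gene_id"].notna()]
        cols[label] = set(hit["gene_id"])
    all_genes = sorted(set().union(*cols.values()))
    mat = pd.DataFrame(
        {label: [int(g in genes) for g in all_genes] for label, genes in cols.items()},
        index=pd.Index(all_genes, name="gene_id"),
    )
    keep = mat.sum(axis=1) >= min_regions
    return mat.loc[keep]


@dataclass
class CladeResult:
    """Two-dimensional clustering of a region incidence matrix."""

    row_linkage: np.ndarray
    col_linkage: np.ndarray
    ordered_matrix: pd.DataFrame
    trunk_genes: list[str]  # present in every region
    private_genes: list[str]  # present in exactly one region


def cluster_binary_matrix(matrix: pd.DataFrame) -> CladeResult:
    """Cluster genes (rows) and regions (columns) with Hamming + Ward.

    Pairwise distance is the fraction of mismatching entries; a constant
    matrix degenerates to zero distances, not an error. Leaf order from
    scipy's deterministic agglomeration reorders the returned matrix.
    """
    if matrix.shape[0] < 2 or matrix.shape[1] < 2:
        raise ValueError("matrix must have at least two rows and two columns")
    x = matrix.to_numpy(dtype=float)
    row_link = hierarchy.linkage(pdist(x, metric="hamming"), method="ward")
    col_link = hierarchy.linkage(pdist(x.T, metric="hamming"), method="ward")
    row_order = hierarchy.leaves_list(row_link)
    col_order = hierarchy.leaves_list(col_link)
    ordered = matrix.iloc[row_order, col_order]
    sums = matrix.sum(axis=1)
    trunk = sorted(matrix.index[sums == matrix.shape[1]])
    private = sorted(matrix.index[sums == 1])
    return CladeResult(row_link, col_link, ordered, trunk, private)


def shared_address_trunk(regions: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Insertion addresses shared across regions of one mass.

    Returns one row per (chrom, pos, strand) address observed in more
    than one region, with per-region read depths, the number of carrying
    regions, and ``trunk`` = True when every region carries it. Trunk
    addresses evidence a single clonal origin; addresses shared by only
    a subset are reported as subclonal shared events.
    """
    if len(regions) < 2:
        raise ValueError("need at least two regions")
    labels = list(regions)
    keyed = {}
    for label, table in regions.items():
        depth = table.groupby(["chrom", "pos", "strand"])["read_count"].sum()
        keyed[label] = depth
    all_keys = sorted(set().union(*(set(d.index) for d in keyed.values())))
    rows = []
    for key in all_keys:
        depths = {
            label: int(keyed[label].get(key, 0)) for label in labels
        }
        n_regions = sum(v > 0 for v in depths.values())
        if n_regions < 2:
            continue
        rows.append(
            {
                "chrom": key[0],
                "pos": key[1],
                "strand": key[2],
                "n_regions": n_regions,
                "trunk": n_regions == len(labels),
                **{f"depth_{label}": depths[label] for label in labels},
            }
        )
    cols = ["chrom", "pos", "strand", "n_regions", "trunk"] + [
        f"depth_{label}" for label in labels
    ]
    return pd.DataFrame(rows, columns=cols)


def linkage_to_newick(link: np.ndarray, labels: list[str]) -> str:
    """Serialize a scipy linkage matrix as a Newick tree string."""
    tree = hierarchy.to_tree(link)

    def _fmt(node, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = _fmt(node.left, node.dist)
        right = _fmt(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return _fmt(tree, tree.dist) + ";"
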