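"""Cluster-relatedness dendrogram from transcriptome correlation.

Each cluster is summarized by the mean normalized expression of the
variable genes (the set surviving the ANOVA sample-variance filter for the
cell type); the distance between two clusters is (1 - Pearson r)/2, which
maps perfect correlation to 0 and perfect anticorrelation to 1. The tree
is built by average-linkage (UPGMA) agglomeration by default, with
neighbor joining available, and serialized as Newick.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average
from scipy.spatial.distance import squareform
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

__all__ = ["cluster_profiles", "cluster_distance", "build_tree"]


def cluster_profiles(norm: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """clusters x genes matrix of mean normalized expression."""
    labels = labels.reindex(norm.columns)
    prof = norm.T.groupby(labels, observed=True).mean()
    prof.index.name = "cluster"
    return prof


def cluster_distance(profiles: pd.DataFrame) -> pd.DataFrame:
    """Pairwise (1 - Pearson r)/2 between cluster profiles."""
    if profiles.shape[0] < 2:
        raise ValueError("need at least 2 clusters")
    if profiles.shape[1] < 2:
        raise ValueError("need at least 2 genes")
    sd = profiles.std(axis=1, ddof=0)
    flat = sd[sd == 0].index.tolist()
    if flat:
        raise ValueError(f"constant profile(s), correlation undefined: {flat}")
    r = np.corrcoef(profiles.to_numpy(dtype=float))
    d = (1.0 - r) / 2.0
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, 1.0)  # symmetrize away rounding
    return pd.DataFrame(d, index=profiles.index, columns=profiles.index)


def build_tree(dist: pd.DataFrame, method: str = "average") -> TreeNode:
    """Dendrogram from the distance matrix.

    ``method='average'`` (UPGMA, default) or ``'nj'`` (neighbor joining).
    Leaves are named after clusters; the returned tree carries branch
    lengths and writes valid Newick via ``str(tree)`` / ``tree.write``.
    """
    arr = dist.to_numpy(dtype=float)
    if not np.allclose(arr, arr.T, atol=1e-10):
        raise ValueError("distance matrix is not symmetric")
    ids = [str(i) for i in dist.index]
    if method == "average":
        linkage = average(squareform(arr, checks=False))
        tree = TreeNode.from_linkage_matrix(linkage, ids)
        # from_linkage_matrix leaves internal nodes unnamed with lengths; fine
    elif method == "nj":
        tree = nj(DistanceMatrix(arr, ids))
    else:
        raise ValueError("method must be 'average' or 'nj'")
    return tree
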