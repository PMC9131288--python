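"""Signature-gene specificity scores, gene-set scores and the DE filter.

A signature gene for a cluster is highly expressed in that cluster but not
in the other clusters of its cell type, and specific to the cell type
relative to the other cell types. Two scores capture this:

* **cluster specificity** — with t the 25th percentile of the gene's
  nonzero values in the focal cluster, let h_c be the fraction of cells of
  cluster c with value > t. The score is ``max(0, 1 - max_other(h)/h_focal)``:
  exactly 1 when the gene is expressed only in the focal cluster and exactly
  0 when some other cluster's high-expressed fraction reaches the focal one.
* **cell-type specificity** — same construction across cell types, with the
  detection threshold the 5th percentile of the gene's nonzero values over
  all cells.

The combined score is their geometric mean; genes at or above 0.7 are
flagged as signature genes. Candidate genes come from a per-cluster
differential-expression step: a Wilcoxon rank-sum test with
Benjamini-Hochberg correction, filtered at expression percent > 10%,
fold change > 2 and adjusted p < 0.05.

The exact algebraic form of the two scores admits several variants that
satisfy the stated boundary behavior; the ratio form above is the default
and a ``strategy`` hook allows substituting another (e.g. a difference
form ``max(0, h_focal - max_other)/h_focal`` is the same thing; a mean-based
competitor aggregation is deliberately not used because the zero boundary
is defined against the single worst competitor).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

__all__ = [
    "cluster_specificity",
    "cell_type_specificity",
    "identify_signature_genes",
    "gene_set_score",
    "de_test",
    "EXHAUSTION_GENES",
]

#: Inhibitory-receptor panel used for the per-cell exhaustion score.
EXHAUSTION_GENES = ("PDCD1", "LAG3", "TIGIT", "HAVCR2", "CTLA4")


def _specificity_from_fractions(h_focal: float, h_other_max: float) -> float:
    if h_other_max == 0.0:
        return 1.0
    if h_focal == 0.0:
        return 0.0
    return max(0.0, 1.0 - h_other_max / h_focal)


def cluster_specificity(
    norm: pd.DataFrame,
    labels: pd.Series,
    gene: str,
    focal_cluster: str,
    quantile: float = 0.25,
) -> float:
    """How exclusively the gene's high-expressing cells sit in one cluster.

    The high-expression threshold t is the ``quantile`` (default 1/4)
    quantile of the gene's *nonzero* values within the focal cluster; cells
    with value > t count as high in every cluster. Returns 0 when the gene
    is silent in the focal cluster.
    """
    labels = labels.reindex(norm.columns)
    if focal_cluster not in set(labels.dropna().unique()):
        raise KeyError(f"unknown cluster {focal_cluster!r}")
    values = norm.loc[gene].to_numpy(dtype=float)
    focal_mask = (labels == focal_cluster).to_numpy()
    focal_vals = values[focal_mask]
    nonzero = focal_vals[focal_vals > 0]
    if nonzero.size == 0:
        return 0.0
    t = np.quantile(nonzero, quantile)
    h_focal = float((focal_vals > t).mean())
    h_other_max = 0.0
    for other in labels.dropna().unique():
        if other == focal_cluster:
            continue
        mask = (labels == other).to_numpy()
        if mask.any():
            h_other_max = max(h_other_max, float((values[mask] > t).mean()))
    return _specificity_from_fractions(h_focal, h_other_max)


def cell_type_specificity(
    norm: pd.DataFrame,
    cell_type_labels: pd.Series,
    gene: str,
    focal_type: str,
    percentile: float = 5.0,
) -> float:
    """How exclusively the gene's expressing cells sit in one cell type.

    A cell counts as expressing when its value exceeds the ``percentile``-th
    percentile of the gene's nonzero values over *all* cells. With a single
    cell type present the score is defined as 1 (with a warning).
    """
    labels = cell_type_labels.reindex(norm.columns)
    types = list(labels.dropna().unique())
    if focal_type not in types:
        raise KeyError(f"unknown cell type {focal_type!r}")
    if len(types) < 2:
        warnings.warn("single cell type present; cell-type specificity set to 1", stacklevel=2)
        return 1.0
    values = norm.loc[gene].to_numpy(dtype=float)
    nonzero = values[values > 0]
    focal_mask = (labels == focal_type).to_numpy()
    if nonzero.size == 0 or values[focal_mask].max(initial=0.0) == 0.0:
        return 0.0
    t = np.percentile(nonzero, percentile)
    f_focal = float((values[focal_mask] > t).mean())
    f_other_max = 0.0
    for other in types:
        if other == focal_type:
            continue
        mask = (labels == other).to_numpy()
        if mask.any():
            f_other_max = max(f_other_max, float((values[mask] > t).mean()))
    return _specificity_from_fractions(f_focal, f_other_max)


def identify_signature_genes(
    candidates: dict[str, list[str]],
    norm: pd.DataFrame,
    cluster_labels: pd.Series,
    cell_type_labels: pd.Series,
    focal_type: str,
    cutoff: float = 0.7,
) -> pd.DataFrame:
    """Score candidate (differentially expressed) genes per cluster.

    ``candidates`` maps each cluster of the focal cell type to its DE gene
    list. ``norm`` spans all cell types; cluster labels need only cover the
    focal type's cells. The combined score is the geometric mean of cluster
    and cell-type specificity; genes with combined >= ``cutoff`` are flagged.
    Output is sorted by combined score descending, ties broken by gene ID.
    """
    type_mask = (cell_type_labels.reindex(norm.columns) == focal_type).to_numpy()
    norm_type = norm.loc[:, type_mask]
    rows = []
    for cluster, genes in candidates.items():
        for gene in genes:
            cs = cluster_specificity(norm_type, cluster_labels, gene, cluster)
            cts = cell_type_specificity(norm, cell_type_labels, gene, focal_type)
            combined = float(np.sqrt(cs * cts))
            rows.append(
                {
                    "gene": gene,
                    "cluster": cluster,
                    "cluster_specificity": cs,
                    "cell_type_specificity": cts,
                    "combined": combined,
                    "is_signature": combined >= cutoff,
                }
            )
    out = pd.DataFrame(
        rows,
        columns=[
            "gene",
            "cluster",
            "cluster_specificity",
            "cell_type_specificity",
            "combined",
            "is_signature",
        ],
    )
    return out.sort_values(
        ["combined", "gene"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)


def gene_set_score(
    norm: pd.DataFrame, gene_set: list[str], min_coverage: float = 0.5
) -> tuple[pd.Series, list[str]]:
    """Per-cell mean normalized expression over a gene set.

    Used for the exhaustion panel (:data:`EXHAUSTION_GENES`), M1/M2
    macrophage programs, Treg signatures etc. Missing genes are returned,
    never silently dropped; if fewer than ``min_coverage`` of the set is
    present an error names them.
    """
    if not gene_set:
        raise ValueError("empty gene set")
    present = [g for g in gene_set if g in norm.index]
    missing = [g for g in gene_set if g not in norm.index]
    if len(present) < min_coverage * len(gene_set) or not present:
        raise ValueError(
            f"only {len(present)}/{len(gene_set)} gene-set genes present; "
            f"missing: {missing}"
        )
    scores = norm.loc[present].mean(axis=0)
    scores.name = "gene_set_score"
    return scores, missing


def de_test(
    norm: pd.DataFrame,
    group_a: list[str],
    group_b: list[str],
    min_pct: float = 0.10,
    min_fold_change: float = 2.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-gene differential expression between two cell groups.

    Two-sided Wilcoxon rank-sum p values with Benjamini-Hochberg
    adjustment across all tested genes; fold change is
    ``(mean expm1_a + 1) / (mean expm1_b + 1)`` (pseudocount 1 keeps it
    finite); expression percent is the detected fraction per group. A gene
    passes the filter when it is detected in more than ``min_pct`` of
    either group, its fold change exceeds ``min_fold_change`` and its
    adjusted p is below ``alpha``.
    """
    if len(group_a) < 3 or len(group_b) < 3:
        raise ValueError("both groups need at least 3 cells")
    a = norm.loc[:, group_a].to_numpy(dtype=float)
    b = norm.loc[:, group_b].to_numpy(dtype=float)
    pct_a = (a > 0).mean(axis=1)
    pct_b = (b > 0).mean(axis=1)
    mean_a = np.expm1(a).mean(axis=1)
    mean_b = np.expm1(b).mean(axis=1)
    fold = (mean_a + 1.0) / (mean_b + 1.0)
    pvals = mannwhitneyu(a, b, axis=1, alternative="two-sided").pvalue
    # constant genes give nan under tie-only data; they carry no signal
    pvals = np.where(np.isnan(pvals), 1.0, pvals)
    padj = multipletests(pvals, method="fdr_bh")[1]
    passes = (
        (np.maximum(pct_a, pct_b) > min_pct)
        & (fold > min_fold_change)
        & (padj < alpha)
    )
    return pd.DataFrame(
        {
            "pct_a": pct_a,
            "pct_b": pct_b,
            "fold_change": fold,
            "p_value": pvals,
            "p_adj": padj,
            "passes_filter": passes,
        },
        index=norm.index,
    )
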