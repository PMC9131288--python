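"""Ligand-receptor interaction testing between cell clusters.

For a directed cluster pair (A -> B) and a catalogued ligand-receptor pair,
the interaction statistic is the average of the ligand's mean normalized
expression in cluster A and the receptor's mean in cluster B; for a
multi-subunit complex the subunit with the minimum cluster mean stands in
for the complex. Only combinations whose every ligand subunit is detected
in more than 25% of cluster-A cells and every receptor subunit in more
than 25% of cluster-B cells are tested. Significance comes from a
permutation null: cluster labels are shuffled over all cells (the same
shuffles for every pair, one shared null per permutation), and the
empirical P value is the proportion of permuted statistics as or more
extreme (>=, one-sided: interactions are enrichment claims) than the
observed one, with an add-one pseudocount so P is never 0.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = [
    "validate_lr_table",
    "expression_filter",
    "interaction_statistic",
    "permutation_test",
]


def validate_lr_table(lr: pd.DataFrame, genes: list[str] | pd.Index) -> list[str]:
    """Check pair-ID uniqueness and return the catalogue genes absent from
    the expression matrix (callers decide whether to drop those pairs)."""
    if lr["pair_id"].duplicated().any():
        dupes = lr.loc[lr["pair_id"].duplicated(), "pair_id"].tolist()
        raise ValueError(f"duplicate pair IDs: {dupes}")
    known = set(genes)
    missing: list[str] = []
    for _, row in lr.iterrows():
        for g in tuple(row["ligand_genes"]) + tuple(row["receptor_genes"]):
            if g not in known and g not in missing:
                missing.append(g)
    return missing


def _cluster_codes(labels: pd.Series, columns: pd.Index) -> tuple[np.ndarray, list[str]]:
    labels = labels.reindex(columns)
    cat = pd.Categorical(labels)
    if labels.isna().any():
        raise ValueError("cells without a cluster label")
    return cat.codes.astype(np.intp), [str(c) for c in cat.categories]


def _group_means(x: np.ndarray, codes: np.ndarray, n_clusters: int) -> np.ndarray:
    """genes x clusters means via one-hot summation."""
    sums = np.zeros((x.shape[0], n_clusters))
    np.add.at(sums.T, codes, x.T)
    counts = np.bincount(codes, minlength=n_clusters).astype(float)
    counts[counts == 0] = np.nan
    return sums / counts[None, :]


def expression_filter(
    norm: pd.DataFrame,
    labels: pd.Series,
    lr: pd.DataFrame,
    min_frac: float = 0.25,
) -> pd.DataFrame:
    """Enumerate (cluster_a, cluster_b, pair) combinations and flag which
    pass the detection filter.

    A combination is tested iff every ligand subunit is detected (value
    > 0) in strictly more than ``min_frac`` of cluster-A cells and every
    receptor subunit likewise in cluster B. Pairs with genes missing from
    the matrix are never tested.
    """
    codes, clusters = _cluster_codes(labels, norm.columns)
    missing = set(validate_lr_table(lr, norm.index))
    det = _group_means((norm.to_numpy(dtype=float) > 0).astype(float), codes, len(clusters))
    det_df = pd.DataFrame(det, index=norm.index, columns=clusters)
    rows = []
    for _, row in lr.iterrows():
        lig = tuple(row["ligand_genes"])
        rec = tuple(row["receptor_genes"])
        mappable = not (set(lig) | set(rec)) & missing
        for a in clusters:
            lig_ok = mappable and all(det_df.loc[g, a] > min_frac for g in lig)
            for b in clusters:
                rec_ok = mappable and all(det_df.loc[g, b] > min_frac for g in rec)
                rows.append(
                    {
                        "cluster_a": a,
                        "cluster_b": b,
                        "pair_id": row["pair_id"],
                        "tested": bool(lig_ok and rec_ok),
                    }
                )
    return pd.DataFrame(rows)


def interaction_statistic(
    norm: pd.DataFrame,
    labels: pd.Series,
    pair: pd.Series,
    cluster_a: str,
    cluster_b: str,
) -> float:
    """Mean-of-means statistic for one combination (min-subunit rule)."""
    codes, clusters = _cluster_codes(labels, norm.columns)
    means = _group_means(norm.to_numpy(dtype=float), codes, len(clusters))
    means_df = pd.DataFrame(means, index=norm.index, columns=clusters)
    lig = min(means_df.loc[g, cluster_a] for g in tuple(pair["ligand_genes"]))
    rec = min(means_df.loc[g, cluster_b] for g in tuple(pair["receptor_genes"]))
    return float((lig + rec) / 2.0)


def permutation_test(
    norm: pd.DataFrame,
    labels: pd.Series,
    lr: pd.DataFrame,
    n_perm: int = 1000,
    seed: int = 0,
    min_frac: float = 0.25,
    alpha: float = 0.05,
    pseudocount: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Permutation interaction test over all directed cluster pairs.

    Returns the per-combination results (observed statistic, empirical P
    for tested combinations) and the directed cluster x cluster matrix
    counting pairs with P < ``alpha``. With ``pseudocount`` (default) the
    empirical P is (1 + #{perm >= obs}) / (n_perm + 1); switching it off
    gives the raw proportion (which can be 0).
    """
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is low; empirical P values will be coarse", stacklevel=2)
    codes, clusters = _cluster_codes(labels, norm.columns)
    n_clusters = len(clusters)
    combos = expression_filter(norm, labels, lr, min_frac=min_frac)
    counts_mat = pd.DataFrame(0, index=clusters, columns=clusters, dtype=int)
    if combos.empty or not combos["tested"].any():
        out = combos.assign(observed_stat=np.nan, empirical_p=np.nan)
        return out, counts_mat

    # restrict to genes actually used, with min-subunit evaluation per pair
    used_genes: list[str] = []
    for _, row in lr.iterrows():
        for g in tuple(row["ligand_genes"]) + tuple(row["receptor_genes"]):
            if g in norm.index and g not in used_genes:
                used_genes.append(g)
    gene_pos = {g: i for i, g in enumerate(used_genes)}
    x = norm.loc[used_genes].to_numpy(dtype=float)

    pair_rows = {
        row["pair_id"]: (
            [gene_pos[g] for g in tuple(row["ligand_genes"]) if g in gene_pos],
            [gene_pos[g] for g in tuple(row["receptor_genes"]) if g in gene_pos],
        )
        for _, row in lr.iterrows()
    }
    tested = combos[combos["tested"]].reset_index(drop=True)
    cluster_pos = {c: i for i, c in enumerate(clusters)}
    a_idx = tested["cluster_a"].map(cluster_pos).to_numpy()
    b_idx = tested["cluster_b"].map(cluster_pos).to_numpy()

    def combo_stats(means: np.ndarray) -> np.ndarray:
        lig_min = {}
        rec_min = {}
        for pid, (lrows, rrows) in pair_rows.items():
            if lrows and rrows:
                lig_min[pid] = means[lrows].min(axis=0)
                rec_min[pid] = means[rrows].min(axis=0)
        return np.array(
            [
                (lig_min[pid][a] + rec_min[pid][b]) / 2.0
                for pid, a, b in zip(tested["pair_id"], a_idx, b_idx)
            ]
        )

    observed = combo_stats(_group_means(x, codes, n_clusters))
    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(tested), dtype=int)
    for _ in range(n_perm):  # one shared shuffle per permutation for all pairs
        perm = rng.permutation(codes)
        exceed += combo_stats(_group_means(x, perm, n_clusters)) >= observed
    if pseudocount:
        pvals = (1.0 + exceed) / (n_perm + 1.0)
    else:
        pvals = exceed / float(n_perm)

    tested = tested.assign(observed_stat=observed, empirical_p=pvals)
    untested = combos[~combos["tested"]].assign(
        observed_stat=np.nan, empirical_p=np.nan
    )
    results = pd.concat([tested, untested], ignore_index=True)
    sig = tested[tested["empirical_p"] < alpha]
    for _, row in sig.iterrows():
        counts_mat.loc[row["cluster_a"], row["cluster_b"]] += 1
    return results, counts_mat
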