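"""Tumor-vs-normal cluster abundance testing with a Poisson GLM.

The number of cells a sample contributes to a cluster is modeled as a
Poisson count with the sample's total cell count as exposure:

    log E[count_s] = beta0 + beta1 * I(tumor_s) + log(total_s)

beta1 is the log rate ratio of the cluster's per-cell rate in tumor versus
normal samples; its significance is a Wald test. Overdispersion is not
modeled by default (plain Poisson likelihood); a quasi-Poisson scale
estimate can be switched on. Raw p values are the primary output;
Benjamini-Hochberg adjusted values are reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

__all__ = ["AbundanceInput", "tabulate", "test_cluster_abundance", "test_all_clusters"]


@dataclass
class AbundanceInput:
    """Per-(sample, cluster) cell counts plus per-sample totals/conditions."""

    counts: pd.DataFrame  # samples x clusters
    totals: pd.Series  # per sample
    condition: pd.Series  # per sample, tumor|normal

    def __post_init__(self) -> None:
        if not (self.counts.sum(axis=1) == self.totals.reindex(self.counts.index)).all():
            raise ValueError("cluster counts do not sum to sample totals")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")


def tabulate(cells: pd.DataFrame, cluster_col: str = "cluster") -> AbundanceInput:
    """Cross-tabulate cells into the (sample, cluster) design.

    ``cells`` needs ``sample``, ``condition`` and the cluster column; empty
    (sample, cluster) combinations are kept as explicit zeros.
    """
    required = ["sample", "condition", cluster_col]
    bad = cells[required].isna().any(axis=1)
    if bad.any():
        raise ValueError(
            f"cells with missing labels: {list(cells.index[bad][:5])}"
        )
    counts = pd.crosstab(cells["sample"], cells[cluster_col])
    counts.columns.name = None
    counts.index.name = "sample"
    totals = counts.sum(axis=1)
    condition = cells.groupby("sample")["condition"].agg(
        lambda v: v.iloc[0] if (v == v.iloc[0]).all() else None
    )
    if condition.isna().any():
        raise ValueError("a sample maps to more than one condition")
    return AbundanceInput(counts=counts, totals=totals, condition=condition)


def test_cluster_abundance(
    tab: AbundanceInput, cluster: str, quasi_poisson: bool = False
) -> pd.Series:
    """Wald test of tumor enrichment for one cluster.

    Returns a Series with ``beta`` (log rate ratio, tumor vs normal),
    ``se``, ``z``, ``p``, ``direction`` and a ``continuity_corrected`` flag.
    When one condition contributes only zeros, 0.5 is added to every
    sample's count for this cluster to keep the Wald statistic finite.
    """
    if cluster not in tab.counts.columns:
        raise KeyError(f"unknown cluster {cluster!r}")
    is_tumor = (tab.condition == "tumor").astype(float)
    if is_tumor.nunique() < 2:
        raise ValueError("need at least one sample per condition")
    y = tab.counts[cluster].astype(float).reindex(tab.condition.index)
    corrected = False
    for cond_mask in (is_tumor == 1.0, is_tumor == 0.0):
        if (y[cond_mask] == 0).all():
            y = y + 0.5
            corrected = True
            break
    x = sm.add_constant(is_tumor.to_numpy())
    offset = np.log(tab.totals.reindex(tab.condition.index).to_numpy(dtype=float))
    model = sm.GLM(y.to_numpy(), x, family=sm.families.Poisson(), offset=offset)
    scale = "X2" if quasi_poisson else 1.0
    fit = model.fit(scale=scale, maxiter=200, tol=1e-12)
    beta = fit.params[1]
    se = fit.bse[1]
    z = beta / se
    p = fit.pvalues[1]
    return pd.Series(
        {
            "beta": beta,
            "se": se,
            "z": z,
            "p": p,
            "direction": "tumor" if beta > 0 else "normal",
            "continuity_corrected": corrected,
        },
        name=cluster,
    )


def test_all_clusters(tab: AbundanceInput, quasi_poisson: bool = False) -> pd.DataFrame:
    """Per-cluster Wald tests with BH-adjusted p values alongside raw p."""
    rows = [
        test_cluster_abundance(tab, c, quasi_poisson=quasi_poisson)
        for c in tab.counts.columns
    ]
    out = pd.DataFrame(rows)
    out.index.name = "cluster"
    out["p_adj"] = multipletests(out["p"].to_numpy(dtype=float), method="fdr_bh")[1]
    return out
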