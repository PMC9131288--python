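"""Bulk-cohort signature scoring and quartile group assignment.

TPM values are first normalized gene-wise by the mean TPM over normal
samples (so a normalized value of 1 means "at the normal-tissue level").
For a signature gene set, tumor samples are ranked by their mean
normalized signature expression; the top 25% form the high-expression
group, the bottom 25% the low-expression group (floor(n/4) samples each;
survival modeling on those groups is done downstream with standard
tooling and is outside this package).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = ["normalize_bulk", "assign_groups"]


def normalize_bulk(
    bulk: pd.DataFrame, labels: pd.Series
) -> tuple[pd.DataFrame, list[str]]:
    """Divide each gene's TPM by its mean over normal samples.

    Genes whose normal mean is zero cannot be normalized and are excluded;
    their names are returned. Requires at least one normal sample.
    """
    labels = labels.reindex(bulk.columns)
    normal = bulk.loc[:, (labels == "normal").to_numpy()]
    if normal.shape[1] == 0:
        raise ValueError("no normal samples; normalization undefined")
    if (bulk.to_numpy() < 0).any():
        raise ValueError("negative TPM values")
    mean_normal = normal.mean(axis=1)
    excluded = mean_normal[mean_normal == 0].index.tolist()
    kept = mean_normal[mean_normal > 0].index
    normalized = bulk.loc[kept].div(mean_normal.loc[kept], axis=0)
    return normalized, excluded


def assign_groups(
    normalized: pd.DataFrame,
    labels: pd.Series,
    signature: list[str],
) -> pd.DataFrame:
    """Quartile group assignment of tumor samples by signature average.

    Returns a survival-ready table indexed by tumor sample with the
    ``signature_average`` and ``group`` in {high, low, middle}: exactly
    floor(n/4) samples in the high and in the low group, ranked by the
    average; ties broken by sample ID for determinism (a fully constant
    average is flagged with a warning).
    """
    present = [g for g in signature if g in normalized.index]
    if not present:
        raise ValueError("no signature gene present in the normalized table")
    labels = labels.reindex(normalized.columns)
    tumor = normalized.columns[(labels == "tumor").to_numpy()]
    n = len(tumor)
    if n < 8:
        raise ValueError(f"need at least 8 tumor samples for quartile groups, got {n}")
    avg = normalized.loc[present, tumor].mean(axis=0)
    if avg.nunique() == 1:
        warnings.warn(
            "constant signature average: groups determined solely by the "
            "sample-ID tie-break",
            stacklevel=2,
        )
    k = n // 4
    order = (
        avg.rename("signature_average")
        .rename_axis("sample")
        .reset_index()
        .sort_values(["signature_average", "sample"], kind="stable")
        .set_index("sample")
    )
    group = np.array(["middle"] * n, dtype=object)
    group[:k] = "low"
    group[n - k :] = "high"
    return order.assign(group=group)
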