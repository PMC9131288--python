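"""QC filtering, normalization, variable-gene selection and PCA embedding.

The conventions follow the standard droplet scRNA-seq pipeline: cells are
kept when they express more than ``min_genes`` and fewer than ``max_genes``
genes and their mitochondrial UMI fraction does not exceed
``max_mito_fraction``; counts are scaled to a fixed total per cell
(scale factor 10,000) and log1p-transformed; variable genes are chosen by a
mean/dispersion window on the de-logged values; expression is optionally
regressed on per-cell covariates, then z-scaled (clipped) and projected on
the top principal components.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.decomposition import PCA

from .synthetic import CountMatrix

__all__ = [
    "QCThresholds",
    "VariableGeneCriteria",
    "qc_metrics",
    "qc_filter",
    "normalize",
    "select_variable_genes",
    "regress_and_embed",
]


@dataclass(frozen=True)
class QCThresholds:
    """Cell-level QC cutoffs.

    A cell is kept iff ``min_genes <= n_expressed <= max_genes`` and its
    mitochondrial fraction is ``<= max_mito_fraction`` (cells with *less
    than* ``min_genes``, *more than* ``max_genes`` or a fraction
    *exceeding* the cap are removed; the boundaries themselves survive).
    """

    min_genes: int = 200
    max_genes: int = 7000
    max_mito_fraction: float = 0.10

    def __post_init__(self) -> None:
        if self.min_genes >= self.max_genes:
            raise ValueError("min_genes must be below max_genes")
        if not 0 <= self.max_mito_fraction <= 1:
            raise ValueError("max_mito_fraction must be in [0, 1]")


@dataclass(frozen=True)
class VariableGeneCriteria:
    """Mean/dispersion window for variable-gene selection.

    Mean and dispersion (variance/mean) are computed on expm1 of the
    log-normalized values. A gene is variable iff
    ``mean_min <= mean <= mean_max`` and ``dispersion >= dispersion_min``.
    """

    mean_min: float = 0.05
    mean_max: float = 5.0
    dispersion_min: float = 0.5

    def __post_init__(self) -> None:
        if self.mean_min >= self.mean_max:
            raise ValueError("mean_min must be below mean_max")


def qc_metrics(counts: CountMatrix, mito_prefix: str = "MT-") -> pd.DataFrame:
    """Per-cell QC metrics: expressed genes, total UMIs, mito fraction."""
    m = counts.matrix.tocsc()
    n_expressed = np.asarray((m > 0).sum(axis=0)).ravel()
    total = np.asarray(m.sum(axis=0)).ravel().astype(float)
    mito_rows = np.array([g.startswith(mito_prefix) for g in counts.genes])
    mito = (
        np.asarray(m[mito_rows].sum(axis=0)).ravel().astype(float)
        if mito_rows.any()
        else np.zeros_like(total)
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total > 0, mito / np.maximum(total, 1.0), 0.0)
    return pd.DataFrame(
        {
            "n_genes_expressed": n_expressed,
            "total_umi": total,
            "mito_fraction": frac,
        },
        index=pd.Index(counts.barcodes, name="barcode"),
    )


def qc_filter(
    counts: CountMatrix,
    cells: pd.DataFrame,
    thresholds: QCThresholds = QCThresholds(),
    mito_prefix: str = "MT-",
) -> tuple[CountMatrix, pd.DataFrame]:
    """Drop low-quality cells; genes are left untouched.

    ``cells`` must be indexed by barcode and aligned with ``counts``;
    the returned table gains the QC metric columns. Cells carrying a truthy
    ``doublet`` column are dropped as well. Raises if no cell survives.
    """
    metrics = qc_metrics(counts, mito_prefix=mito_prefix)
    keep = (
        (metrics["n_genes_expressed"] >= thresholds.min_genes)
        & (metrics["n_genes_expressed"] <= thresholds.max_genes)
        & (metrics["mito_fraction"] <= thresholds.max_mito_fraction)
    ).to_numpy()
    if "doublet" in cells.columns:
        keep &= ~cells["doublet"].reindex(counts.barcodes).fillna(False).astype(bool).to_numpy()
    if not keep.any():
        raise ValueError("QC filtering removed every cell")
    kept_barcodes = [b for b, k in zip(counts.barcodes, keep) if k]
    filtered = CountMatrix(
        genes=list(counts.genes),
        barcodes=kept_barcodes,
        matrix=counts.matrix.tocsc()[:, keep].tocsr(),
    )
    out_cells = (
        cells.reindex(kept_barcodes)
        .drop(columns=metrics.columns, errors="ignore")
        .join(metrics.loc[kept_barcodes])
    )
    return filtered, out_cells


def normalize(counts: CountMatrix, scale_factor: float = 10_000.0) -> pd.DataFrame:
    """Total-count scale each cell to ``scale_factor`` and log1p-transform.

    value(g, c) = log(1 + scale_factor * count(g, c) / total(c)).
    Returns a dense genes x cells DataFrame. Zero-total cells are an error.
    """
    m = counts.matrix
    total = np.asarray(m.sum(axis=0)).ravel().astype(float)
    if (total <= 0).any():
        bad = [counts.barcodes[i] for i in np.flatnonzero(total <= 0)[:5]]
        raise ValueError(f"cells with zero total counts (e.g. {bad}); run QC first")
    scaled = m.multiply(scale_factor / total[None, :]).toarray()
    return pd.DataFrame(
        np.log1p(scaled), index=list(counts.genes), columns=list(counts.barcodes)
    )


def select_variable_genes(
    norm: pd.DataFrame, criteria: VariableGeneCriteria = VariableGeneCriteria()
) -> list[str]:
    """Genes inside the mean window with dispersion above the floor.

    Statistics are computed on ``expm1`` of the log-normalized values;
    dispersion is variance/mean (0 for all-zero genes).
    """
    if norm.shape[1] < 2:
        raise ValueError("need at least 2 cells")
    x = np.expm1(norm.to_numpy())
    mean = x.mean(axis=1)
    var = x.var(axis=1, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        disp = np.where(mean > 0, var / np.maximum(mean, 1e-300), 0.0)
    keep = (
        (mean >= criteria.mean_min)
        & (mean <= criteria.mean_max)
        & (disp >= criteria.dispersion_min)
    )
    return [g for g, k in zip(norm.index, keep) if k]


def _regress_out(y: np.ndarray, covariates: np.ndarray) -> np.ndarray:
    """Residuals of each row of y on the covariate columns (with intercept)."""
    n = y.shape[1]
    x = np.column_stack([np.ones(n), covariates])
    # drop collinear columns for a stable fit
    q, r = np.linalg.qr(x)
    diag = np.abs(np.diag(r))
    keep = diag > 1e-10 * max(diag.max(), 1.0)
    if not keep.all():
        warnings.warn("dropping collinear covariate column(s)", stacklevel=3)
        x = x[:, keep]
    beta, *_ = np.linalg.lstsq(x, y.T, rcond=None)
    return y - (x @ beta).T


def regress_and_embed(
    norm: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    n_components: int = 20,
    variable_genes: list[str] | None = None,
    clip: float = 10.0,
    external_embedding: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Covariate regression, per-gene scaling and PCA.

    Per gene: residualize on ``covariates`` (per-cell table, e.g. total UMI
    and mito fraction), center and unit-scale, clip at ``clip``, then project
    the cells onto the top ``n_components`` principal components over
    ``variable_genes`` (all genes if None). If ``external_embedding`` is
    given (e.g. a batch-integrated embedding computed elsewhere) it is
    returned as-is after alignment, making downstream clustering
    integration-agnostic.
    """
    if external_embedding is not None:
        return external_embedding.reindex(norm.columns)
    genes = variable_genes if variable_genes is not None else list(norm.index)
    missing = set(genes) - set(norm.index)
    if missing:
        raise KeyError(f"variable genes absent from matrix: {sorted(missing)[:5]}")
    y = norm.loc[genes].to_numpy(dtype=float, copy=True)
    if covariates is not None:
        cov = covariates.reindex(norm.columns).to_numpy(dtype=float)
        if np.isnan(cov).any():
            raise ValueError("covariates not aligned with cells")
        y = _regress_out(y, cov)
    y -= y.mean(axis=1, keepdims=True)
    sd = y.std(axis=1, ddof=0)
    sd[sd == 0] = 1.0
    y /= sd[:, None]
    np.clip(y, -clip, clip, out=y)
    k = min(n_components, y.shape[0], y.shape[1] - 1)
    pca = PCA(n_components=k, svd_solver="full", random_state=0)
    emb = pca.fit_transform(y.T)
    return pd.DataFrame(
        emb, index=norm.columns, columns=[f"PC{i + 1}" for i in range(k)]
    )
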