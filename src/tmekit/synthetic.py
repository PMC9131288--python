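"""Synthetic multi-sample tumor/normal scRNA-seq data with known ground truth.

Every downstream stage of the pipeline (QC, reclustering, ANOVA batch-gene
filtering, abundance testing, signature scoring, ligand-receptor permutation
testing, bulk quartile grouping) is validated against data produced here,
where the true cluster of every cell, the planted marker genes, the planted
batch-driven genes, the condition-enriched clusters and the active
ligand-receptor pairs are all known by construction.

Counts are negative-binomial (gamma-Poisson): the log-mean of gene *g* in
cell *c* is

    log mu_gc = log(baseline_g) + log(2) * log2fc(g, cluster_c)
                + batch(sample_c, g) + log(library_size_c)

with a per-(sample, gene) Gaussian batch effect drawn once per simulation --
exactly the additive sample-level structure the two-way ANOVA filter is
designed to remove. Mitochondrial genes are an explicit ``MT-`` prefixed
subset whose expected share of each cell's counts is ``mito_fraction_target``,
so QC on the mitochondrial fraction is testable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "CountMatrix",
    "default_marker_plan",
    "simulate_counts",
    "simulate_lr_table",
    "simulate_bulk",
]


@dataclass
class CountMatrix:
    """Sparse genes x cells UMI count matrix with identifiers."""

    genes: list[str]
    barcodes: list[str]
    matrix: sp.csr_matrix  # genes x cells, non-negative integers

    def __post_init__(self) -> None:
        if self.matrix.shape != (len(self.genes), len(self.barcodes)):
            raise ValueError(
                f"matrix shape {self.matrix.shape} does not match "
                f"{len(self.genes)} genes x {len(self.barcodes)} barcodes"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.matrix.toarray(), index=self.genes, columns=self.barcodes
        )


@dataclass
class GroundTruth:
    """What was planted: the answer key for downstream tests."""

    true_cluster: pd.Series  # per-barcode cluster label
    true_markers: dict[str, str]  # gene -> cluster it marks
    true_batch_genes: tuple[str, ...]  # genes with elevated sample effects
    true_enriched_clusters: tuple[str, ...]  # tumor proportion > normal
    true_interactions: frozenset = frozenset()  # (cluster_a, cluster_b, pair)
    log2fc: dict[tuple[str, str], float] = field(default_factory=dict)


@dataclass
class SimulationConfig:
    """Generative parameters for a multi-sample two-condition experiment.

    Defaults describe a deliberately modest experiment: 4 samples (2 tumor,
    2 normal), 3 cell clusters with ten 4-fold markers each, mild shared
    batch variation (sd 0.3 on the natural-log scale), UMI-typical
    overdispersion (inverse-dispersion 5), ~2000 UMIs per cell and a 5%
    mitochondrial load.
    """

    n_genes: int = 500
    n_cells_per_sample: int = 300
    n_samples: int = 4
    n_clusters: int = 3
    condition_assignment: dict[str, str] | None = None  # sample -> tumor|normal
    cluster_proportions: dict[str, np.ndarray] | None = None  # condition -> probs
    marker_plan: list[tuple[str, str, float]] | None = None  # (gene, cluster, log2fc)
    marker_baseline_count: float | None = 0.3  # expected baseline counts/cell of marker genes
    baseline_boost: dict[str, float] = field(default_factory=dict)  # gene -> log2
    batch_sd: float = 0.3
    batch_genes: tuple[str, ...] = ()
    batch_gene_sd: float = 1.0
    dispersion: float = 5.0  # NB inverse-dispersion theta; var = mu + mu^2/theta
    library_size_lognormal: tuple[float, float] = (math.log(2000.0), 0.35)
    n_mito_genes: int = 10
    mito_fraction_target: float = 0.05
    seed: int = 0

    def gene_names(self) -> list[str]:
        n_reg = self.n_genes - self.n_mito_genes
        names = [f"G{i:04d}" for i in range(n_reg)]
        names += [f"MT-{i + 1}" for i in range(self.n_mito_genes)]
        return names

    def sample_names(self) -> list[str]:
        return [f"S{i + 1}" for i in range(self.n_samples)]

    def cluster_names(self) -> list[str]:
        return [f"C{i + 1}" for i in range(self.n_clusters)]

    def resolved_conditions(self) -> dict[str, str]:
        if self.condition_assignment is not None:
            cond = dict(self.condition_assignment)
        else:  # alternate tumor/normal
            cond = {
                s: ("tumor" if i % 2 == 0 else "normal")
                for i, s in enumerate(self.sample_names())
            }
        bad = set(cond.values()) - {"tumor", "normal"}
        if bad:
            raise ValueError(f"conditions must be tumor|normal, got {sorted(bad)}")
        return cond

    def resolved_proportions(self) -> dict[str, np.ndarray]:
        if self.cluster_proportions is None:
            p = np.full(self.n_clusters, 1.0 / self.n_clusters)
            props = {"tumor": p, "normal": p.copy()}
        else:
            props = {k: np.asarray(v, dtype=float) for k, v in self.cluster_proportions.items()}
        for cond, p in props.items():
            if len(p) != self.n_clusters:
                raise ValueError(
                    f"cluster_proportions[{cond!r}] has length {len(p)}, "
                    f"expected n_clusters={self.n_clusters}"
                )
            if abs(p.sum() - 1.0) > 1e-9:
                raise ValueError(f"cluster_proportions[{cond!r}] sums to {p.sum()}, not 1")
            if (p < 0).any():
                raise ValueError("cluster proportions must be non-negative")
        return props

    def validate(self) -> None:
        for name in ("n_genes", "n_cells_per_sample", "n_samples", "n_clusters"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if not 0 <= self.mito_fraction_target < 1:
            raise ValueError("mito_fraction_target must be in [0, 1)")
        if self.n_mito_genes >= self.n_genes:
            raise ValueError("n_mito_genes must be smaller than n_genes")
        genes = set(self.gene_names())
        clusters = set(self.cluster_names())
        for gene, cluster, _ in self.marker_plan or []:
            if gene not in genes:
                raise ValueError(f"marker gene {gene!r} not in the simulated gene list")
            if cluster not in clusters:
                raise ValueError(f"marker cluster {cluster!r} not simulated")
        for gene in self.batch_genes:
            if gene not in genes:
                raise ValueError(f"batch gene {gene!r} not in the simulated gene list")
        self.resolved_conditions()
        self.resolved_proportions()


def default_marker_plan(
    config: SimulationConfig, n_per_cluster: int = 10, log2fc: float = 2.0
) -> list[tuple[str, str, float]]:
    """Assign the first genes as exclusive markers, ``n_per_cluster`` each."""
    genes = config.gene_names()
    plan = []
    k = 0
    for cluster in config.cluster_names():
        for _ in range(n_per_cluster):
            plan.append((genes[k], cluster, log2fc))
            k += 1
    return plan


def simulate_counts(
    config: SimulationConfig,
) -> tuple[CountMatrix, pd.DataFrame, GroundTruth]:
    """Draw a count matrix, a per-cell annotation table and the answer key.

    Returns
    -------
    counts : CountMatrix
        genes x cells sparse UMI counts.
    cells : pandas.DataFrame
        indexed by barcode with columns ``sample``, ``condition``,
        ``cell_type`` and ``true_cluster``.
    truth : GroundTruth
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    genes = config.gene_names()
    n_genes = len(genes)
    samples = config.sample_names()
    clusters = config.cluster_names()
    conditions = config.resolved_conditions()
    proportions = config.resolved_proportions()
    marker_plan = config.marker_plan if config.marker_plan is not None else []

    gene_index = {g: i for i, g in enumerate(genes)}
    cluster_index = {c: i for i, c in enumerate(clusters)}
    is_mito = np.array([g.startswith("MT-") for g in genes])

    # Relative baseline expression; mitochondrial genes carry the target share.
    rel = rng.lognormal(mean=0.0, sigma=1.0, size=n_genes)
    for g, boost in config.baseline_boost.items():
        rel[gene_index[g]] *= 2.0**boost
    if is_mito.any():
        rel[is_mito] *= (
            config.mito_fraction_target
            / (1.0 - config.mito_fraction_target)
            * rel[~is_mito].sum()
            / rel[is_mito].sum()
        )
    rel = rel / rel.sum()
    # pin marker-gene baselines to a known per-cell count so planted effects
    # land at a realistic, detectable expression level
    if config.marker_baseline_count is not None and marker_plan:
        mu_lib, sd_lib = config.library_size_lognormal
        expected_lib = math.exp(mu_lib + sd_lib**2 / 2.0)
        for gene, _, _ in marker_plan:
            rel[gene_index[gene]] = config.marker_baseline_count / expected_lib

    # log2 fold changes per (gene, cluster)
    lfc = np.zeros((n_genes, len(clusters)))
    log2fc_map: dict[tuple[str, str], float] = {}
    true_markers: dict[str, str] = {}
    for gene, cluster, fc in marker_plan:
        lfc[gene_index[gene], cluster_index[cluster]] += fc
        log2fc_map[(gene, cluster)] = log2fc_map.get((gene, cluster), 0.0) + fc
        true_markers[gene] = cluster

    # per-(sample, gene) batch effects, drawn once
    sd = np.full(n_genes, config.batch_sd)
    if config.batch_genes:
        sd[[gene_index[g] for g in config.batch_genes]] = config.batch_gene_sd
    batch = rng.normal(0.0, 1.0, size=(len(samples), n_genes)) * sd[None, :]

    mu_ln, sigma_ln = config.library_size_lognormal

    blocks: list[sp.csr_matrix] = []
    barcodes: list[str] = []
    rows: list[dict] = []
    for si, sample in enumerate(samples):
        cond = conditions[sample]
        n_cells = config.n_cells_per_sample
        cell_clusters = rng.choice(
            len(clusters), size=n_cells, p=proportions[cond]
        )
        lib = rng.lognormal(mean=mu_ln, sigma=sigma_ln, size=n_cells)
        # mean matrix for this sample: genes x cells
        base = rel[:, None] * np.exp(batch[si])[:, None]
        mu = base * np.exp2(lfc[:, cell_clusters]) * lib[None, :]
        lam = rng.gamma(shape=config.dispersion, scale=mu / config.dispersion)
        block = rng.poisson(lam)
        blocks.append(sp.csr_matrix(block))
        for ci, k in enumerate(cell_clusters):
            bc = f"{sample}_BC{ci + 1:05d}"
            barcodes.append(bc)
            rows.append(
                {
                    "barcode": bc,
                    "sample": sample,
                    "condition": cond,
                    "cell_type": "major",
                    "true_cluster": clusters[k],
                }
            )

    matrix = sp.hstack(blocks, format="csr")
    counts = CountMatrix(genes=genes, barcodes=barcodes, matrix=matrix)
    cells = pd.DataFrame(rows).set_index("barcode")

    enriched = tuple(
        clusters[k]
        for k in range(len(clusters))
        if proportions["tumor"][k] > proportions["normal"][k] + 1e-12
    )
    truth = GroundTruth(
        true_cluster=cells["true_cluster"].copy(),
        true_markers=true_markers,
        true_batch_genes=tuple(config.batch_genes),
        true_enriched_clusters=enriched,
        log2fc=log2fc_map,
    )
    return counts, cells, truth


def simulate_lr_table(
    n_pairs: int,
    n_complex: int,
    active: set[tuple[str, str, str]],
    genes: list[str],
    clusters: list[str],
    seed: int = 0,
    baseline_boost_log2: float = 2.0,
    active_boost_log2: float = 2.0,
) -> tuple[pd.DataFrame, dict]:
    """Build a ligand-receptor pair table and the expression plan realizing it.

    Pairs are assembled from distinct genes of ``genes``; the first
    ``n_complex`` pairs receive a two-subunit receptor complex. Every
    ligand/receptor gene gets a global ``baseline_boost_log2`` so it is
    detectable (>25% of cells) across clusters; for each active triple
    ``(cluster_a, cluster_b, pair_id)`` the ligand genes get an extra
    ``active_boost_log2`` in cluster A and the receptor genes in cluster B.

    Returns the table (``pair_id``, ``ligand_genes``, ``receptor_genes`` as
    tuples) and a plan ``{"baseline_boost": {...}, "markers": [...]}`` to be
    merged into a :class:`SimulationConfig`.
    """
    if n_complex > n_pairs:
        raise ValueError("n_complex cannot exceed n_pairs")
    rng = np.random.default_rng(seed)
    needed = 2 * n_pairs + n_complex
    if needed > len(genes):
        raise ValueError(f"need {needed} distinct genes, got {len(genes)}")
    pool = list(rng.choice(len(genes), size=needed, replace=False))

    records = []
    for i in range(n_pairs):
        pid = f"LR{i + 1:03d}"
        lig = (genes[pool.pop()],)
        if i < n_complex:
            rec = (genes[pool.pop()], genes[pool.pop()])
        else:
            rec = (genes[pool.pop()],)
        records.append(
            {"pair_id": pid, "ligand_genes": lig, "receptor_genes": rec}
        )
    table = pd.DataFrame(records, columns=["pair_id", "ligand_genes", "receptor_genes"])
    if table["pair_id"].duplicated().any():
        raise ValueError("duplicate pair IDs generated")

    cluster_set = set(clusters)
    pair_ids = set(table["pair_id"])
    boost: dict[str, float] = {}
    markers: list[tuple[str, str, float]] = []
    for _, row in table.iterrows():
        for g in row["ligand_genes"] + row["receptor_genes"]:
            boost[g] = baseline_boost_log2
    by_id = table.set_index("pair_id")
    for ca, cb, pid in sorted(active):
        if ca not in cluster_set or cb not in cluster_set:
            raise ValueError(f"active triple references unknown cluster: {(ca, cb, pid)}")
        if pid not in pair_ids:
            raise ValueError(f"active triple references unknown pair {pid!r}")
        for g in by_id.loc[pid, "ligand_genes"]:
            markers.append((g, ca, active_boost_log2))
        for g in by_id.loc[pid, "receptor_genes"]:
            markers.append((g, cb, active_boost_log2))
    return table, {"baseline_boost": boost, "markers": markers}


def simulate_bulk(
    n_tumor: int,
    n_normal: int,
    signature: list[str],
    effect: float,
    seed: int = 0,
    n_background_genes: int = 100,
    frac_shifted: float = 0.25,
) -> tuple[pd.DataFrame, pd.Series, list[str]]:
    """Simulate a bulk TPM cohort with a signature shifted in some tumors.

    ``effect`` is the log2 shift applied to the signature genes in a random
    ``frac_shifted`` subset of tumor samples. Returns the genes x samples TPM
    table, the per-sample condition labels, and the shifted sample IDs.
    """
    if n_tumor < 4:
        raise ValueError("need at least 4 tumor samples for non-degenerate quartiles")
    if n_normal < 1:
        raise ValueError("need at least 1 normal sample")
    rng = np.random.default_rng(seed)
    genes = list(signature) + [f"BG{i + 1:04d}" for i in range(n_background_genes)]
    tumor_ids = [f"T{i + 1:03d}" for i in range(n_tumor)]
    normal_ids = [f"N{i + 1:03d}" for i in range(n_normal)]
    samples = tumor_ids + normal_ids
    labels = pd.Series(
        ["tumor"] * n_tumor + ["normal"] * n_normal, index=samples, name="condition"
    )
    tpm = rng.lognormal(mean=math.log(10.0), sigma=1.0, size=(len(genes), len(samples)))
    n_shift = max(1, round(frac_shifted * n_tumor)) if effect != 0 else 0
    shifted = sorted(rng.choice(tumor_ids, size=n_shift, replace=False).tolist())
    if shifted:
        cols = [samples.index(s) for s in shifted]
        sig_rows = np.arange(len(signature))
        tpm[np.ix_(sig_rows, cols)] *= 2.0**effect
    bulk = pd.DataFrame(tpm, index=genes, columns=samples)
    return bulk, labels, shifted
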