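"""Synthetic droplet scRNA-seq generator with known ground truth.

Counts follow a two-phase (off/on) transcription process: every gene x cell
entry is either "off" — a small Poisson background standing in for
technical dropout and stray molecules — or "on", with a Poisson rate drawn
around a lognormal gene-level mean and scaled by the cell's sequencing
depth.  The probability of being on increases with the gene's relative
expression level through a logistic link, which reproduces the familiar
dropout-vs-mean relationship of UMI data.  Lognormal rate jitter across
cells produces negative-binomial-like overdispersion.

The generator plants the structure the downstream stages are tested
against: cluster-specific marker genes, neuronal clusters with higher
library sizes than non-neuronal ones, a named mitochondrial gene block
("mt-*") and ribosomal block ("Rps*/Rpl*"), doublets (sums of two cells),
low-quality cells (inflated mitochondrial fraction or collapsed depth),
and, with two conditions, per-cluster differentially expressed genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.special import expit

from .containers import ExpressionMatrix
from . import io as cio

__all__ = ["SimulationConfig", "GroundTruth", "generate_dataset", "write_dataset"]

#: canonical class-marker names so that name-based QC rules are exercised
NEURONAL_MARKERS = ("Snap25", "Syt1", "Slc17a7", "Gad2")
NON_NEURONAL_MARKERS = ("Gja1", "C1qa", "Flt1")


@dataclass
class SimulationConfig:
    """Knobs of the generator; defaults emulate a two-condition mouse
    cortex experiment at desk scale.

    Depths keep the roughly 3.5x neuronal/non-neuronal library-size ratio
    seen in cortical droplet data.  ``phase2_mu``/``phase2_sigma`` set the
    lognormal spread of gene-level "on" expression; the dropout logit
    links a gene's relative level to its probability of being on.
    """

    n_clusters: int = 8
    cells_per_cluster: int = 200
    n_genes: int = 3000
    markers_per_cluster: int = 30
    marker_fold: float = 4.0
    neuronal_clusters: tuple = (0, 1, 2, 3)
    depth_neuronal: float = 13000.0
    depth_non_neuronal: float = 3800.0
    pct_mito_mean: float = 0.03
    doublet_rate: float = 0.01
    lowq_rate: float = 0.05
    n_conditions: int = 2
    de_genes_per_cluster: int = 20
    de_fold: float = 2.0
    phase2_mu: float = 0.0
    phase2_sigma: float = 1.5
    dropout_logit_slope: float = 1.0
    dropout_logit_intercept: float = 2.0
    bg_rate: float = 0.02
    rate_jitter_sigma: float = 0.3
    depth_cv_sigma: float = 0.2
    n_mito: int = 10
    n_ribo: int = 20
    seed: int = 0

    def __post_init__(self):
        for name in ("pct_mito_mean", "doublet_rate", "lowq_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} must lie in [0, 1]")
        if self.marker_fold <= 1 or self.de_fold < 1:
            raise ValueError("marker_fold must be > 1 and de_fold >= 1")
        if min(self.depth_neuronal, self.depth_non_neuronal) <= 0:
            raise ValueError("depths must be positive")
        if self.n_conditions not in (1, 2):
            raise ValueError("n_conditions must be 1 or 2")


@dataclass
class GroundTruth:
    """Planted truth aligned with the emitted matrix.

    ``cells``: barcode, cluster (-1 for doublets), broad_class, condition,
    is_doublet, is_lowq.  ``genes``: marker_of / de_cluster (-1 when not
    planted), de_direction (+1/-1/0), family flags.  ``phase_on``: sparse
    boolean genes x cells on-state indicator.
    """

    cells: pd.DataFrame
    genes: pd.DataFrame
    phase_on: sp.spmatrix = field(repr=False, default=None)


def _gene_names(cfg: SimulationConfig) -> tuple:
    names = [f"mt-{i + 1}" for i in range(cfg.n_mito)]
    for i in range(cfg.n_ribo):
        names.append(f"Rps{i + 1}" if i % 2 == 0 else f"Rpl{i + 1}")
    class_markers = list(NEURONAL_MARKERS) + list(NON_NEURONAL_MARKERS)
    names.extend(class_markers)
    n_special = len(names)
    names.extend(f"Gene{i + 1:05d}" for i in range(cfg.n_genes - n_special))
    return np.array(names, dtype=object), n_special


def generate_dataset(config: SimulationConfig):
    """Draw one dataset; fully reproducible from ``config.seed``.

    Returns ``(ExpressionMatrix, GroundTruth)``.  Raises ``ValueError``
    when the planted marker/DE blocks do not fit into ``n_genes``.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)

    gene_names, n_special = _gene_names(cfg)
    n_generic = cfg.n_genes - n_special
    needed = cfg.n_clusters * (cfg.markers_per_cluster + cfg.de_genes_per_cluster)
    if needed > n_generic:
        raise ValueError(
            f"capacity: {needed} marker/DE genes requested but only "
            f"{n_generic} generic genes available (n_genes={cfg.n_genes})"
        )

    G, K = cfg.n_genes, cfg.n_clusters
    n_cells = K * cfg.cells_per_cluster

    is_mito = np.char.startswith(gene_names.astype(str), "mt-")
    is_ribo = np.array([n.startswith(("Rps", "Rpl")) for n in gene_names])
    neuronal_idx = np.array(
        [np.flatnonzero(gene_names == m)[0] for m in NEURONAL_MARKERS]
    )
    non_neuronal_idx = np.array(
        [np.flatnonzero(gene_names == m)[0] for m in NON_NEURONAL_MARKERS]
    )

    # gene-level relative expression weights
    base_w = np.exp(rng.normal(cfg.phase2_mu, cfg.phase2_sigma, size=G))
    base_w[is_ribo] *= 5.0  # ribosomal genes sit in the high-expression tail
    base_w[neuronal_idx] = np.exp(cfg.phase2_mu + 1.5 * cfg.phase2_sigma)
    base_w[non_neuronal_idx] = np.exp(cfg.phase2_mu + 1.5 * cfg.phase2_sigma)

    # plant disjoint marker and DE blocks among the generic genes
    marker_of = np.full(G, -1, dtype=np.int64)
    de_cluster = np.full(G, -1, dtype=np.int64)
    de_direction = np.zeros(G, dtype=np.int64)
    generic = np.arange(n_special, G)
    cursor = 0
    for k in range(K):
        block = generic[cursor : cursor + cfg.markers_per_cluster]
        marker_of[block] = k
        cursor += cfg.markers_per_cluster
    if cfg.n_conditions == 2:
        for k in range(K):
            block = generic[cursor : cursor + cfg.de_genes_per_cluster]
            de_cluster[block] = k
            half = len(block) // 2
            de_direction[block[:half]] = 1
            de_direction[block[half:]] = -1
            cursor += cfg.de_genes_per_cluster

    # per-cell structure
    cluster = np.repeat(np.arange(K), cfg.cells_per_cluster)
    is_neuronal_cluster = np.isin(np.arange(K), np.asarray(cfg.neuronal_clusters))
    broad = np.where(is_neuronal_cluster[cluster], "neuronal", "non_neuronal")
    if cfg.n_conditions == 2:
        condition = np.tile([0, 1], n_cells // 2 + 1)[:n_cells]
    else:
        condition = np.zeros(n_cells, dtype=int)
    sample = np.array(
        [f"s{c * 2 + (i % 2) + 1}" for i, c in enumerate(condition)], dtype=object
    )

    target_depth = np.where(
        is_neuronal_cluster[cluster], cfg.depth_neuronal, cfg.depth_non_neuronal
    )
    depth = target_depth * np.exp(
        rng.normal(0.0, cfg.depth_cv_sigma, size=n_cells) - cfg.depth_cv_sigma**2 / 2
    )

    # low-quality cells: half get contaminated mito fractions, half collapse
    is_lowq = rng.random(n_cells) < cfg.lowq_rate
    lowq_idx = np.flatnonzero(is_lowq)
    lowq_mito = lowq_idx[: len(lowq_idx) // 2]
    lowq_shallow = lowq_idx[len(lowq_idx) // 2 :]
    depth[lowq_shallow] *= 0.1

    conc = 60.0
    pct_mito = rng.beta(
        cfg.pct_mito_mean * conc, (1 - cfg.pct_mito_mean) * conc, size=n_cells
    )
    pct_mito[lowq_mito] = rng.uniform(0.12, 0.40, size=len(lowq_mito))

    # per-gene x cell weights with planted folds
    W = np.repeat(base_w[:, None], n_cells, axis=1).astype(np.float64)
    for k in range(K):
        cells_k = cluster == k
        mk = marker_of == k
        W[np.ix_(mk, cells_k)] *= cfg.marker_fold
        if cfg.n_conditions == 2 and cfg.de_fold != 1.0:
            dk = de_cluster == k
            treated_k = cells_k & (condition == 1)
            up = dk & (de_direction == 1)
            dn = dk & (de_direction == -1)
            W[np.ix_(up, treated_k)] *= cfg.de_fold
            W[np.ix_(dn, treated_k)] /= cfg.de_fold
    # class markers: essentially restricted to their class
    neu_cells = broad == "neuronal"
    W[np.ix_(neuronal_idx, ~neu_cells)] *= 0.02
    W[np.ix_(neuronal_idx, neu_cells)] *= 20.0
    W[np.ix_(non_neuronal_idx, neu_cells)] *= 0.02
    W[np.ix_(non_neuronal_idx, ~neu_cells)] *= 20.0

    # on/off states: logistic in log relative weight; mito always on
    ref = np.median(np.log(base_w))
    p_on = expit(
        cfg.dropout_logit_intercept + cfg.dropout_logit_slope * (np.log(W) - ref)
    )
    p_on[is_mito, :] = 1.0
    z_on = rng.random((G, n_cells)) < p_on

    # scale the "on" weights so realized non-mito depth tracks the target
    W_eff = W * z_on
    W_eff[is_mito, :] = 0.0
    colsum = W_eff.sum(axis=0)
    colsum[colsum == 0] = 1.0
    lam = W_eff * (depth * (1 - pct_mito) / colsum)
    # mito block: split the mito budget by the block's base weights
    mito_w = base_w[is_mito] / base_w[is_mito].sum()
    lam[is_mito, :] = mito_w[:, None] * (depth * pct_mito)
    lam[~z_on & ~is_mito[:, None]] = cfg.bg_rate
    if cfg.rate_jitter_sigma > 0:
        jitter = np.exp(
            rng.normal(0.0, cfg.rate_jitter_sigma, size=lam.shape)
            - cfg.rate_jitter_sigma**2 / 2
        )
        lam *= jitter

    counts = rng.poisson(lam).astype(np.int32)

    barcodes = np.array([f"CELL{i + 1:05d}" for i in range(n_cells)], dtype=object)

    # doublets: sums of two random same-condition cells, appended
    n_dbl = int(round(cfg.doublet_rate * n_cells))
    dbl_cols, dbl_cond, dbl_sample, dbl_on = [], [], [], []
    for d in range(n_dbl):
        cond = int(rng.integers(cfg.n_conditions))
        pool = np.flatnonzero((condition == cond) & ~is_lowq)
        i, j = rng.choice(pool, size=2, replace=False)
        dbl_cols.append(counts[:, i] + counts[:, j])
        dbl_on.append(z_on[:, i] | z_on[:, j])
        dbl_cond.append(cond)
        dbl_sample.append(sample[i])
    if n_dbl:
        counts = np.concatenate([counts, np.stack(dbl_cols, axis=1)], axis=1)
        z_on = np.concatenate([z_on, np.stack(dbl_on, axis=1)], axis=1)
        barcodes = np.concatenate(
            [barcodes, np.array([f"DBL{d + 1:03d}" for d in range(n_dbl)], dtype=object)]
        )
        cluster = np.concatenate([cluster, np.full(n_dbl, -1)])
        broad = np.concatenate([broad, np.array(["doublet"] * n_dbl)])
        condition = np.concatenate([condition, np.array(dbl_cond)])
        sample = np.concatenate([sample, np.array(dbl_sample, dtype=object)])
        is_lowq = np.concatenate([is_lowq, np.zeros(n_dbl, dtype=bool)])

    cond_label = np.where(condition == 0, "ctrl", "treat")
    cell_meta = pd.DataFrame(
        {"sample": sample, "condition": cond_label},
        index=pd.Index(barcodes, name="barcode"),
    )
    em = ExpressionMatrix(sp.csr_matrix(counts), gene_names, barcodes, cell_meta)

    cells = pd.DataFrame(
        {
            "barcode": barcodes,
            "cluster": cluster,
            "broad_class": broad,
            "condition": cond_label,
            "is_doublet": np.char.startswith(barcodes.astype(str), "DBL"),
            "is_lowq": is_lowq,
        }
    )
    genes = pd.DataFrame(
        {
            "gene": gene_names,
            "marker_of": marker_of,
            "de_cluster": de_cluster,
            "de_direction": de_direction,
            "is_mito": is_mito,
            "is_ribo": is_ribo,
        }
    )
    gt = GroundTruth(cells=cells, genes=genes, phase_on=sp.csr_matrix(z_on))
    return em, gt


def write_dataset(em: ExpressionMatrix, gt: GroundTruth, outdir) -> None:
    """Write the 10x triplet plus ground-truth TSVs."""
    outdir = Path(outdir)
    cio.write_10x_mtx(em, outdir)
    gt.cells.to_csv(outdir / "truth_cells.tsv", sep="\t", index=False)
    gt.genes.to_csv(outdir / "truth_genes.tsv", sep="\t", index=False)
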