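"""Cell and gene quality control, and log-CPM normalization.

Filtering rules, in order: (1) drop cells with strictly more than 10% of
their UMIs from mitochondrial genes; (2) drop suspected doublets — cells
detecting strictly more genes than the 99th percentile of genes-per-cell,
the percentile being computed (linear interpolation) over the cells that
survived the mito filter and frozen; (3) class-specific gene floors —
at least 800 detected genes for non-neuronal cells and 1500 for neuronal
cells, reflecting the higher mRNA content of neurons.  Mitochondrial and
ribosomal gene rows are removed only after the mito fraction has been
computed.  Normalization is counts-per-million followed by ln(1 + x).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, NormalizedMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "QCParams",
    "compute_qc",
    "filter_cells",
    "remove_gene_families",
    "normalize_log_cpm",
    "mito_gene_mask",
    "ribo_gene_mask",
    "score_neuronal_clusters",
]


def mito_gene_mask(gene_ids) -> np.ndarray:
    """Mitochondrial genes by the conventional 'mt-' prefix (any case)."""
    return np.array([str(g).lower().startswith("mt-") for g in gene_ids])


def ribo_gene_mask(gene_ids) -> np.ndarray:
    """Ribosomal protein genes by the Rps*/Rpl* prefix (any case)."""
    return np.array([str(g).lower().startswith(("rps", "rpl")) for g in gene_ids])


@dataclass
class QCParams:
    mito_max: float = 0.10
    doublet_pctile: float = 99.0
    min_genes_non_neuronal: int = 800
    min_genes_neuronal: int = 1500


def compute_qc(matrix: ExpressionMatrix, mito_genes=None) -> pd.DataFrame:
    """Per-cell QC metrics.

    Returns a frame indexed by barcode with ``n_umi``, ``n_genes_detected``,
    ``pct_mito`` (0 by convention for zero-count cells) and ``broad_class``
    (``unknown`` until classes are assigned).  ``mito_genes`` may be a gene
    set or omitted to use the 'mt-' name rule; genes named but absent are
    warned about.
    """
    if mito_genes is None:
        mito_mask = mito_gene_mask(matrix.gene_ids)
    else:
        mito_genes = set(mito_genes)
        missing = mito_genes - set(matrix.gene_ids)
        if missing:
            logger.warning("%d mito genes not in matrix: %s", len(missing),
                           sorted(missing)[:5])
        mito_mask = np.isin(matrix.gene_ids, list(mito_genes))

    n_umi = matrix.depths()
    n_genes = matrix.genes_detected()
    mito_umi = np.asarray(matrix.counts[mito_mask, :].sum(axis=0)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(n_umi > 0, mito_umi / np.maximum(n_umi, 1), 0.0)
    return pd.DataFrame(
        {
            "n_umi": n_umi.astype(np.int64),
            "n_genes_detected": n_genes.astype(np.int64),
            "pct_mito": pct,
            "broad_class": np.array(["unknown"] * matrix.n_cells, dtype=object),
        },
        index=pd.Index(matrix.barcodes, name="barcode"),
    )


def filter_cells(
    matrix: ExpressionMatrix,
    qc: pd.DataFrame,
    params: QCParams = None,
):
    """Apply the three removal rules; returns (filtered matrix, removal log,
    thresholds).

    The removal log has one row per removed cell with the rule that removed
    it (first matching rule in order mito > doublet > gene_floor).  The
    returned thresholds record the frozen doublet percentile cut so a
    second application is a no-op.
    """
    params = params or QCParams()
    if len(qc) != matrix.n_cells:
        raise ValueError("qc table is not aligned with the matrix")

    pct = qc["pct_mito"].to_numpy(float)
    ngen = qc["n_genes_detected"].to_numpy(np.int64)
    broad = qc["broad_class"].to_numpy(object)

    high_mito = pct > params.mito_max  # strictly above the 10% bound
    survivors = ~high_mito
    if survivors.sum() == 0:
        raise ValueError("all cells removed by the mito filter")
    # percentile over cells surviving the mito filter, linear interpolation
    doublet_cut = float(np.percentile(ngen[survivors], params.doublet_pctile))
    doublet = survivors & (ngen > doublet_cut)

    floors = np.where(
        broad == "neuronal", params.min_genes_neuronal, params.min_genes_non_neuronal
    )
    below_floor = survivors & ~doublet & (ngen < floors)

    removed_rule = np.array([""] * matrix.n_cells, dtype=object)
    removed_rule[high_mito] = "high_mito"
    removed_rule[doublet] = "doublet_candidate"
    removed_rule[below_floor] = "below_gene_floor"
    keep = removed_rule == ""
    if keep.sum() == 0:
        raise ValueError("all cells removed by QC filtering")

    log = pd.DataFrame(
        {
            "barcode": matrix.barcodes[~keep],
            "rule": removed_rule[~keep],
            "n_genes_detected": ngen[~keep],
            "pct_mito": pct[~keep],
        }
    )
    thresholds = {
        "mito_max": params.mito_max,
        "doublet_gene_cut": doublet_cut,
        "min_genes_non_neuronal": params.min_genes_non_neuronal,
        "min_genes_neuronal": params.min_genes_neuronal,
    }
    return matrix.subset_cells(keep), log, thresholds


def remove_gene_families(matrix: ExpressionMatrix, families=("mito", "ribo"),
                         extra_genes=None) -> ExpressionMatrix:
    """Drop mitochondrial/ribosomal gene rows (name-rule based) and any
    explicitly listed genes.  Call after :func:`compute_qc`: the mito
    fraction is frozen before removal."""
    drop = np.zeros(matrix.n_genes, dtype=bool)
    if "mito" in families:
        drop |= mito_gene_mask(matrix.gene_ids)
    if "ribo" in families:
        drop |= ribo_gene_mask(matrix.gene_ids)
    if extra_genes:
        drop |= np.isin(matrix.gene_ids, list(extra_genes))
    if not drop.any():
        return matrix
    return matrix.subset_genes(~drop)


def normalize_log_cpm(matrix: ExpressionMatrix) -> NormalizedMatrix:
    """ln(1 + CPM) per entry: x = ln(1 + 1e6 * c / depth)."""
    depths = matrix.depths()
    zero = np.flatnonzero(depths == 0)
    if len(zero):
        raise ValueError(
            f"zero-depth cells cannot be normalized: {list(matrix.barcodes[zero][:5])}"
        )
    m = matrix.counts.tocsc().astype(np.float64)
    # scale columns to CPM, then log1p on the sparse data
    scale = 1e6 / depths
    m = m.multiply(scale[None, :]).tocsr()
    m.data = np.log1p(m.data)
    return NormalizedMatrix(m, matrix.gene_ids, matrix.barcodes, matrix.cell_meta)


def score_neuronal_clusters(
    norm: NormalizedMatrix, labels: np.ndarray, neuronal_markers
) -> np.ndarray:
    """Decide which clusters are neuronal from marker expression.

    Scores each cluster by the mean log-CPM of the neuronal marker panel
    and splits the scores with 1-d 2-means; the high-score group is called
    neuronal.  Returns a boolean per-cluster array.
    """
    present = np.isin(norm.gene_ids, list(neuronal_markers))
    if not present.any():
        raise ValueError("none of the neuronal markers are in the gene universe")
    sub = np.asarray(norm.matrix[present, :].todense())
    k = int(labels.max()) + 1
    scores = np.array([sub[:, labels == c].mean() for c in range(k)])
    if len(scores) == 1:
        return np.array([True])
    # 1-d 2-means by threshold search (deterministic)
    order = np.sort(scores)
    best_cut, best_ss = None, np.inf
    for i in range(1, len(order)):
        lo, hi = order[:i], order[i:]
        ss = ((lo - lo.mean()) ** 2).sum() + ((hi - hi.mean()) ** 2).sum()
        if ss < best_ss:
            best_ss, best_cut = ss, (order[i - 1] + order[i]) / 2
    return scores > best_cut
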