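"""Core in-memory containers shared across the pipeline.

The pipeline operates on sparse UMI count matrices in genes x cells
orientation (the native orientation of the 10x MatrixMarket layout),
with per-cell metadata carried alongside as a :class:`pandas.DataFrame`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "ExpressionMatrix",
    "NormalizedMatrix",
    "GWASCatalog",
    "ClusterAssignment",
    "EmbeddingSpace",
    "SNNGraph",
    "SimilarityMap",
]


def _as_csr(m) -> sp.csr_matrix:
    if sp.issparse(m):
        return m.tocsr()
    return sp.csr_matrix(np.asarray(m))


@dataclass
class ExpressionMatrix:
    """Sparse genes x cells UMI count matrix with identifiers and cell metadata.

    Parameters
    ----------
    counts : scipy.sparse matrix, shape (n_genes, n_cells)
        Non-negative molecule counts.  Integral for raw data; depth
        rescaling produces real-valued expected counts, allowed when
        ``integral=False``.
    gene_ids : array of str
        Unique gene identifiers (duplicates must be resolved upstream).
    barcodes : array of str
        Unique cell barcodes.
    cell_meta : pandas.DataFrame, optional
        Per-cell table (sample id, condition label, timepoint, ...),
        indexed like ``barcodes``.
    """

    counts: sp.spmatrix
    gene_ids: np.ndarray
    barcodes: np.ndarray
    cell_meta: pd.DataFrame = field(default=None)
    integral: bool = True

    def __post_init__(self):
        self.counts = _as_csr(self.counts)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.barcodes = np.asarray(self.barcodes, dtype=object)
        if self.counts.shape[0] != len(self.gene_ids):
            raise ValueError(
                f"matrix has {self.counts.shape[0]} rows but {len(self.gene_ids)} gene ids"
            )
        if self.counts.shape[1] != len(self.barcodes):
            raise ValueError(
                f"matrix has {self.counts.shape[1]} columns but {len(self.barcodes)} barcodes"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene_ids are not unique")
        if len(set(self.barcodes)) != len(self.barcodes):
            raise ValueError("barcodes are not unique")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("counts must be non-negative")
        if self.integral and self.counts.nnz:
            if not np.allclose(self.counts.data, np.round(self.counts.data)):
                raise ValueError("counts must be integral UMI counts")
        if self.cell_meta is None:
            self.cell_meta = pd.DataFrame(index=pd.Index(self.barcodes, name="barcode"))
        elif len(self.cell_meta) != len(self.barcodes):
            raise ValueError("cell_meta length does not match barcodes")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def depths(self) -> np.ndarray:
        """Total UMI per cell."""
        return np.asarray(self.counts.sum(axis=0)).ravel()

    def genes_detected(self) -> np.ndarray:
        """Number of genes with at least one count, per cell."""
        return np.asarray((self.counts > 0).sum(axis=0)).ravel()

    def subset_cells(self, mask_or_idx) -> "ExpressionMatrix":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return replace(
            self,
            counts=self.counts[:, idx],
            barcodes=self.barcodes[idx],
            cell_meta=self.cell_meta.iloc[idx].copy(),
        )

    def subset_genes(self, mask_or_idx) -> "ExpressionMatrix":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return replace(self, counts=self.counts[idx, :], gene_ids=self.gene_ids[idx])


@dataclass
class NormalizedMatrix:
    """Genes x cells matrix of ln(1 + CPM) values.

    Satisfies, per cell, ``sum_g(exp(x) - 1) == 1e6`` up to floating error.
    """

    matrix: sp.spmatrix
    gene_ids: np.ndarray
    barcodes: np.ndarray
    cell_meta: pd.DataFrame = field(default=None)

    def __post_init__(self):
        self.matrix = _as_csr(self.matrix)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.barcodes = np.asarray(self.barcodes, dtype=object)
        if self.cell_meta is None:
            self.cell_meta = pd.DataFrame(index=pd.Index(self.barcodes, name="barcode"))

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_cells(self) -> int:
        return self.matrix.shape[1]

    def dense(self) -> np.ndarray:
        return np.asarray(self.matrix.todense())

    def subset_cells(self, mask_or_idx) -> "NormalizedMatrix":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return NormalizedMatrix(
            self.matrix[:, idx], self.gene_ids, self.barcodes[idx],
            self.cell_meta.iloc[idx].copy(),
        )

    def subset_genes(self, mask_or_idx) -> "NormalizedMatrix":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return NormalizedMatrix(
            self.matrix[idx, :], self.gene_ids[idx], self.barcodes, self.cell_meta
        )


@dataclass
class GWASCatalog:
    """Gene-disease associations restricted to exonic variants.

    ``records`` has columns ``gene``, ``disease``, ``functional_class``; the
    (gene, disease) pairs are unique after filtering.
    """

    records: pd.DataFrame

    def __post_init__(self):
        required = {"gene", "disease", "functional_class"}
        missing = required - set(self.records.columns)
        if missing:
            raise ValueError(f"catalog records missing columns: {sorted(missing)}")

    def genes_for(self, disease: str) -> list:
        sel = self.records[self.records["disease"] == disease]
        return sorted(set(sel["gene"]))

    @property
    def diseases(self) -> list:
        return sorted(set(self.records["disease"]))

    def __len__(self):
        return len(self.records)


@dataclass
class ClusterAssignment:
    """Per-cell cluster labels at a named resolution level.

    Labels are relabelled to the contiguous range 0..K-1 in decreasing
    cluster-size order (ties broken by first occurrence), so the
    assignment is invariant to permutations of the input labelling.
    """

    labels: np.ndarray
    level: str = "broad"
    resolution: float = None

    def __post_init__(self):
        self.labels = canonical_labels(np.asarray(self.labels))

    @property
    def n_clusters(self) -> int:
        return len(np.unique(self.labels))

    def sizes(self) -> np.ndarray:
        return np.bincount(self.labels)


def canonical_labels(labels: np.ndarray) -> np.ndarray:
    """Map arbitrary labels onto 0..K-1, largest cluster first."""
    uniq, first_pos = np.unique(labels, return_index=True)
    counts = np.array([(labels == u).sum() for u in uniq])
    order = np.lexsort((first_pos, -counts))
    mapping = {uniq[o]: rank for rank, o in enumerate(order)}
    return np.array([mapping[v] for v in labels], dtype=np.int64)


@dataclass
class EmbeddingSpace:
    """Aligned low-dimensional coordinates for one or two datasets.

    ``coords`` stacks dataset A then dataset B cells (dataset membership in
    ``dataset``).  ``scores`` holds the per-vector alignment quality
    (biweight midcorrelation between pre- and post-alignment coordinates);
    ``mask`` selects vectors with score at or above the threshold.
    ``gene_loadings`` maps genes onto vectors for feature selection.
    """

    coords: np.ndarray
    dataset: np.ndarray
    scores: np.ndarray
    mask: np.ndarray
    gene_loadings: np.ndarray = None
    gene_ids: np.ndarray = None

    @property
    def n_vectors(self) -> int:
        return self.coords.shape[1]

    def selected(self, n_first: int = None) -> np.ndarray:
        """Coordinates restricted to selected vectors (optionally the first n)."""
        cols = np.flatnonzero(self.mask)
        if n_first is not None:
            cols = cols[:n_first]
        return self.coords[:, cols]


@dataclass
class SNNGraph:
    """Shared-nearest-neighbour graph: symmetric Jaccard weights in [0, 1]."""

    weights: sp.spmatrix
    k: int

    def __post_init__(self):
        self.weights = self.weights.tocsr()

    @property
    def n_cells(self) -> int:
        return self.weights.shape[0]


@dataclass
class SimilarityMap:
    """Cluster x cluster correspondence between two datasets.

    ``scores`` is a (K_A, K_B) matrix on the 0-100 scale.  ``groups`` maps
    each cluster ("A:3", "B:1", ...) to a block id obtained by
    single-linkage over pairs scoring at or above the threshold;
    ``unique_a`` / ``unique_b`` flag clusters whose best cross-dataset
    score falls below it.
    """

    scores: np.ndarray
    groups: dict
    unique_a: np.ndarray
    unique_b: np.ndarray
    threshold: float = 90.0
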