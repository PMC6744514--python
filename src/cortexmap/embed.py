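"""Variable-gene selection, CCA alignment of two datasets, SNN graph
clustering, and iterative cluster merge validation.

The alignment co-embeds two batches by singular value decomposition of the
cross-product of their gene-standardized expression matrices (canonical
correlation vectors), then harmonizes each vector's two coordinate
distributions by rank-quantile matching onto their average quantile
function.  A vector's alignment quality is the biweight midcorrelation
between its pre- and post-alignment coordinates (both datasets pooled);
vectors scoring >= 0.15 are retained.

Clusters come from Louvain modularity on a shared-nearest-neighbour graph
(Jaccard overlap of k-NN sets).  Merge validation then iteratively fuses
cluster pairs that are both highly connected in the SNN graph (mean
inter-cluster edge weight above the 0.90 quantile of all pairwise
connectivities) and not separable by a linear SVM (accuracy < 0.90 with
the top 100 genes from each of the first 5 PCs as features).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import scipy.sparse as sp
from sklearn.base import BaseEstimator
from sklearn.decomposition import PCA
from sklearn.metrics import balanced_accuracy_score
from sklearn.model_selection import (
    LeaveOneOut,
    StratifiedKFold,
    cross_val_predict,
    cross_val_score,
)
from sklearn.neighbors import NearestNeighbors
from sklearn.svm import LinearSVC

from .containers import ClusterAssignment, EmbeddingSpace, NormalizedMatrix, SNNGraph

logger = logging.getLogger(__name__)

__all__ = [
    "select_variable_genes",
    "bicor",
    "CCAAligner",
    "cca_align",
    "pca_embed",
    "build_snn",
    "build_snn_and_cluster",
    "MergeValidator",
    "MergeDecision",
    "validate_and_merge",
]


def _dispersion_z(dense: np.ndarray, n_bins: int) -> np.ndarray:
    """Within-bin z-score of the log variance/mean dispersion.

    Mean and dispersion are computed on the count (CPM) scale after
    undoing the log transform; genes are binned by log mean expression
    (equal-width bins; sparse bins merged rightward).
    """
    cpm = np.expm1(dense)
    mean = cpm.mean(axis=1)
    var = cpm.var(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        disp = np.log(np.maximum(np.where(mean > 0, var / np.maximum(mean, 1e-300), 0.0), 1e-12))
    logmean = np.log1p(mean)
    edges = np.linspace(logmean.min(), logmean.max() + 1e-12, n_bins + 1)
    bins = np.clip(np.digitize(logmean, edges) - 1, 0, n_bins - 1)
    # merge bins holding < 2 genes into their right neighbour
    for b in range(n_bins - 1):
        if (bins == b).sum() < 2:
            if (bins == b).sum():
                logger.debug("merging sparse dispersion bin %d rightward", b)
            bins[bins == b] = b + 1
    if (bins == n_bins - 1).sum() < 2:
        occupied = np.unique(bins[bins < n_bins - 1])
        if len(occupied):
            bins[bins == n_bins - 1] = occupied[-1]
    z = np.zeros_like(disp)
    for b in np.unique(bins):
        sel = bins == b
        sd = disp[sel].std()
        z[sel] = (disp[sel] - disp[sel].mean()) / sd if sd > 0 else 0.0
    return z


def select_variable_genes(
    normA: NormalizedMatrix,
    normB: NormalizedMatrix = None,
    n_top: int = 2000,
    n_bins: int = 20,
    z_cutoff: float = 2.0,
    min_genes: int = 200,
) -> np.ndarray:
    """Highly variable genes; with two datasets, the intersection of each
    dataset's top-``n_top`` list.

    Per dataset: genes are binned by mean expression, dispersion
    (variance/mean) is z-scored within bin, genes with z above the cutoff
    are ranked by z and the top ``n_top`` kept.  When the cutoff would
    leave fewer than ``min_genes`` genes (small gene universes), the top
    ``min_genes`` by z are used instead, logged.
    """

    def _top(norm):
        z = _dispersion_z(norm.dense(), n_bins)
        order = np.argsort(-z, kind="stable")
        top = [norm.gene_ids[i] for i in order if z[i] > z_cutoff][:n_top]
        if len(top) < min_genes:
            logger.warning(
                "only %d genes pass dispersion z > %.1f; falling back to the "
                "top %d by z", len(top), z_cutoff, min_genes,
            )
            top = [norm.gene_ids[i] for i in order[: min(min_genes, len(order))]]
        return top

    topA = _top(normA)
    if normB is None:
        return np.array(topA, dtype=object)
    in_b = set(_top(normB))
    return np.array([g for g in topA if g in in_b], dtype=object)


def bicor(x, y, c: float = 9.0) -> float:
    """Biweight midcorrelation: a robust correlation built on Tukey
    biweights around the median (weighting constant ``c``).  Falls back to
    the Pearson correlation when a median absolute deviation is zero."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)

    def _weights(v):
        med = np.median(v)
        mad = np.median(np.abs(v - med))
        if mad == 0:
            return None, None
        u = (v - med) / (c * mad)
        w = np.where(np.abs(u) < 1, (1 - u**2) ** 2, 0.0)
        return (v - med) * w, med

    ax, _ = _weights(x)
    ay, _ = _weights(y)
    if ax is None or ay is None:
        sx, sy = x.std(), y.std()
        if sx == 0 or sy == 0:
            return 0.0
        return float(np.corrcoef(x, y)[0, 1])
    denom = np.sqrt((ax**2).sum() * (ay**2).sum())
    if denom == 0:
        return 0.0
    return float((ax * ay).sum() / denom)


def _standardize_genes(dense: np.ndarray) -> np.ndarray:
    mu = dense.mean(axis=1, keepdims=True)
    sd = dense.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (dense - mu) / sd


def _quantile_align(a: np.ndarray, b: np.ndarray):
    """Match both coordinate vectors onto the average of their quantile
    functions.  Exact identity when the two vectors are identical."""
    na, nb = len(a), len(b)
    sa, sb = np.sort(a), np.sort(b)
    pa = (np.arange(na) + 0.5) / na
    pb = (np.arange(nb) + 0.5) / nb
    qb_at_pa = np.interp(pa, pb, sb)
    qa_at_pb = np.interp(pb, pa, sa)
    ref_a = 0.5 * (sa + qb_at_pa)
    ref_b = 0.5 * (sb + qa_at_pb)
    out_a = np.empty(na)
    out_a[np.argsort(a, kind="stable")] = ref_a
    out_b = np.empty(nb)
    out_b[np.argsort(b, kind="stable")] = ref_b
    return out_a, out_b


class CCAAligner(BaseEstimator):
    """Co-embed two normalized datasets in aligned canonical space.

    Parameters
    ----------
    n_cc : int
        Number of canonical vectors to compute.
    bicor_threshold : float
        Minimum biweight midcorrelation between pre- and post-alignment
        coordinates for a vector to be selected (default 0.15).

    Attributes
    ----------
    embedding_ : EmbeddingSpace
        Aligned pooled coordinates (dataset A cells first), per-vector
        scores, selection mask and gene loadings.
    """

    def __init__(self, n_cc: int = 20, bicor_threshold: float = 0.15):
        self.n_cc = n_cc
        self.bicor_threshold = bicor_threshold

    def fit(self, normA: NormalizedMatrix, normB: NormalizedMatrix, genes):
        genes = np.asarray(genes, dtype=object)
        ia = {g: i for i, g in enumerate(normA.gene_ids)}
        ib = {g: i for i, g in enumerate(normB.gene_ids)}
        missing = [g for g in genes if g not in ia or g not in ib]
        if missing:
            raise ValueError(f"genes absent from one dataset: {missing[:5]}")
        A = np.asarray(normA.matrix[[ia[g] for g in genes], :].todense())
        B = np.asarray(normB.matrix[[ib[g] for g in genes], :].todense())
        nA, nB = A.shape[1], B.shape[1]
        n_cc = min(self.n_cc, nA - 1, nB - 1)
        if n_cc < self.n_cc:
            logger.warning("reducing n_cc to %d (too few cells)", n_cc)

        Za = _standardize_genes(A).T  # cells x genes
        Zb = _standardize_genes(B).T
        K = Za @ Zb.T / Za.shape[1]
        U, s, Vt = np.linalg.svd(K, full_matrices=False)
        rank = int((s > s[0] * 1e-10).sum()) if len(s) else 0
        if rank < n_cc:
            logger.warning("cross-product rank %d < requested %d vectors", rank, n_cc)
            n_cc = max(rank, 1)
        U, Vt = U[:, :n_cc], Vt[:n_cc, :]
        # deterministic sign: largest-magnitude element of each U column positive
        for j in range(n_cc):
            i = np.argmax(np.abs(U[:, j]))
            if U[i, j] < 0:
                U[:, j] = -U[:, j]
                Vt[j, :] = -Vt[j, :]
        coords_a, coords_b = U, Vt.T

        aligned = np.empty((nA + nB, n_cc))
        scores = np.empty(n_cc)
        for j in range(n_cc):
            out_a, out_b = _quantile_align(coords_a[:, j], coords_b[:, j])
            aligned[:nA, j] = out_a
            aligned[nA:, j] = out_b
            pre = np.concatenate([coords_a[:, j], coords_b[:, j]])
            post = aligned[:, j]
            scores[j] = 1.0 if np.array_equal(pre, post) else bicor(pre, post)
        mask = scores >= self.bicor_threshold
        if not mask.any():
            logger.warning("no vector passed bicor >= %.2f; keeping the best one",
                           self.bicor_threshold)
            mask[np.argmax(scores)] = True

        Z_pool = np.vstack([Za, Zb])  # cells x genes
        loadings = Z_pool.T @ aligned
        norms = np.linalg.norm(loadings, axis=0)
        norms[norms == 0] = 1.0
        loadings = loadings / norms

        self.embedding_ = EmbeddingSpace(
            coords=aligned,
            dataset=np.concatenate([np.zeros(nA, int), np.ones(nB, int)]),
            scores=scores,
            mask=mask,
            gene_loadings=loadings,
            gene_ids=genes,
        )
        return self


def cca_align(normA, normB, genes, n_cc: int = 20,
              bicor_threshold: float = 0.15) -> EmbeddingSpace:
    """Functional wrapper over :class:`CCAAligner`."""
    return CCAAligner(n_cc=n_cc, bicor_threshold=bicor_threshold).fit(
        normA, normB, genes
    ).embedding_


def pca_embed(norm: NormalizedMatrix, n_pcs: int = 20,
              genes=None, seed: int = 0) -> EmbeddingSpace:
    """Single-dataset PCA embedding with the same interface as the aligned
    space (all vectors selected, score 1)."""
    if genes is not None:
        idx = {g: i for i, g in enumerate(norm.gene_ids)}
        rows = [idx[g] for g in genes if g in idx]
        dense = np.asarray(norm.matrix[rows, :].todense())
        gene_ids = np.asarray([g for g in genes if g in idx], dtype=object)
    else:
        dense = norm.dense()
        gene_ids = norm.gene_ids
    Z = _standardize_genes(dense).T
    n_pcs = min(n_pcs, Z.shape[0] - 1, Z.shape[1])
    pca = PCA(n_components=n_pcs, svd_solver="randomized", random_state=seed)
    coords = pca.fit_transform(Z)
    return EmbeddingSpace(
        coords=coords,
        dataset=np.zeros(Z.shape[0], int),
        scores=np.ones(n_pcs),
        mask=np.ones(n_pcs, bool),
        gene_loadings=pca.components_.T,
        gene_ids=gene_ids,
    )


def build_snn(coords: np.ndarray, k: int = 20) -> SNNGraph:
    """Shared-nearest-neighbour graph: Jaccard overlap of k-NN sets
    (self included in each set), Euclidean metric, zero diagonal."""
    n = coords.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of cells ({n})")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(coords)
    _, idx = nn.kneighbors(coords)
    rows = np.repeat(np.arange(n), k + 1)
    adj = sp.csr_matrix(
        (np.ones(n * (k + 1)), (rows, idx.ravel())), shape=(n, n)
    )
    shared = (adj @ adj.T).tocoo()
    union = 2 * (k + 1) - shared.data
    jac = shared.data / union
    w = sp.csr_matrix((jac, (shared.row, shared.col)), shape=(n, n))
    w.setdiag(0.0)
    w.eliminate_zeros()
    return SNNGraph(weights=w, k=k)


def _louvain(snn: SNNGraph, resolution: float, seed: int) -> np.ndarray:
    g = nx.from_scipy_sparse_array(snn.weights)
    comms = nx.community.louvain_communities(
        g, weight="weight", resolution=resolution, seed=seed
    )
    labels = np.empty(snn.n_cells, dtype=np.int64)
    for c, members in enumerate(comms):
        labels[list(members)] = c
    return labels


def build_snn_and_cluster(
    embedding: EmbeddingSpace,
    k: int = 20,
    resolution: float = 1.0,
    n_vectors: int = None,
    level: str = "broad",
    seed: int = 0,
):
    """k-NN/SNN graph in the selected aligned space and Louvain clustering
    at the given resolution.  Returns (SNNGraph, ClusterAssignment)."""
    coords = embedding.selected(n_vectors)
    if coords.shape[1] == 0:
        raise ValueError("embedding mask selects no vectors")
    snn = build_snn(coords, k=k)
    labels = _louvain(snn, resolution, seed)
    return snn, ClusterAssignment(labels, level=level, resolution=resolution)


@dataclass
class MergeDecision:
    cluster_a: int
    cluster_b: int
    connectivity: float
    threshold: float
    svm_accuracy: float
    merged: bool
    iteration: int


class MergeValidator(BaseEstimator):
    """Iteratively merge cluster pairs that are SNN-connected but not
    linearly separable.

    A pair is a merge candidate when its mean inter-cluster SNN edge weight
    exceeds the ``conn_pctile`` quantile of all current pairwise
    connectivities; candidates are examined in decreasing connectivity
    (ties by pair order) and a pair is merged when a linear SVM, trained on
    the union of the top ``n_genes`` genes by absolute loading from each of
    the first ``n_pcs`` PCs of the pair's submatrix, separates the two
    clusters with cross-validated accuracy below ``svm_acc``.  The loop
    repeats until no candidate merges; at most K-1 merges can occur.

    Attributes
    ----------
    labels_ : array
        Final contiguous labels.
    decisions_ : list of MergeDecision
        Audit trail of every pair examined.
    """

    def __init__(self, conn_pctile: float = 0.90, svm_acc: float = 0.90,
                 n_genes: int = 100, n_pcs: int = 5, cv: int = 5,
                 C: float = 1.0, seed: int = 0):
        self.conn_pctile = conn_pctile
        self.svm_acc = svm_acc
        self.n_genes = n_genes
        self.n_pcs = n_pcs
        self.cv = cv
        self.C = C
        self.seed = seed

    # -- helpers -------------------------------------------------------
    def _connectivity(self, W: sp.spmatrix, labels: np.ndarray):
        ks = np.unique(labels)
        M = sp.csr_matrix(
            (np.ones(len(labels)), (np.arange(len(labels)),
                                    np.searchsorted(ks, labels))),
            shape=(len(labels), len(ks)),
        )
        S = np.asarray((M.T @ W @ M).todense())
        sizes = np.array([(labels == k).sum() for k in ks])
        conn = S / np.outer(sizes, sizes)
        return ks, conn

    def _pair_accuracy(self, dense: np.ndarray, labels: np.ndarray,
                       a: int, b: int) -> float:
        sel = (labels == a) | (labels == b)
        X = dense[:, sel].T  # cells x genes
        y = (labels[sel] == b).astype(int)
        n_pcs = min(self.n_pcs, X.shape[0] - 1, X.shape[1])
        pca = PCA(n_components=n_pcs, svd_solver="randomized",
                  random_state=self.seed)
        pca.fit(X - X.mean(axis=0, keepdims=True))
        feat = set()
        for comp in pca.components_:
            feat.update(np.argsort(-np.abs(comp), kind="stable")[: self.n_genes])
        Xf = X[:, sorted(feat)]
        # balanced accuracy: with unequal cluster sizes the plain accuracy
        # of even a chance-level classifier approaches the majority-class
        # fraction, which would block every micro-cluster merge
        clf = LinearSVC(C=self.C, dual="auto", max_iter=5000,
                        class_weight="balanced", random_state=self.seed)
        min_class = min((y == 0).sum(), (y == 1).sum())
        if min_class < 2 * self.cv:
            pred = cross_val_predict(clf, Xf, y, cv=LeaveOneOut())
            return float(balanced_accuracy_score(y, pred))
        splitter = StratifiedKFold(self.cv, shuffle=True,
                                   random_state=self.seed)
        scores = cross_val_score(clf, Xf, y, cv=splitter,
                                 scoring="balanced_accuracy")
        return float(scores.mean())

    # -- main ----------------------------------------------------------
    def fit(self, norm: NormalizedMatrix, assignment: ClusterAssignment,
            snn: SNNGraph):
        labels = assignment.labels.copy()
        W = snn.weights
        dense = norm.dense()
        decisions = []
        iteration = 0

        # fold singletons into their best-connected neighbour first
        while True:
            ks, conn = self._connectivity(W, labels)
            sizes = np.array([(labels == k).sum() for k in ks])
            single = np.flatnonzero(sizes == 1)
            if len(single) == 0 or len(ks) < 2:
                break
            i = single[0]
            np.fill_diagonal(conn, -np.inf)
            j = int(np.argmax(conn[i]))
            logger.info("merging singleton cluster %d into %d", ks[i], ks[j])
            decisions.append(MergeDecision(int(ks[j]), int(ks[i]),
                                           float(conn[i, j]), np.nan, np.nan,
                                           True, iteration))
            labels[labels == ks[i]] = ks[j]

        while len(np.unique(labels)) >= 2:
            ks, conn = self._connectivity(W, labels)
            iu, ju = np.triu_indices(len(ks), 1)
            pair_conn = conn[iu, ju]
            threshold = float(np.quantile(pair_conn, self.conn_pctile))
            cand = np.flatnonzero(pair_conn > threshold)
            if len(cand) == 0:
                # few clusters: the quantile equals the max; still examine
                # the best-connected pair so the loop can terminate naturally
                cand = np.flatnonzero(pair_conn == pair_conn.max())
            order = sorted(cand, key=lambda c: (-pair_conn[c], iu[c], ju[c]))
            merged = False
            for c in order:
                a, b = int(ks[iu[c]]), int(ks[ju[c]])
                acc = self._pair_accuracy(dense, labels, a, b)
                do_merge = acc < self.svm_acc
                decisions.append(MergeDecision(a, b, float(pair_conn[c]),
                                               threshold, acc, do_merge,
                                               iteration))
                if do_merge:
                    labels[labels == b] = a
                    merged = True
                    break
            iteration += 1
            if not merged:
                break

        self.decisions_ = decisions
        self.assignment_ = ClusterAssignment(
            labels, level=assignment.level, resolution=assignment.resolution
        )
        self.labels_ = self.assignment_.labels
        return self


def validate_and_merge(norm, assignment, snn, conn_pctile: float = 0.90,
                       svm_acc: float = 0.90, n_genes: int = 100,
                       n_pcs: int = 5, seed: int = 0):
    """Functional wrapper over :class:`MergeValidator`; returns the merged
    assignment and the decision audit list."""
    mv = MergeValidator(conn_pctile=conn_pctile, svm_acc=svm_acc,
                        n_genes=n_genes, n_pcs=n_pcs, seed=seed)
    mv.fit(norm, assignment, snn)
    return mv.assignment_, mv.decisions_
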