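"""Cluster correspondence between two datasets and label transfer.

Correspondence uses neighbor voting in the aligned canonical space: votes
seeded from one dataset's cluster memberships are propagated one step over
the row-normalized cell-similarity graph, and a target cluster in the
other dataset is scored by the AUROC of the votes its cells receive
(scaled 0-100, symmetrized over both directions).  Pairs scoring >= 90
are grouped by single linkage into blocks; clusters whose best
cross-dataset score stays below 90 are flagged unique.

Label transfer assigns reference cluster identities to query cells by
bootstrapped Spearman correlation: a CC-loading-derived gene set is
subsampled (80% without replacement) in each of 100 bootstraps, query
cells are correlated with reference cluster centroids, and a cell is
assigned to the cluster winning more than half of the bootstraps.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import rankdata
from sklearn.base import BaseEstimator
from sklearn.metrics import roc_auc_score

from .containers import (
    ClusterAssignment,
    EmbeddingSpace,
    NormalizedMatrix,
    SimilarityMap,
)
from .embed import build_snn

logger = logging.getLogger(__name__)

__all__ = [
    "neighbor_voting_similarity",
    "BootstrapLabelTransfer",
    "bootstrap_label_transfer",
]


def _voting_scores(W_norm: sp.spmatrix, seed_labels: np.ndarray,
                   seed_mask: np.ndarray, target_labels: np.ndarray,
                   target_mask: np.ndarray, n_seed: int, n_target: int):
    """One voting pass: returns an (n_seed_clusters, n_target_clusters)
    AUROC matrix scaled to 0-100."""
    n = W_norm.shape[0]
    votes = np.zeros((n, n_seed))
    seed_idx = np.flatnonzero(seed_mask)
    votes[seed_idx, seed_labels[seed_idx]] = 1.0
    received = np.asarray(W_norm @ votes)  # n_cells x n_seed_clusters
    tgt_idx = np.flatnonzero(target_mask)
    out = np.full((n_seed, n_target), np.nan)
    for sc in range(n_seed):
        ranking = received[tgt_idx, sc]
        for tc in range(n_target):
            truth = (target_labels[tgt_idx] == tc).astype(int)
            if truth.sum() == 0 or truth.sum() == len(truth):
                out[sc, tc] = 100.0 if truth.all() else np.nan
                continue
            out[sc, tc] = 100.0 * roc_auc_score(truth, ranking)
    return out


def neighbor_voting_similarity(
    embedding: EmbeddingSpace,
    labels_a: np.ndarray,
    labels_b: np.ndarray,
    k: int = 20,
    n_cc: int = 20,
    threshold: float = 90.0,
) -> SimilarityMap:
    """Neighbor-voting cluster similarity over the pooled aligned space.

    ``labels_a`` / ``labels_b`` give cluster labels for the cells of
    dataset A and B in the order they appear in ``embedding``.  Scores are
    the average of the A->B and B->A voting AUROCs, on a 0-100 scale.
    """
    labels_a = np.asarray(labels_a).astype(int)
    labels_b = np.asarray(labels_b).astype(int)
    is_a = embedding.dataset == 0
    if is_a.sum() != len(labels_a) or (~is_a).sum() != len(labels_b):
        raise ValueError("labels not aligned with the embedding's datasets")
    coords = embedding.selected(n_cc)
    eff_k = min(k, coords.shape[0] - 1)
    if eff_k < k:
        logger.warning("reducing k to %d for the voting graph", eff_k)
    snn = build_snn(coords, k=eff_k)
    W = snn.weights
    rowsum = np.asarray(W.sum(axis=1)).ravel()
    rowsum[rowsum == 0] = 1.0
    W_norm = sp.diags(1.0 / rowsum) @ W

    labels_full = np.empty(coords.shape[0], dtype=int)
    labels_full[is_a] = labels_a
    labels_full[~is_a] = labels_b
    ka, kb = labels_a.max() + 1, labels_b.max() + 1

    ab = _voting_scores(W_norm, labels_full, is_a, labels_full, ~is_a, ka, kb)
    ba = _voting_scores(W_norm, labels_full, ~is_a, labels_full, is_a, kb, ka)
    scores = np.nanmean(np.stack([ab, ba.T]), axis=0)

    # single-linkage blocks over pairs at or above the threshold
    n_nodes = ka + kb
    parent = list(range(n_nodes))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(ka):
        for j in range(kb):
            if scores[i, j] >= threshold:
                ri, rj = find(i), find(ka + j)
                if ri != rj:
                    parent[rj] = ri
    roots = {}
    groups = {}
    for node in range(n_nodes):
        r = find(node)
        gid = roots.setdefault(r, len(roots))
        name = f"A:{node}" if node < ka else f"B:{node - ka}"
        groups[name] = gid

    best_a = np.nanmax(scores, axis=1)
    best_b = np.nanmax(scores, axis=0)
    return SimilarityMap(
        scores=scores,
        groups=groups,
        unique_a=best_a < threshold,
        unique_b=best_b < threshold,
        threshold=threshold,
    )


def _spearman_matrix(Q: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Spearman correlation of every query column of Q (genes x cells)
    against every centroid column of C (genes x clusters)."""
    rq = np.apply_along_axis(rankdata, 0, Q)
    rc = np.apply_along_axis(rankdata, 0, C)
    rq = rq - rq.mean(axis=0, keepdims=True)
    rc = rc - rc.mean(axis=0, keepdims=True)
    nq = np.linalg.norm(rq, axis=0)
    nc = np.linalg.norm(rc, axis=0)
    nq[nq == 0] = np.nan  # constant query columns abstain
    nc[nc == 0] = np.nan
    return (rq.T @ rc) / np.outer(nq, nc)


class BootstrapLabelTransfer(BaseEstimator):
    """Transfer reference cluster labels to query cells by bootstrapped
    Spearman correlation against cluster centroids.

    Parameters
    ----------
    n_boot : int
        Number of bootstrap rounds (default 100).
    gene_frac : float
        Fraction of the CC-derived gene set sampled without replacement
        per round (default 0.8).
    top_genes_per_cc, n_cc : int
        The gene set is the union over the first ``n_cc`` canonical
        vectors of the ``top_genes_per_cc`` genes by absolute loading.
    assign_prob : float
        A cell is assigned when its best cluster wins more than this
        fraction of bootstraps (default 0.5), else left unassigned.
    min_corr : "auto", None or float
        Similarity floor for a bootstrap round to cast a vote: a round
        abstains when the cell's best centroid correlation does not exceed
        it.  "auto" (default) uses the one-sided 5% critical value of the
        null Spearman correlation, 1.645/sqrt(n sampled genes), so that a
        cell with no genuine similarity to any reference profile gathers
        votes in only a minority of rounds and ends up unassigned.

    Attributes
    ----------
    gene_set_ : array
        The genes used for correlation.
    centroids_ : ndarray (n_genes_in_set, n_clusters)
        Mean log-CPM reference profiles.
    """

    def __init__(self, n_boot: int = 100, gene_frac: float = 0.8,
                 top_genes_per_cc: int = 100, n_cc: int = 20,
                 assign_prob: float = 0.5, min_corr="auto", seed: int = 0):
        self.n_boot = n_boot
        self.gene_frac = gene_frac
        self.top_genes_per_cc = top_genes_per_cc
        self.n_cc = n_cc
        self.assign_prob = assign_prob
        self.min_corr = min_corr
        self.seed = seed

    def fit(self, reference: NormalizedMatrix, clusters: ClusterAssignment,
            embedding: EmbeddingSpace):
        labels = clusters.labels if isinstance(clusters, ClusterAssignment) \
            else np.asarray(clusters)
        if embedding.gene_loadings is None:
            raise ValueError("embedding carries no gene loadings")
        cols = np.flatnonzero(embedding.mask)[: self.n_cc]
        feat = set()
        for j in cols:
            load = np.abs(embedding.gene_loadings[:, j])
            feat.update(np.argsort(-load, kind="stable")[: self.top_genes_per_cc])
        gene_set = np.asarray(embedding.gene_ids, dtype=object)[sorted(feat)]
        idx = {g: i for i, g in enumerate(reference.gene_ids)}
        present = [g for g in gene_set if g in idx]
        if len(present) < len(gene_set):
            logger.warning("%d gene-set genes absent from the reference",
                           len(gene_set) - len(present))
        self.gene_set_ = np.asarray(present, dtype=object)
        rows = [idx[g] for g in present]
        ref_dense = np.asarray(reference.matrix[rows, :].todense())
        k = int(labels.max()) + 1
        self.centroids_ = np.column_stack(
            [ref_dense[:, labels == c].mean(axis=1) for c in range(k)]
        )
        self.n_clusters_ = k
        return self

    def predict(self, query: NormalizedMatrix) -> pd.DataFrame:
        idx = {g: i for i, g in enumerate(query.gene_ids)}
        missing = [g for g in self.gene_set_ if g not in idx]
        if missing:
            raise ValueError(
                f"query is missing {len(missing)} gene-set genes, e.g. {missing[:3]}"
            )
        rows = [idx[g] for g in self.gene_set_]
        Q = np.asarray(query.matrix[rows, :].todense())
        n_cells = Q.shape[1]
        n_genes = len(self.gene_set_)
        n_sample = int(np.floor(self.gene_frac * n_genes))
        rng = np.random.default_rng(self.seed)

        if self.min_corr == "auto":
            min_corr = 1.645 / np.sqrt(n_sample)
        else:
            min_corr = -np.inf if self.min_corr is None else float(self.min_corr)
        wins = np.zeros((n_cells, self.n_clusters_))
        valid = np.zeros(n_cells)
        for _ in range(self.n_boot):
            take = rng.choice(n_genes, size=n_sample, replace=False)
            corr = _spearman_matrix(Q[take, :], self.centroids_[take, :])
            ok = ~np.isnan(corr).all(axis=1)
            ok &= np.where(ok, np.nanmax(np.where(np.isnan(corr), -np.inf, corr),
                                         axis=1), -np.inf) > min_corr
            best = np.full(n_cells, -1)
            best[ok] = np.nanargmax(corr[ok], axis=1)  # ties -> lowest index
            for c in range(self.n_clusters_):
                wins[best == c, c] += 1
            valid += ok
        with np.errstate(invalid="ignore", divide="ignore"):
            probs = wins / self.n_boot
        best = np.argmax(probs, axis=1)
        best_prob = probs[np.arange(n_cells), best]
        assigned = best_prob > self.assign_prob
        out = pd.DataFrame(
            {
                "barcode": query.barcodes,
                "label": np.where(assigned, best, -1),
                "probability": best_prob,
                "assigned": assigned,
            }
        )
        self.probabilities_ = probs
        self.unassigned_fraction_ = float((~assigned).mean())
        return out


def bootstrap_label_transfer(reference, clusters, embedding, query,
                             n_boot: int = 100, gene_frac: float = 0.8,
                             top_genes_per_cc: int = 100, n_cc: int = 20,
                             assign_prob: float = 0.5, seed: int = 0):
    """Functional wrapper; returns (result frame, probability matrix)."""
    blt = BootstrapLabelTransfer(
        n_boot=n_boot, gene_frac=gene_frac, top_genes_per_cc=top_genes_per_cc,
        n_cc=n_cc, assign_prob=assign_prob, seed=seed,
    ).fit(reference, clusters, embedding)
    result = blt.predict(query)
    return result, blt.probabilities_
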