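"""Entropy-based detection of cluster-enriched genes and disease-level
summaries.

A gene is called cluster-specific when it passes two Shannon-entropy
criteria: (i) its outlier-trimmed per-cluster mean expression is
non-uniform across clusters (entropy-deviance G-statistic against the
uniform-share null, chi-square with C-1 df, p < 1e-5), and (ii) the cells
expressing it are concentrated in a subset of clusters rather than spread
proportionally to cluster sizes (G-test of expressing-cell counts against
size-proportional expectation, p < 1e-8).  The second criterion guards
against broadly expressed genes that merely vary in level.

For each passing gene, the enriched clusters are annotated by knee-point
detection: cluster means are ranked increasingly, every two-segment
least-squares split is evaluated, and clusters strictly above the lower
segment's fitted value at the best split are marked enriched.

The criterion-i deviance is scaled by the number of expressing cells
(after trimming) rather than by summed expression mass: on log-scale
values a mass scaling inflates the statistic by the mean log expression
and breaks the chi-square calibration, while the expressing-cell count
keeps the null conservative.  The scaling is configurable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .containers import GWASCatalog, NormalizedMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "trimmed_cluster_means",
    "entropy_tests",
    "knee_annotation",
    "EntropyEnrichment",
    "EnrichmentMatrix",
    "disease_summary",
]


def trimmed_cluster_means(
    norm: NormalizedMatrix, clusters: np.ndarray, trim_pctile: float = 99.0
) -> np.ndarray:
    """Per-gene, per-cluster mean expression with top-tail cells excluded.

    For every gene, cells whose value lies strictly above that gene's
    ``trim_pctile`` percentile (linear interpolation, computed over all
    cells) are excluded from every cluster's mean.  A constant gene and a
    trim at 100 both reduce to plain means.
    """
    clusters = np.asarray(clusters).astype(int)
    dense = norm.dense()
    C = clusters.max() + 1
    thr = np.percentile(dense, trim_pctile, axis=1)
    include = dense <= thr[:, None]
    out = np.zeros((dense.shape[0], C))
    for c in range(C):
        cells = clusters == c
        inc = include[:, cells]
        vals = dense[:, cells]
        n_inc = inc.sum(axis=1)
        sums = (vals * inc).sum(axis=1)
        # a cluster whose cells were all trimmed falls back to its plain mean
        plain = vals.mean(axis=1) if cells.sum() else np.zeros(dense.shape[0])
        with np.errstate(invalid="ignore"):
            out[:, c] = np.where(n_inc > 0, sums / np.maximum(n_inc, 1), plain)
    return out


def entropy_tests(
    norm: NormalizedMatrix,
    clusters: np.ndarray,
    alpha_i: float = 1e-5,
    alpha_ii: float = 1e-8,
    min_cells: int = 10,
    trim_pctile: float = 99.0,
    n_eff: str = "expressing_cells",
) -> pd.DataFrame:
    """Per-gene expression-specificity statistics and pass flags.

    Criterion i (non-uniform level): shares ``p_c`` from trimmed cluster
    means, entropy ``H = -sum p ln p``, statistic ``2 N_eff (ln C - H)``
    against chi-square with C-1 df.  ``n_eff`` selects the deviance
    scaling: ``"expressing_cells"`` (default) or ``"mass"`` (total trimmed
    expression).  Criterion ii (concentrated detection): G-test of
    expressing-cell counts per cluster against cluster-size proportions.
    Genes detected in fewer than ``min_cells`` cells are not tested.
    """
    clusters = np.asarray(clusters).astype(int)
    C = clusters.max() + 1
    if C < 2:
        raise ValueError("entropy tests need at least two clusters")
    dense = norm.dense()
    G = dense.shape[0]
    tmeans = trimmed_cluster_means(norm, clusters, trim_pctile)

    sizes = np.bincount(clusters, minlength=C).astype(float)
    expr_counts = np.zeros((G, C))
    for c in range(C):
        expr_counts[:, c] = (dense[:, clusters == c] > 0).sum(axis=1)
    total_expr = expr_counts.sum(axis=1)
    tested = total_expr >= min_cells

    thr = np.percentile(dense, trim_pctile, axis=1)
    include = dense <= thr[:, None]
    mass = (dense * include).sum(axis=1)
    n_expr_trimmed = ((dense > 0) & include).sum(axis=1)

    row_tot = tmeans.sum(axis=1)
    stat_i = np.full(G, np.nan)
    p_i = np.full(G, np.nan)
    ok = tested & (row_tot > 0)
    shares = np.zeros((G, C))
    shares[ok] = tmeans[ok] / row_tot[ok, None]
    with np.errstate(invalid="ignore", divide="ignore"):
        logp = np.where(shares > 0, np.log(shares), 0.0)
    H = -(shares * logp).sum(axis=1)
    scale = n_expr_trimmed if n_eff == "expressing_cells" else mass
    if n_eff not in ("expressing_cells", "mass"):
        raise ValueError("n_eff must be 'expressing_cells' or 'mass'")
    stat_i[ok] = 2.0 * scale[ok] * (np.log(C) - H[ok])
    stat_i[ok] = np.maximum(stat_i[ok], 0.0)
    p_i[ok] = stats.chi2.sf(stat_i[ok], df=C - 1)

    stat_ii = np.full(G, np.nan)
    p_ii = np.full(G, np.nan)
    expect = np.outer(total_expr, sizes / sizes.sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        terms = np.where(expr_counts > 0,
                         expr_counts * np.log(expr_counts / expect), 0.0)
    stat_ii[tested] = np.maximum(2.0 * terms[tested].sum(axis=1), 0.0)
    p_ii[tested] = stats.chi2.sf(stat_ii[tested], df=C - 1)

    return pd.DataFrame(
        {
            "gene": norm.gene_ids,
            "tested": tested,
            "n_expressing": total_expr.astype(int),
            "stat_nonuniform": stat_i,
            "p_nonuniform": p_i,
            "pass_nonuniform": tested & (p_i < alpha_i),
            "stat_concentration": stat_ii,
            "p_concentration": p_ii,
            "pass_concentration": tested & (p_ii < alpha_ii),
        }
    )


def _segment_sse(y: np.ndarray):
    """SSE of the least-squares line through (0..m-1, y); 0 for m <= 2."""
    m = len(y)
    if m <= 2:
        if m == 2:
            return 0.0, float(y[1])
        return 0.0, float(y[-1]) if m else (0.0, 0.0)
    x = np.arange(m, dtype=float)
    xm, ym = x.mean(), y.mean()
    sxx = ((x - xm) ** 2).sum()
    slope = ((x - xm) * (y - ym)).sum() / sxx
    fit = ym + slope * (x - xm)
    return float(((y - fit) ** 2).sum()), float(fit[-1])


def knee_annotation(cluster_means, degenerate_tol: float = 1e-9):
    """Binary enrichment vector from knee-point detection on ranked means.

    Means are sorted increasingly; every split into two contiguous
    segments is scored by the summed SSE of per-segment least-squares
    lines; at the best split, clusters strictly above the lower segment's
    fitted value at its right end are enriched.  All-equal means yield no
    enrichment; means already on a single straight line are degenerate and
    fall back to marking only the top cluster (``degenerate=True``).

    Returns ``(calls, degenerate_flag)``.
    """
    means = np.asarray(cluster_means, float)
    C = len(means)
    if C < 3:
        raise ValueError("knee annotation needs at least 3 clusters")
    if np.ptp(means) == 0:
        return np.zeros(C, dtype=int), False

    order = np.argsort(means, kind="stable")
    y = means[order]
    scale = max(float(((y - y.mean()) ** 2).sum()), 1e-300)
    sse_single, _ = _segment_sse(y)
    if sse_single <= degenerate_tol * scale:
        calls = np.zeros(C, dtype=int)
        calls[order[-1]] = 1
        logger.info("knee degenerate (collinear means); marking top cluster only")
        return calls, True

    best = (np.inf, None, None)
    for s in range(1, C):
        sse_lo, knee_val = _segment_sse(y[:s])
        sse_hi, _ = _segment_sse(y[s:])
        total = sse_lo + sse_hi
        if total < best[0]:
            best = (total, s, knee_val)
    _, s, knee_val = best
    calls = (means > knee_val).astype(int)
    if calls.sum() == 0:  # numerical guard: the top cluster is always above
        calls[order[-1]] = 1
    return calls, False


@dataclass
class EnrichmentMatrix:
    """Binary gene x cluster enrichment calls plus the test statistics."""

    calls: pd.DataFrame  # genes x clusters, 0/1
    stats: pd.DataFrame  # per-gene statistics from entropy_tests
    trimmed_means: np.ndarray

    def enriched_genes(self) -> np.ndarray:
        return self.calls.index[(self.calls.sum(axis=1) > 0)].to_numpy()


class EntropyEnrichment(BaseEstimator):
    """Two-criterion entropy specificity test plus knee-point annotation.

    Attributes (after ``fit``)
    --------------------------
    stats_ : DataFrame from :func:`entropy_tests`.
    calls_ : DataFrame (genes x clusters); nonzero rows only for genes
        passing both criteria.
    result_ : EnrichmentMatrix bundling both.
    """

    def __init__(self, alpha_i: float = 1e-5, alpha_ii: float = 1e-8,
                 min_cells: int = 10, trim_pctile: float = 99.0,
                 n_eff: str = "expressing_cells"):
        self.alpha_i = alpha_i
        self.alpha_ii = alpha_ii
        self.min_cells = min_cells
        self.trim_pctile = trim_pctile
        self.n_eff = n_eff

    def fit(self, norm: NormalizedMatrix, clusters: np.ndarray):
        clusters = np.asarray(clusters).astype(int)
        C = clusters.max() + 1
        st = entropy_tests(
            norm, clusters, alpha_i=self.alpha_i, alpha_ii=self.alpha_ii,
            min_cells=self.min_cells, trim_pctile=self.trim_pctile,
            n_eff=self.n_eff,
        )
        tmeans = trimmed_cluster_means(norm, clusters, self.trim_pctile)
        calls = np.zeros((len(st), C), dtype=int)
        passing = st["pass_nonuniform"] & st["pass_concentration"]
        degenerate = np.zeros(len(st), dtype=bool)
        for gi in np.flatnonzero(passing.to_numpy()):
            calls[gi], degenerate[gi] = knee_annotation(tmeans[gi])
        st = st.assign(knee_degenerate=degenerate)
        self.stats_ = st
        self.calls_ = pd.DataFrame(
            calls, index=pd.Index(norm.gene_ids, name="gene"),
            columns=[f"cluster_{c}" for c in range(C)],
        )
        self.trimmed_means_ = tmeans
        self.result_ = EnrichmentMatrix(self.calls_, st, tmeans)
        return self


def disease_summary(
    enrichment: EnrichmentMatrix,
    catalog: GWASCatalog,
    de_results: pd.DataFrame = None,
):
    """Percent of each disease's catalog genes enriched per cluster.

    Returns ``(per_cluster, per_disease)`` frames.  ``per_cluster`` has one
    row per (disease, cluster) with the percentage of the disease's
    in-universe catalog genes enriched in that cluster (NA when the
    disease has no catalog gene in the expression universe), plus counts
    of catalog genes passing the DE cutoffs when ``de_results`` (with
    ``gene``, ``cluster``, ``pass`` columns) is supplied.  ``per_disease``
    reports the percentage of catalog genes with any enriched call.
    """
    calls = enrichment.calls
    universe = set(calls.index)
    cluster_cols = list(calls.columns)
    rows, overall = [], []
    for disease in catalog.diseases:
        genes = catalog.genes_for(disease)
        present = [g for g in genes if g in universe]
        missing = len(genes) - len(present)
        if missing:
            logger.info("%s: %d catalog genes not in universe", disease, missing)
        if not present:
            for col in cluster_cols:
                rows.append({"disease": disease, "cluster": col,
                             "pct_enriched": np.nan, "n_de": np.nan})
            overall.append({"disease": disease, "n_genes": 0,
                            "pct_any_enriched": np.nan})
            continue
        sub = calls.loc[present]
        for col in cluster_cols:
            n_de = np.nan
            if de_results is not None:
                cid = int(col.split("_")[1])
                de_sub = de_results[
                    (de_results["cluster"] == cid)
                    & de_results["gene"].isin(present)
                    & de_results["pass"]
                ]
                n_de = int(len(de_sub))
            rows.append(
                {
                    "disease": disease,
                    "cluster": col,
                    "pct_enriched": 100.0 * sub[col].sum() / len(present),
                    "n_de": n_de,
                }
            )
        overall.append(
            {
                "disease": disease,
                "n_genes": len(present),
                "pct_any_enriched": 100.0 * (sub.sum(axis=1) > 0).mean(),
            }
        )
    return pd.DataFrame(rows), pd.DataFrame(overall)
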