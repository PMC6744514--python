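"""Marker detection and differential expression.

Three test families:

* a negative-binomial GLM on raw UMI counts with a log link, testing a
  binary contrast while controlling for log library size, mitochondrial
  fraction and sample of origin (Wald test on the contrast coefficient,
  Bonferroni correction by default);
* a zero-inflated bimodal likelihood-ratio test on normalized values,
  modelling each group as a point mass at zero plus a Gaussian for
  positive values (chi-square with 2 degrees of freedom);
* utilities to rescale batches sequenced at different depths to the
  shallowest batch before cross-dataset testing.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
import scipy.sparse as sp
import statsmodels.api as sm
from scipy import stats
from scipy.optimize import minimize_scalar
from scipy.special import gammaln

from .containers import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "nb_glm_test",
    "de_between_timepoints",
    "bimod_lrt",
    "rescale_depth",
    "default_covariates",
    "passes_cutoffs",
]

LOG_FC_CUTOFF = np.log(1.5)  # "at least 50% change"


def passes_cutoffs(log_fc, q, fc: float = 1.5, q_max: float = 0.05):
    """Strict DE cutoffs: |FC| > fc (a fold change of exactly ``fc`` fails)
    and adjusted p < ``q_max``."""
    return (np.abs(np.asarray(log_fc, float)) > np.log(fc)) & (
        np.asarray(q, float) < q_max
    )


def default_covariates(matrix: ExpressionMatrix, pct_mito=None) -> pd.DataFrame:
    """Standard covariate frame: log UMI, optional mito fraction, sample."""
    cov = pd.DataFrame({"log_umi": np.log(np.maximum(matrix.depths(), 1))})
    if pct_mito is not None:
        cov["pct_mito"] = np.asarray(pct_mito, float)
    if "sample" in matrix.cell_meta.columns:
        cov["sample"] = matrix.cell_meta["sample"].to_numpy()
    return cov


def _design_matrix(labels: np.ndarray, covariates: pd.DataFrame):
    cols = [np.ones(len(labels)), labels.astype(float)]
    names = ["intercept", "contrast"]
    if covariates is not None:
        for c in covariates.columns:
            col = covariates[c]
            if col.dtype == object or str(col.dtype) == "category":
                dummies = pd.get_dummies(col, prefix=c, drop_first=True)
                for d in dummies.columns:
                    v = dummies[d].to_numpy(float)
                    if v.std() > 0:
                        cols.append(v)
                        names.append(d)
            else:
                v = col.to_numpy(float)
                if v.std() > 0:
                    cols.append((v - v.mean()) / v.std())
                    names.append(c)
    return np.column_stack(cols), names


def _nb_loglik_alpha(alpha: float, y: np.ndarray, mu: np.ndarray) -> float:
    """NB2 log-likelihood in the dispersion alpha, means held fixed."""
    size = 1.0 / alpha
    return float(
        np.sum(
            gammaln(y + size)
            - gammaln(size)
            - gammaln(y + 1)
            + size * np.log(size / (size + mu))
            + y * np.log(mu / (size + mu))
        )
    )


def _estimate_alpha(y: np.ndarray, mu: np.ndarray) -> float:
    """Dispersion by maximum likelihood (profile in alpha), seeded by a
    method-of-moments estimate."""
    mom = np.sum((y - mu) ** 2 - mu) / max(np.sum(mu**2), 1e-12)
    mom = float(np.clip(mom, 1e-6, 100.0))
    try:
        res = minimize_scalar(
            lambda la: -_nb_loglik_alpha(np.exp(la), y, np.maximum(mu, 1e-12)),
            bracket=(np.log(mom) - 2, np.log(mom), np.log(mom) + 2),
            method="brent",
            options={"maxiter": 50},
        )
        alpha = float(np.exp(np.clip(res.x, np.log(1e-6), np.log(100.0))))
    except Exception:  # fall back to the moment estimate
        alpha = mom
    return alpha


def nb_glm_test(
    counts,
    labels: np.ndarray,
    covariates: pd.DataFrame = None,
    gene_ids=None,
    min_frac: float = 0.1,
    adjust: str = "bonferroni",
) -> pd.DataFrame:
    """Per-gene NB regression of raw counts on a binary contrast plus
    covariates.

    A gene is tested only when it is detected in at least ``min_frac`` of
    the cells of one of the two groups.  Dispersion is estimated per gene
    by profile maximum likelihood with a method-of-moments seed; the Wald
    p-value of the contrast coefficient is corrected over the tested genes
    (Bonferroni by default, Benjamini-Hochberg with ``adjust="bh"``).
    Non-converging fits fall back to a Poisson GLM with robust standard
    errors, flagged per gene.
    """
    if isinstance(counts, ExpressionMatrix):
        gene_ids = counts.gene_ids
        counts = counts.counts
    counts = counts.tocsr() if sp.issparse(counts) else sp.csr_matrix(counts)
    labels = np.asarray(labels).astype(int)
    if set(np.unique(labels)) - {0, 1}:
        raise ValueError("labels must be a binary 0/1 contrast")
    if labels.sum() == 0 or labels.sum() == len(labels):
        raise ValueError("both contrast groups must be non-empty")
    if gene_ids is None:
        gene_ids = np.array([f"g{i}" for i in range(counts.shape[0])], dtype=object)
    if covariates is not None and len(covariates) != counts.shape[1]:
        raise ValueError("covariates not aligned to cells")

    X, _ = _design_matrix(labels, covariates)
    g0, g1 = labels == 0, labels == 1
    rows = []
    for gi in range(counts.shape[0]):
        y = np.asarray(counts[gi, :].todense()).ravel().astype(float)
        fA = (y[g0] > 0).mean()
        fB = (y[g1] > 0).mean()
        if max(fA, fB) < min_frac:
            rows.append((gene_ids[gi], np.nan, np.nan, np.nan, np.nan, False, ""))
            continue
        coef = se = np.nan
        flag = ""
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                pois = sm.GLM(y, X, family=sm.families.Poisson()).fit(maxiter=50)
                alpha = _estimate_alpha(y, pois.fittedvalues)
                nb = sm.GLM(
                    y, X, family=sm.families.NegativeBinomial(alpha=alpha)
                ).fit(maxiter=100)
                alpha = _estimate_alpha(y, nb.fittedvalues)
                nb = sm.GLM(
                    y, X, family=sm.families.NegativeBinomial(alpha=alpha)
                ).fit(maxiter=100)
            coef, se = nb.params[1], nb.bse[1]
            if not np.isfinite(coef) or not np.isfinite(se) or se == 0:
                raise ValueError("degenerate NB fit")
        except Exception:
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    pois = sm.GLM(y, X, family=sm.families.Poisson()).fit(
                        maxiter=100, cov_type="HC0"
                    )
                coef, se = pois.params[1], pois.bse[1]
                flag = "poisson_fallback"
            except Exception:
                rows.append((gene_ids[gi], np.nan, np.nan, np.nan, np.nan,
                             False, "fit_failed"))
                continue
        z = coef / se
        p = 2 * stats.norm.sf(abs(z))
        rows.append((gene_ids[gi], coef, np.exp(coef), z, p, True, flag))

    out = pd.DataFrame(
        rows,
        columns=["gene", "log_fc", "fc", "stat", "p_raw", "tested", "flag"],
    )
    tested = out["tested"].to_numpy()
    n_tested = int(tested.sum())
    p_adj = np.full(len(out), np.nan)
    if n_tested:
        praw = out.loc[tested, "p_raw"].to_numpy()
        if adjust == "bonferroni":
            p_adj[tested] = np.minimum(praw * n_tested, 1.0)
        elif adjust == "bh":
            from statsmodels.stats.multitest import multipletests

            p_adj[tested] = multipletests(praw, method="fdr_bh")[1]
        else:
            raise ValueError(f"unknown adjustment {adjust!r}")
    out["p_adj"] = p_adj
    out["adjust"] = adjust
    out["direction"] = np.where(out["log_fc"] > 0, "up", "down")
    out.loc[~tested, "direction"] = ""
    return out


def de_between_timepoints(
    matrix: ExpressionMatrix,
    clusters: np.ndarray,
    timepoints: np.ndarray,
    fc: float = 1.5,
    q: float = 0.05,
    covariates: pd.DataFrame = None,
    min_frac: float = 0.1,
    adjust: str = "bonferroni",
):
    """Within-cluster DE on a two-timepoint contrast.

    Runs :func:`nb_glm_test` inside each cluster and reports genes passing
    ``|FC| > fc`` (strict) and adjusted p < ``q``, split by direction.
    Returns (per-cluster results dict, summary frame of up/down counts).
    """
    clusters = np.asarray(clusters)
    timepoints = np.asarray(timepoints)
    tp = np.unique(timepoints)
    if len(tp) != 2:
        raise ValueError(f"expected exactly two timepoints, got {list(tp)}")
    results, summary = {}, []
    for k in np.unique(clusters):
        sel = clusters == k
        t_here = np.unique(timepoints[sel])
        if len(t_here) < 2:
            logger.warning("cluster %s missing a timepoint; skipped", k)
            continue
        labels = (timepoints[sel] == tp[1]).astype(int)
        cov = covariates.iloc[np.flatnonzero(sel)].reset_index(drop=True) \
            if covariates is not None else None
        res = nb_glm_test(
            matrix.subset_cells(sel), labels, covariates=cov,
            min_frac=min_frac, adjust=adjust,
        )
        passing = res["tested"] & passes_cutoffs(
            res["log_fc"].fillna(0.0), res["p_adj"].fillna(1.0), fc=fc, q_max=q
        )
        res["pass"] = passing
        results[int(k)] = res
        summary.append(
            {
                "cluster": int(k),
                "n_up": int((passing & (res["log_fc"] > 0)).sum()),
                "n_down": int((passing & (res["log_fc"] < 0)).sum()),
            }
        )
    return results, pd.DataFrame(summary)


def _bimod_loglik(values: np.ndarray, pi: float, mu: float, sigma: float) -> float:
    """Log-likelihood of the zero/Gaussian two-component model."""
    zero = values <= 0
    n0, pos = int(zero.sum()), values[~zero]
    ll = 0.0
    if n0:
        ll += n0 * np.log(max(pi, 1e-300))
    if len(pos):
        ll += len(pos) * np.log(max(1 - pi, 1e-300))
        ll += stats.norm.logpdf(pos, loc=mu, scale=sigma).sum()
    return float(ll)


def bimod_lrt(group_a, group_b):
    """Likelihood-ratio test under the bimodal (zero-inflated Gaussian)
    model.

    Each group is a point mass at zero with probability pi plus a Gaussian
    over positive values; the Gaussian scale is shared.  The LRT compares
    pooled (common pi, mu) against per-group (pi, mu); the statistic is
    referred to chi-square with 2 df.  Symmetric in group order.
    """
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if np.any(a < 0) or np.any(b < 0):
        raise ValueError("bimod_lrt expects non-negative normalized values")
    pooled = np.concatenate([a, b])
    pos_all = pooled[pooled > 0]
    if len(pos_all) == 0:
        return 0.0, 1.0
    sigma = max(float(pos_all.std()), 1e-6)
    mu_pool = float(pos_all.mean())

    def group_ll(v, pooled_pi=None, pooled_mu=None):
        pi = pooled_pi if pooled_pi is not None else (v <= 0).mean()
        pos = v[v > 0]
        mu = pooled_mu if pooled_mu is not None else (
            float(pos.mean()) if len(pos) else mu_pool
        )
        return _bimod_loglik(v, pi, mu, sigma)

    pi_pool = (pooled <= 0).mean()
    ll_pooled = group_ll(a, pi_pool, mu_pool) + group_ll(b, pi_pool, mu_pool)
    ll_sep = group_ll(a) + group_ll(b)
    stat = max(0.0, 2.0 * (ll_sep - ll_pooled))
    p = float(stats.chi2.sf(stat, df=2))
    return float(stat), p


def rescale_depth(matrices):
    """Scale each batch's counts so all batches match the shallowest
    batch's mean depth; returns real-valued expected-count matrices."""
    if len(matrices) < 2:
        return list(matrices)
    gene_sets = {tuple(m.gene_ids) for m in matrices}
    if len(gene_sets) != 1:
        raise ValueError("batches must share an identical gene universe")
    means = []
    for m in matrices:
        if m.n_cells == 0:
            raise ValueError("cannot rescale an empty batch")
        means.append(m.depths().mean())
    target = min(means)
    out = []
    for m, mean_depth in zip(matrices, means):
        scaled = m.counts.astype(np.float64) * (target / mean_depth)
        out.append(
            ExpressionMatrix(scaled, m.gene_ids, m.barcodes, m.cell_meta,
                             integral=False)
        )
    return out
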