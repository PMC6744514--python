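import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from scipy import stats

from cortexmap.containers import ExpressionMatrix
from cortexmap.markers import (
    bimod_lrt,
    de_between_timepoints,
    default_covariates,
    nb_glm_test,
    passes_cutoffs,
    rescale_depth,
)


def _em(counts, genes=None, barcodes=None, meta=None):
    counts = np.asarray(counts)
    genes = genes or [f"g{i}" for i in range(counts.shape[0])]
    barcodes = barcodes or [f"b{i}" for i in range(counts.shape[1])]
    return ExpressionMatrix(sp.csr_matrix(counts), np.array(genes, dtype=object),
                            np.array(barcodes, dtype=object), meta)


class TestNbGlm:
    def test_planted_fold_recovered_with_sign(self):
        rng = np.random.default_rng(0)
        n0, n1 = 300, 300
        labels = np.repeat([0, 1], [n0, n1])
        base = rng.gamma(5, 1, size=n0 + n1)
        y_null = rng.poisson(base)
        y_up = rng.poisson(base * np.where(labels == 1, 4.0, 1.0))
        res = nb_glm_test(np.vstack([y_null, y_up]), labels)
        up = res.iloc[1]
        assert up["p_adj"] < 0.05
        assert up["log_fc"] == pytest.approx(np.log(4), abs=0.3)
        assert up["direction"] == "up"
        assert res.iloc[0]["p_raw"] > 0.001

    def test_null_gene_fc_near_one_with_balanced_covariates(self):
        rng = np.random.default_rng(1)
        labels = np.tile([0, 1], 200)
        y = rng.poisson(5.0, size=400)
        cov = pd.DataFrame({"log_umi": rng.normal(8, 0.1, 400)})
        res = nb_glm_test(y[None, :], labels, covariates=cov)
        assert res.iloc[0]["fc"] == pytest.approx(1.0, abs=0.15)

    def test_low_expression_genes_skipped(self):
        rng = np.random.default_rng(2)
        labels = np.repeat([0, 1], 50)
        y = np.zeros(100)
        y[:3] = 1  # 6% of one group
        res = nb_glm_test(y[None, :], labels, min_frac=0.1)
        assert not res.iloc[0]["tested"]
        assert np.isnan(res.iloc[0]["p_adj"])

    def test_reduces_to_direct_nb_lrt_without_covariates(self):
        """With constant covariates the Wald test agrees with a direct
        two-group NB likelihood ratio computed by independent optimization."""
        from scipy.optimize import minimize
        from scipy.special import gammaln

        rng = np.random.default_rng(3)
        labels = np.repeat([0, 1], 100)
        y = rng.negative_binomial(5, 0.5, size=200).astype(float)
        y[labels == 1] = rng.negative_binomial(5, 0.44, size=100)

        def nb_ll(params, yy):
            mu, alpha = np.exp(params)
            size = 1 / alpha
            return -np.sum(gammaln(yy + size) - gammaln(size) - gammaln(yy + 1)
                           + size * np.log(size / (size + mu))
                           + yy * np.log(np.maximum(mu, 1e-12) / (size + mu)))

        # independent oracle: separate vs pooled means, free dispersion
        r_pool = minimize(nb_ll, [np.log(y.mean()), 0.0], args=(y,), method="Nelder-Mead")
        r0 = minimize(nb_ll, [np.log(y[labels == 0].mean()), 0.0],
                      args=(y[labels == 0],), method="Nelder-Mead")
        r1 = minimize(nb_ll, [np.log(y[labels == 1].mean()), 0.0],
                      args=(y[labels == 1],), method="Nelder-Mead")
        lrt = 2 * (r_pool.fun - r0.fun - r1.fun)
        p_oracle = stats.chi2.sf(lrt, 1)

        res = nb_glm_test(y[None, :], labels)
        p_wald = res.iloc[0]["p_raw"]
        # Wald and LRT agree asymptotically at moderate effect sizes
        assert 1e-4 < p_oracle < 0.5
        assert np.log10(p_wald) == pytest.approx(np.log10(p_oracle), abs=0.5)

    def test_invalid_labels_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            nb_glm_test(np.ones((1, 4)), np.array([0, 1, 2, 1]))
        with pytest.raises(ValueError, match="non-empty"):
            nb_glm_test(np.ones((1, 4)), np.zeros(4))


class TestTimepointDE:
    def _dataset(self, seed=4, fold=2.0):
        rng = np.random.default_rng(seed)
        n = 400
        clusters = np.repeat([0, 1], n // 2)
        tp = np.tile(["P21", "P60"], n // 2)
        base = rng.gamma(4, 1, size=(60, n))
        lam = base.copy()
        # genes 0-9 shift 2-fold at P60 in cluster 0 only
        sel = (clusters == 0) & (tp == "P60")
        lam[:10, sel] *= fold
        counts = rng.poisson(lam)
        meta = pd.DataFrame({"sample": np.tile(["s1", "s2"], n // 2)})
        return _em(counts, meta=meta), clusters, tp

    def test_planted_up_genes_recovered_in_up_list(self):
        em, clusters, tp = self._dataset()
        results, summary = de_between_timepoints(em, clusters, tp, min_frac=0.05)
        r0 = results[0]
        planted = r0.iloc[:10]
        assert (planted["pass"] & (planted["log_fc"] > 0)).mean() >= 0.8
        up0 = summary.loc[summary["cluster"] == 0, "n_up"].item()
        assert up0 >= 8

    def test_null_cluster_yields_no_calls(self):
        em, clusters, tp = self._dataset()
        results, summary = de_between_timepoints(em, clusters, tp, min_frac=0.05)
        row = summary.loc[summary["cluster"] == 1]
        assert int(row["n_up"].item() + row["n_down"].item()) <= 1

    def test_cluster_missing_a_timepoint_skipped(self):
        em, clusters, tp = self._dataset()
        tp = tp.copy()
        tp[clusters == 1] = "P21"
        results, summary = de_between_timepoints(em, clusters, tp, min_frac=0.05)
        assert 1 not in results

    def test_fc_cutoff_strict_at_boundary(self):
        assert not passes_cutoffs(np.log(1.5), 0.01)
        assert passes_cutoffs(np.log(1.5) + 1e-9, 0.01)
        assert not passes_cutoffs(np.log(2.0), 0.05)
        assert passes_cutoffs(-np.log(2.0), 0.01)


class TestBimodLRT:
    def test_identical_groups_give_zero_and_one(self):
        rng = np.random.default_rng(5)
        v = np.concatenate([np.zeros(30), np.abs(rng.normal(3, 1, 70))])
        stat, p = bimod_lrt(v, v)
        assert stat == pytest.approx(0.0, abs=1e-9)
        assert p == 1.0

    def test_zero_fraction_difference_detected(self):
        rng = np.random.default_rng(6)
        a = np.concatenate([np.zeros(40), np.abs(rng.normal(3, 1, 160))])
        b = np.concatenate([np.zeros(160), np.abs(rng.normal(3, 1, 40))])
        stat, p = bimod_lrt(a, b)
        assert p < 1e-6

    def test_statistic_matches_direct_likelihood_on_ten_cells(self):
        """The statistic equals 2*(ll_sep - ll_pooled) evaluated by an
        independent, fully spelled-out likelihood computation."""
        a = np.array([0.0, 0.0, 1.2, 2.5, 3.1])
        b = np.array([0.0, 2.0, 2.2, 2.9, 4.0])

        pos = np.concatenate([a[a > 0], b[b > 0]])
        sigma = pos.std()

        def ll(v, pi, mu):
            n0 = (v <= 0).sum()
            out = 0.0
            if n0:
                out += n0 * np.log(pi)
            vpos = v[v > 0]
            if len(vpos):
                out += len(vpos) * np.log(1 - pi)
                out += np.sum(-0.5 * np.log(2 * np.pi * sigma**2)
                              - (vpos - mu) ** 2 / (2 * sigma**2))
            return out

        pooled = np.concatenate([a, b])
        pi_p = (pooled <= 0).mean()
        mu_p = pooled[pooled > 0].mean()
        ll_pooled = ll(a, pi_p, mu_p) + ll(b, pi_p, mu_p)
        ll_sep = (ll(a, (a <= 0).mean(), a[a > 0].mean())
                  + ll(b, (b <= 0).mean(), b[b > 0].mean()))
        expected = 2 * (ll_sep - ll_pooled)

        stat, p = bimod_lrt(a, b)
        assert stat == pytest.approx(expected, abs=1e-8)
        assert p == pytest.approx(stats.chi2.sf(expected, 2), abs=1e-12)

    def test_symmetric_in_group_order(self):
        rng = np.random.default_rng(7)
        a = np.concatenate([np.zeros(10), np.abs(rng.normal(2, 1, 30))])
        b = np.concatenate([np.zeros(25), np.abs(rng.normal(2.5, 1, 15))])
        assert bimod_lrt(a, b)[0] == pytest.approx(bimod_lrt(b, a)[0], abs=1e-10)

    def test_both_all_zero_gives_p_one(self):
        assert bimod_lrt(np.zeros(5), np.zeros(8)) == (0.0, 1.0)

    def test_negative_values_rejected(self):
        with pytest.raises(ValueError):
            bimod_lrt(np.array([-1.0]), np.array([1.0]))


class TestRescaleDepth:
    def _batch(self, depth, n, seed):
        rng = np.random.default_rng(seed)
        lam = np.full((30, n), depth / 30)
        return _em(rng.poisson(lam), barcodes=[f"s{seed}_{i}" for i in range(n)])

    def test_deeper_batch_scaled_down(self):
        a = self._batch(10_000, 50, 1)
        b = self._batch(20_000, 50, 2)
        ra, rb = rescale_depth([a, b])
        ratio = rb.counts.sum() / b.counts.sum()
        assert ratio == pytest.approx(0.5, abs=0.05)

    def test_post_rescale_means_agree_within_one_percent(self):
        batches = [self._batch(d, 60, s) for s, d in enumerate([8000, 15000, 30000])]
        rescaled = rescale_depth(batches)
        means = [m.depths().mean() for m in rescaled]
        assert max(means) / min(means) < 1.01

    def test_single_batch_identity(self):
        a = self._batch(5000, 10, 3)
        out = rescale_depth([a])
        assert out[0] is a

    def test_empty_batch_raises(self):
        a = self._batch(5000, 10, 4)
        empty = a.subset_cells(np.zeros(10, bool))
        with pytest.raises(ValueError, match="empty"):
            rescale_depth([a, empty])


def test_default_covariates_composition(sim_qc):
    _, em, _ = sim_qc
    cov = default_covariates(em, pct_mito=np.zeros(em.n_cells))
    assert list(cov.columns) == ["log_umi", "pct_mito", "sample"]
    assert len(cov) == em.n_cells
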