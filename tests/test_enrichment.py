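import numpy as np
import pandas as pd
import pytest

from cortexmap.containers import GWASCatalog
from cortexmap.enrichment import (
    EntropyEnrichment,
    disease_summary,
    entropy_tests,
    knee_annotation,
    trimmed_cluster_means,
)
from .conftest import make_norm


class TestTrimmedMeans:
    def test_single_outlier_excluded_from_its_cluster_mean(self):
        rng = np.random.default_rng(0)
        X = np.abs(rng.normal(2, 0.2, size=(1, 200)))
        X[0, 0] = 50.0
        clusters = np.repeat([0, 1], 100)
        means = trimmed_cluster_means(make_norm(X), clusters)
        assert means[0, 0] < 3.0  # outlier did not inflate cluster 0

    def test_constant_gene_unchanged(self):
        X = np.full((1, 60), 2.5)
        clusters = np.repeat([0, 1, 2], 20)
        means = trimmed_cluster_means(make_norm(X), clusters)
        np.testing.assert_allclose(means, 2.5)

    def test_trim_at_100_gives_plain_means(self):
        rng = np.random.default_rng(1)
        X = np.abs(rng.normal(2, 1, size=(5, 90)))
        clusters = np.repeat([0, 1, 2], 30)
        means = trimmed_cluster_means(make_norm(X), clusters, trim_pctile=100)
        for c in range(3):
            np.testing.assert_allclose(means[:, c], X[:, clusters == c].mean(axis=1))


class TestEntropyTests:
    def test_uniform_gene_has_zero_statistic(self):
        X = np.tile(np.full(120, 3.0), (1, 1))
        clusters = np.repeat(np.arange(4), 30)
        st = entropy_tests(make_norm(X), clusters, min_cells=5)
        assert st["stat_nonuniform"].iloc[0] == pytest.approx(0.0, abs=1e-9)
        assert not st["pass_nonuniform"].iloc[0]
        assert not st["pass_concentration"].iloc[0]

    def test_single_cluster_gene_passes_both_criteria(self):
        """A gene expressed in exactly one of 10 equal clusters with 100
        expressing cells clears both cutoffs; the closed-form G-test value
        is matched."""
        n_per = 100
        C = 10
        clusters = np.repeat(np.arange(C), n_per)
        X = np.zeros((1, C * n_per))
        X[0, clusters == 4] = 3.0
        st = entropy_tests(make_norm(X), clusters)
        assert st["pass_nonuniform"].iloc[0]
        assert st["pass_concentration"].iloc[0]
        # criterion ii closed form: all K cells in one cluster of C equal ones
        K = n_per
        expected = 2 * K * np.log(C)
        assert st["stat_concentration"].iloc[0] == pytest.approx(expected, rel=1e-9)

    def test_null_calibration_on_unstructured_genes(self):
        """Genes simulated with no cluster effect pass criterion i at no
        more than the nominal rate (alpha = 0.01, binomial error)."""
        from cortexmap.simulate import SimulationConfig, generate_dataset
        from cortexmap.qc import normalize_log_cpm, remove_gene_families

        cfg = SimulationConfig(seed=21, n_clusters=8, cells_per_cluster=120,
                               n_genes=1300, markers_per_cluster=1,
                               de_genes_per_cluster=0, n_conditions=1,
                               doublet_rate=0, lowq_rate=0,
                               neuronal_clusters=())
        em, gt = generate_dataset(cfg)
        norm = normalize_log_cpm(remove_gene_families(em))
        clusters = gt.cells["cluster"].to_numpy()
        st = entropy_tests(norm, clusters, alpha_i=0.01, alpha_ii=0.01)
        structured = set(gt.genes.loc[gt.genes["marker_of"] >= 0, "gene"])
        structured |= {"Snap25", "Syt1", "Slc17a7", "Gad2", "Gja1", "C1qa", "Flt1"}
        null = st[st["tested"] & ~st["gene"].isin(structured)]
        assert len(null) >= 1000
        err = 3 * np.sqrt(0.01 * 0.99 / len(null))
        assert null["pass_nonuniform"].mean() <= 0.01 + err

    def test_invariant_to_cluster_relabelling(self):
        rng = np.random.default_rng(2)
        X = np.abs(rng.normal(1, 1, size=(30, 160)))
        clusters = np.repeat(np.arange(4), 40)
        st1 = entropy_tests(make_norm(X), clusters)
        perm = np.array([2, 3, 0, 1])[clusters]
        st2 = entropy_tests(make_norm(X), perm)
        np.testing.assert_allclose(st1["stat_nonuniform"], st2["stat_nonuniform"],
                                   atol=1e-9)

    def test_undetected_gene_not_tested(self):
        X = np.zeros((1, 90))
        clusters = np.repeat([0, 1, 2], 30)
        st = entropy_tests(make_norm(X), clusters)
        assert not st["tested"].iloc[0]


def _brute_force_knee(means):
    """Independent oracle: enumerate splits, fit each segment with lstsq."""
    y = np.sort(np.asarray(means, float))
    C = len(y)
    best = (np.inf, None, None)
    for s in range(1, C):
        total = 0.0
        knee_val = None
        for seg, is_lower in (((0, s), True), ((s, C), False)):
            lo, hi = seg
            x = np.arange(hi - lo, dtype=float)
            yy = y[lo:hi]
            if len(yy) <= 2:
                fit = yy
            else:
                A = np.column_stack([x, np.ones_like(x)])
                coef, *_ = np.linalg.lstsq(A, yy, rcond=None)
                fit = A @ coef
            total += float(((yy - fit) ** 2).sum())
            if is_lower:
                knee_val = float(fit[-1])
        if total < best[0]:
            best = (total, s, knee_val)
    return (np.asarray(means) > best[2]).astype(int)


class TestKneeAnnotation:
    @pytest.mark.parametrize("means,expected", [
        ([1, 1, 1, 1, 10], [0, 0, 0, 0, 1]),
        ([0, 0, 5, 5], [0, 0, 1, 1]),
        ([0, 5, 5, 5], [0, 1, 1, 1]),
        ([2, 2, 2, 2, 2, 9, 9], [0, 0, 0, 0, 0, 1, 1]),
    ])
    def test_constructed_vectors(self, means, expected):
        calls, degenerate = knee_annotation(means)
        assert not degenerate
        np.testing.assert_array_equal(calls, expected)

    def test_matches_brute_force_oracle_on_random_vectors(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            C = rng.integers(4, 20)
            means = np.round(rng.gamma(2, 1, size=C), 3)
            if np.ptp(means) == 0:
                continue
            calls, degenerate = knee_annotation(means)
            if degenerate:
                continue
            np.testing.assert_array_equal(calls, _brute_force_knee(means),
                                          err_msg=str(means))

    def test_linear_means_degenerate_top_one(self):
        calls, degenerate = knee_annotation([1.0, 2.0, 3.0, 4.0, 5.0])
        assert degenerate
        np.testing.assert_array_equal(calls, [0, 0, 0, 0, 1])

    def test_all_equal_means_no_enrichment(self):
        calls, degenerate = knee_annotation([3, 3, 3, 3])
        assert calls.sum() == 0

    def test_scaling_invariance_but_not_shift_invariance(self):
        means = np.array([0.5, 0.6, 0.7, 3.0, 3.2])
        base, _ = knee_annotation(means)
        scaled, _ = knee_annotation(means * 7.3)
        np.testing.assert_array_equal(base, scaled)
        shifted, _ = knee_annotation(means + 100.0)
        # absolute two-line fit: shift changes relative geometry is NOT
        # guaranteed to preserve calls, only scaling is
        assert scaled.sum() == base.sum()

    def test_needs_three_clusters(self):
        with pytest.raises(ValueError):
            knee_annotation([1, 2])


@pytest.fixture(scope="module")
def fitted():
    rng = np.random.default_rng(4)
    n_per, C = 80, 5
    clusters = np.repeat(np.arange(C), n_per)
    X = np.abs(rng.normal(1.5, 0.5, size=(6, C * n_per)))
    X[0] = 0.0
    X[0, clusters == 2] = np.abs(rng.normal(3, 0.5, n_per))  # restricted
    X[1] = 0.0                                               # undetected
    return EntropyEnrichment().fit(make_norm(X), clusters)


class TestEnrichmentPipeline:
    def test_restricted_gene_enriched_in_exactly_its_cluster(self, fitted):
        calls = fitted.calls_.loc["g0"].to_numpy()
        np.testing.assert_array_equal(calls, [0, 0, 1, 0, 0])

    def test_non_passing_genes_have_no_calls(self, fitted):
        assert fitted.calls_.loc["g1"].sum() == 0
        passing = (fitted.stats_["pass_nonuniform"]
                   & fitted.stats_["pass_concentration"]).to_numpy()
        row_sums = fitted.calls_.to_numpy().sum(axis=1)
        assert (row_sums[~passing] == 0).all()
        assert (row_sums[passing] >= 1).all()

    def test_disease_summary_arithmetic(self, fitted):
        catalog = GWASCatalog(pd.DataFrame({
            "gene": ["g0", "g2", "g3", "g4"],
            "disease": ["schizophrenia"] * 4,
            "functional_class": ["missense_variant"] * 4,
        }))
        per_cluster, per_disease = disease_summary(fitted.result_, catalog)
        c2 = per_cluster.loc[per_cluster["cluster"] == "cluster_2",
                             "pct_enriched"].item()
        assert c2 == pytest.approx(25.0)
        assert per_disease["pct_any_enriched"].item() == pytest.approx(25.0)

    def test_disease_with_no_genes_in_universe_is_na(self, fitted):
        catalog = GWASCatalog(pd.DataFrame({
            "gene": ["ABSENT1"], "disease": ["mania"],
            "functional_class": ["missense_variant"],
        }))
        per_cluster, per_disease = disease_summary(fitted.result_, catalog)
        assert per_cluster["pct_enriched"].isna().all()
        assert per_disease["pct_any_enriched"].isna().all()

    def test_empty_enrichment_gives_zero_percent(self):
        rng = np.random.default_rng(5)
        X = np.abs(rng.normal(2, 0.1, size=(3, 120)))
        clusters = np.repeat([0, 1, 2], 40)
        ee = EntropyEnrichment().fit(make_norm(X), clusters)
        catalog = GWASCatalog(pd.DataFrame({
            "gene": ["g0"], "disease": ["autism"],
            "functional_class": ["missense_variant"],
        }))
        per_cluster, _ = disease_summary(ee.result_, catalog)
        assert (per_cluster["pct_enriched"] == 0).all()
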