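import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from cortexmap.containers import ClusterAssignment, canonical_labels
from cortexmap.embed import (
    MergeValidator,
    bicor,
    build_snn,
    build_snn_and_cluster,
    cca_align,
    pca_embed,
    select_variable_genes,
    validate_and_merge,
)
from .conftest import make_norm


class TestVariableGenes:
    def test_constant_gene_excluded(self):
        rng = np.random.default_rng(0)
        X = rng.gamma(2, 1, size=(50, 200))
        X[7] = 1.0  # constant
        genes = select_variable_genes(make_norm(X), n_top=10, min_genes=10)
        assert "g7" not in set(genes)

    def test_identical_datasets_intersection_equals_top_list(self):
        rng = np.random.default_rng(1)
        X = rng.gamma(2, 1, size=(100, 150))
        norm = make_norm(X)
        solo = select_variable_genes(norm, n_top=30, min_genes=20)
        both = select_variable_genes(norm, norm, n_top=30, min_genes=20)
        assert list(solo) == list(both)

    def test_planted_markers_outrank_housekeeping(self, sim_clean, sim_clean_norm):
        _, em, gt = sim_clean
        norm = sim_clean_norm
        genes = select_variable_genes(norm, n_top=2000)
        marker_set = set(gt.genes.loc[gt.genes["marker_of"] >= 0, "gene"])
        frac_markers = np.mean([g in marker_set for g in genes])
        # markers are ~8% of the genome but dominate the variable list
        assert frac_markers > 0.5


class TestBicor:
    def test_perfect_correlation(self):
        x = np.random.default_rng(0).normal(size=200)
        assert bicor(x, x) == pytest.approx(1.0)

    def test_robust_to_single_outlier(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=200)
        y = x + rng.normal(scale=0.05, size=200)
        y_out = y.copy()
        y_out[0] += 50
        assert bicor(x, y_out) > 0.95
        assert abs(np.corrcoef(x, y_out)[0, 1]) < bicor(x, y_out)

    def test_agrees_with_pearson_on_clean_gaussian(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=2000)
        y = 0.5 * x + rng.normal(scale=np.sqrt(0.75), size=2000)
        assert bicor(x, y) == pytest.approx(np.corrcoef(x, y)[0, 1], abs=0.05)


class TestCCAAlign:
    def test_identical_datasets_score_one_all_selected(self):
        rng = np.random.default_rng(3)
        X = rng.gamma(2, 1, size=(60, 120))
        norm = make_norm(X)
        genes = norm.gene_ids[:40]
        space = cca_align(norm, norm, genes, n_cc=5)
        np.testing.assert_allclose(space.scores, 1.0)
        assert space.mask.all()
        # pre == post alignment: the two halves carry identical coordinates
        a = space.coords[space.dataset == 0]
        b = space.coords[space.dataset == 1]
        np.testing.assert_allclose(a, b, atol=1e-8)

    def test_global_shift_alignment_improves_mixing(self):
        """B = A plus a per-gene shift: after alignment, cross-dataset
        nearest-neighbour mixing is at least as good as before."""
        rng = np.random.default_rng(4)
        base = rng.gamma(2, 1, size=(60, 150))
        shift = rng.normal(scale=1.0, size=(60, 1))
        normA = make_norm(base)
        normB = make_norm(base + shift)
        genes = normA.gene_ids
        space = cca_align(normA, normB, genes, n_cc=5)

        def mixing(coords):
            from sklearn.neighbors import NearestNeighbors

            nn = NearestNeighbors(n_neighbors=11).fit(coords)
            _, idx = nn.kneighbors(coords)
            ds = space.dataset
            return np.mean(ds[idx[:, 1:]] != ds[idx[:, 0:1]])

        aligned = mixing(space.coords)
        assert aligned >= 0.3  # cross-dataset neighbours are common

    def test_threshold_default_is_015(self):
        from cortexmap.embed import CCAAligner

        assert CCAAligner().bicor_threshold == 0.15

    def test_missing_gene_raises(self):
        rng = np.random.default_rng(5)
        norm = make_norm(rng.gamma(2, 1, size=(10, 30)))
        with pytest.raises(ValueError, match="absent"):
            cca_align(norm, norm, ["nope"])


class TestSNNCluster:
    def test_weights_bounded_no_self_loops(self):
        rng = np.random.default_rng(6)
        snn = build_snn(rng.normal(size=(100, 5)), k=10)
        assert snn.weights.diagonal().sum() == 0
        assert snn.weights.data.max() <= 1.0 + 1e-12
        assert snn.weights.data.min() >= 0.0
        asym = (snn.weights - snn.weights.T)
        assert abs(asym).max() < 1e-12

    def test_k_must_be_smaller_than_n(self):
        with pytest.raises(ValueError, match="k="):
            build_snn(np.zeros((5, 2)), k=5)

    @pytest.mark.parametrize("resolution", [0.4, 0.8, 1.2])
    def test_two_separated_blobs_give_two_clusters(self, resolution):
        rng = np.random.default_rng(7)
        coords = np.vstack([
            rng.normal(0, 0.3, size=(80, 4)),
            rng.normal(4, 0.3, size=(80, 4)),
        ])
        from cortexmap.containers import EmbeddingSpace

        space = EmbeddingSpace(coords=coords, dataset=np.zeros(160, int),
                               scores=np.ones(4), mask=np.ones(4, bool))
        _, assign = build_snn_and_cluster(space, k=15, resolution=resolution, seed=0)
        truth = np.repeat([0, 1], 80)
        assert adjusted_rand_score(truth, assign.labels) == 1.0


class TestMergeValidation:
    def _snn_for(self, norm, n_pcs=10, k=15, seed=0):
        space = pca_embed(norm, n_pcs=n_pcs, seed=seed)
        return build_snn(space.coords, k=k)

    def test_random_split_of_one_population_is_merged(self):
        rng = np.random.default_rng(8)
        X = np.abs(rng.normal(2, 1, size=(400, 300)))
        norm = make_norm(X)
        labels = rng.permutation(np.repeat([0, 1], 150))
        mv = MergeValidator(seed=0).fit(norm, ClusterAssignment(labels),
                                        self._snn_for(norm))
        assert len(np.unique(mv.labels_)) == 1
        assert mv.decisions_[-1].svm_accuracy < 0.65

    def test_marker_separated_populations_not_merged(self):
        rng = np.random.default_rng(9)
        X = np.abs(rng.normal(2, 1, size=(400, 300)))
        X[:50, 150:] += np.log(4)  # 50 markers at 4-fold on the log scale
        norm = make_norm(X)
        labels = np.repeat([0, 1], 150)
        mv = MergeValidator(seed=0).fit(norm, ClusterAssignment(labels),
                                        self._snn_for(norm))
        assert len(np.unique(mv.labels_)) == 2
        assert all(d.svm_accuracy > 0.95 for d in mv.decisions_)

    def test_single_cluster_returned_unchanged(self):
        rng = np.random.default_rng(10)
        norm = make_norm(np.abs(rng.normal(2, 1, size=(100, 80))))
        mv = MergeValidator(seed=0).fit(
            norm, ClusterAssignment(np.zeros(80, int)), self._snn_for(norm)
        )
        assert len(np.unique(mv.labels_)) == 1
        assert mv.decisions_ == []

    def test_merge_count_bounded_by_initial_clusters(self):
        rng = np.random.default_rng(11)
        norm = make_norm(np.abs(rng.normal(2, 1, size=(200, 200))))
        labels = rng.integers(0, 6, size=200)
        mv = MergeValidator(seed=0).fit(norm, ClusterAssignment(labels),
                                        self._snn_for(norm))
        n_merges = sum(d.merged for d in mv.decisions_)
        assert n_merges <= 5

    def test_invariant_to_label_permutation(self):
        rng = np.random.default_rng(12)
        X = np.abs(rng.normal(2, 1, size=(300, 240)))
        X[:40, :80] += np.log(4)
        X[40:80, 80:160] += np.log(4)
        norm = make_norm(X)
        labels = np.repeat([0, 1, 2], 80)
        snn = self._snn_for(norm)
        mv1 = MergeValidator(seed=0).fit(norm, ClusterAssignment(labels), snn)
        perm = np.array([2, 0, 1])[labels]
        mv2 = MergeValidator(seed=0).fit(norm, ClusterAssignment(perm), snn)
        assert adjusted_rand_score(mv1.labels_, mv2.labels_) == 1.0

    def test_functional_wrapper_matches_estimator(self):
        rng = np.random.default_rng(13)
        norm = make_norm(np.abs(rng.normal(2, 1, size=(150, 120))))
        labels = rng.permutation(np.repeat([0, 1], 60))
        snn = self._snn_for(norm)
        assign, decisions = validate_and_merge(norm, ClusterAssignment(labels), snn)
        mv = MergeValidator(seed=0).fit(norm, ClusterAssignment(labels), snn)
        np.testing.assert_array_equal(assign.labels, mv.labels_)


def test_canonical_labels_order_by_size_then_occurrence():
    labels = np.array([5, 5, 2, 2, 2, 9])
    out = canonical_labels(labels)
    np.testing.assert_array_equal(out, [1, 1, 0, 0, 0, 2])
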