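"""Module detection: profile correlations, hierarchical/k-means clustering,
k selection diagnostics, PCA of the correlation matrix."""

import numpy as np
import pytest

from emapnet import (
    EmapValidationError,
    InteractionMatrix,
    SimulationConfig,
    adjusted_rand_index,
    cluster_hierarchical,
    correlate_profiles,
    cut_largest_gap,
    kmeans_modules,
    pca_correlations,
    select_k,
    simulate_scores,
)


def _matrix(scores, mask=None):
    scores = np.asarray(scores, dtype=float)
    return InteractionMatrix(
        queries=[f"q{i}" for i in range(scores.shape[0])],
        tests=[f"t{j}" for j in range(scores.shape[1])],
        condition="u",
        scores=scores,
        mask=np.zeros(scores.shape, bool) if mask is None else mask,
    )


@pytest.fixture(scope="module")
def planted_two_module():
    """Noise-free 2-module screen, one module the negation of the other."""
    config = SimulationConfig(
        n_queries=10, n_tests=300, conditions=("u",), n_modules=2,
        interaction_sparsity=0.1, noise_sd=1e-12, missing_fraction=0.0,
        anti_module=("M2", "M1"), seed=11,
    )
    matrices, truth = simulate_scores(config)
    return matrices["u"], truth


@pytest.fixture(scope="module")
def planted_four_module():
    config = SimulationConfig(
        n_queries=24, n_tests=600, conditions=("u",), n_modules=4,
        interaction_sparsity=0.1, effect_sd=5.0, noise_sd=1.0,
        missing_fraction=0.02, seed=12,
    )
    matrices, truth = simulate_scores(config)
    return matrices["u"], truth


class TestCorrelateProfiles:
    def test_duplicate_profile_correlates_to_one(self):
        rng = np.random.default_rng(0)
        profile = rng.normal(size=50)
        m = _matrix(np.vstack([profile, profile, rng.normal(size=50)]))
        corr = correlate_profiles(m, min_shared=10)
        assert corr.pair("q0", "q1") == pytest.approx(1.0)

    def test_negated_profile_correlates_to_minus_one(self):
        rng = np.random.default_rng(1)
        profile = rng.normal(size=50)
        m = _matrix(np.vstack([profile, -profile]))
        corr = correlate_profiles(m, min_shared=10)
        assert corr.pair("q0", "q1") == pytest.approx(-1.0)

    def test_affine_rescaling_leaves_r_unchanged(self):
        rng = np.random.default_rng(2)
        scores = rng.normal(size=(4, 60))
        corr_a = correlate_profiles(_matrix(scores), min_shared=10)
        scaled = scores.copy()
        scaled[0] = 3.7 * scaled[0] + 11.0
        corr_b = correlate_profiles(_matrix(scaled), min_shared=10)
        np.testing.assert_allclose(corr_a.r, corr_b.r, atol=1e-12)

    def test_pairwise_complete_and_n_shared(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(size=(2, 100))
        mask = np.zeros((2, 100), bool)
        mask[0, :20] = True
        mask[1, 10:30] = True
        corr = correlate_profiles(_matrix(scores, mask), min_shared=10)
        assert corr.n_shared[0, 1] == 70
        x, y = scores[0, 30:], scores[1, 30:]
        assert corr.pair("q0", "q1") == pytest.approx(np.corrcoef(x, y)[0, 1])

    def test_insufficient_overlap_masks_pair_with_warning(self, caplog):
        rng = np.random.default_rng(4)
        scores = rng.normal(size=(2, 40))
        mask = np.zeros((2, 40), bool)
        mask[0, :25] = True
        mask[1, 20:] = True  # only tests 15..19 shared -> 0 shared? no: 5 shared
        with caplog.at_level("WARNING"):
            corr = correlate_profiles(_matrix(scores, mask), min_shared=30)
        assert corr.masked[0, 1]
        assert any("masked" in r.message for r in caplog.records)

    def test_anti_module_anticorrelates(self, planted_two_module):
        matrix, truth = planted_two_module
        corr = correlate_profiles(matrix)
        labels = np.array(truth.labels_for(corr.queries))
        cross = corr.r[np.ix_(labels == "M1", labels == "M2")]
        assert np.allclose(cross, -1.0, atol=1e-6)


class TestHierarchical:
    def test_two_queries_single_merge_at_one_minus_r(self):
        rng = np.random.default_rng(5)
        profile = rng.normal(size=60)
        m = _matrix(np.vstack([profile, profile * 0.5 + rng.normal(size=60)]))
        corr = correlate_profiles(m, min_shared=10)
        link = cluster_hierarchical(corr)
        assert link.shape == (1, 4)
        assert link[0, 2] == pytest.approx(1.0 - corr.pair("q0", "q1"))

    def test_largest_gap_cut_recovers_planted_bipartition(self, planted_two_module):
        matrix, truth = planted_two_module
        corr = correlate_profiles(matrix)
        labels = cut_largest_gap(cluster_hierarchical(corr))
        assert adjusted_rand_index(labels, truth.labels_for(corr.queries)) == 1.0

    def test_input_order_permutation_preserves_topology(self, planted_four_module):
        matrix, truth = planted_four_module
        corr = correlate_profiles(matrix)
        labels_a = cut_largest_gap(cluster_hierarchical(corr))
        order = list(np.random.default_rng(6).permutation(len(matrix.queries)))
        corr_p = correlate_profiles(matrix, [matrix.queries[i] for i in order])
        labels_b = cut_largest_gap(cluster_hierarchical(corr_p))
        # same partition up to label names and query order
        restored = np.empty_like(labels_b)
        restored[order] = labels_b
        assert adjusted_rand_index(labels_a, restored) == 1.0

    def test_masked_pair_raises_with_guidance(self):
        rng = np.random.default_rng(7)
        scores = rng.normal(size=(3, 40))
        mask = np.zeros((3, 40), bool)
        mask[0, :35] = True
        corr = correlate_profiles(_matrix(scores, mask), min_shared=30)
        with pytest.raises(EmapValidationError, match="impute"):
            cluster_hierarchical(corr)


class TestKMeans:
    def test_k_one_is_total_ss(self, planted_four_module):
        matrix, _ = planted_four_module
        corr = correlate_profiles(matrix)
        assignment = kmeans_modules(corr, k=1, seed=0)
        assert len(set(assignment.labels.values())) == 1
        X = corr.r
        assert assignment.method["wss"] == pytest.approx(
            float(((X - X.mean(axis=0)) ** 2).sum())
        )

    def test_k_equals_n_gives_zero_wss(self):
        rng = np.random.default_rng(8)
        m = _matrix(rng.normal(size=(6, 50)))
        corr = correlate_profiles(m, min_shared=10)
        assignment = kmeans_modules(corr, k=6, seed=0)
        assert assignment.method["wss"] == pytest.approx(0.0, abs=1e-9)

    def test_recovers_planted_modules(self, planted_four_module):
        matrix, truth = planted_four_module
        corr = correlate_profiles(matrix)
        assignment = kmeans_modules(corr, k=4, seed=1)
        ari = adjusted_rand_index(
            [assignment.labels[q] for q in corr.queries],
            truth.labels_for(corr.queries),
        )
        assert ari >= 0.9

    def test_invalid_k_rejected(self, planted_four_module):
        matrix, _ = planted_four_module
        corr = correlate_profiles(matrix)
        with pytest.raises(EmapValidationError):
            kmeans_modules(corr, k=0)


class TestSelectK:
    def test_diagnostics_shapes_and_invariants(self, planted_four_module):
        matrix, _ = planted_four_module
        corr = correlate_profiles(matrix)
        assignment = select_k(corr, k_range=range(1, 7), seed=2, n_refs=20)
        d = assignment.diagnostics
        assert list(d["k"]) == list(range(1, 7))
        assert (np.diff(d["wss"]) <= 1e-9).all()  # WSS non-increasing in k
        finite = d["silhouette"].dropna()
        assert ((finite >= -1) & (finite <= 1)).all()
        assert set(assignment.method["votes"]) == {"elbow", "silhouette", "gap"}

    def test_planted_four_modules_voted(self, planted_four_module):
        matrix, truth = planted_four_module
        corr = correlate_profiles(matrix)
        assignment = select_k(corr, k_range=range(1, 7), seed=3)
        assert assignment.k == 4

    def test_degenerate_identical_rows_returns_k1(self, caplog):
        m = _matrix(np.tile(np.arange(40.0), (4, 1)))
        corr = correlate_profiles(m, min_shared=10)
        with caplog.at_level("WARNING"):
            assignment = select_k(corr, seed=4)
        assert assignment.k == 1


class TestPCA:
    def test_components_orthonormal(self, planted_four_module):
        matrix, _ = planted_four_module
        corr = correlate_profiles(matrix)
        pca = pca_correlations(corr)
        gram = pca.components @ pca.components.T
        np.testing.assert_allclose(gram, np.eye(2), atol=1e-10)

    def test_variance_explained_ordered_and_bounded(self, planted_four_module):
        matrix, _ = planted_four_module
        corr = correlate_profiles(matrix)
        pca = pca_correlations(corr)
        assert pca.variance_explained[0] >= pca.variance_explained[1] >= 0
        assert pca.variance_explained.sum() <= 1.0 + 1e-12

    def test_noise_free_modules_separate_on_pc1(self, planted_two_module):
        matrix, truth = planted_two_module
        corr = correlate_profiles(matrix)
        pca = pca_correlations(corr)
        labels = np.array(truth.labels_for(corr.queries))
        pc1_m1 = pca.coordinates[labels == "M1", 0]
        pc1_m2 = pca.coordinates[labels == "M2", 0]
        assert np.ptp(pc1_m1) < 1e-6 and np.ptp(pc1_m2) < 1e-6
        assert abs(pc1_m1.mean() - pc1_m2.mean()) > 1e-3

    def test_sign_convention_deterministic(self, planted_four_module):
        matrix, _ = planted_four_module
        corr = correlate_profiles(matrix)
        assert pca_correlations(corr).components[:, 0].min() >= 0

    def test_2d_projection_preserves_cluster_structure(self, planted_four_module):
        """k-means on the 2-D coordinates agrees with full-space clustering."""
        from sklearn.cluster import KMeans

        matrix, _ = planted_four_module
        corr = correlate_profiles(matrix)
        full = kmeans_modules(corr, k=4, seed=5)
        pca = pca_correlations(corr)
        km2d = KMeans(n_clusters=4, n_init=50, random_state=5).fit(pca.coordinates)
        ari = adjusted_rand_index(
            [full.labels[q] for q in corr.queries], km2d.labels_
        )
        assert ari >= 0.9

    def test_too_few_queries_rejected(self):
        rng = np.random.default_rng(9)
        m = _matrix(rng.normal(size=(2, 50)))
        corr = correlate_profiles(m, min_shared=10)
        with pytest.raises(EmapValidationError):
            pca_correlations(corr)
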