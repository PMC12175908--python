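"""Segment features, PCA/UMAP embedding, graph clustering, validation, Rg."""

import numpy as np
import pytest

from idpre.ensemble import Ensemble
from idpre.landscape import (
    cluster_conformations,
    cluster_contributions,
    embed_umap,
    kmeans_on_embedding,
    radius_of_gyration,
    reduce_pca,
    segment_features,
    segment_pairs,
    segment_windows,
    validate_clustering,
    weighted_quantile,
    EmbeddingModel,
)


class TestSegmentScheme:
    def test_default_chain_gives_2775_features(self):
        windows = segment_windows(311)
        assert len(windows) == 78  # final partial window retained
        assert windows[-1] == (308, 311)
        assert len(segment_pairs(78)) == 2775

    def test_short_chain_has_no_retained_pairs(self):
        assert len(segment_pairs(len(segment_windows(16)))) == 0

    def test_forty_residue_chain(self):
        assert len(segment_pairs(len(segment_windows(40)))) == 21

    def test_pair_count_formula_vs_brute_force(self):
        for n in range(4, 101):
            brute = sum(
                1 for a in range(n) for b in range(a + 4, n)
            )
            assert len(segment_pairs(n)) == brute
            assert brute == n * (n - 1) // 2 - (3 * n - 6)

    def test_chain_shorter_than_window_errors(self):
        with pytest.raises(ValueError):
            segment_windows(3)

    def test_features_match_brute_force(self):
        rng = np.random.default_rng(8)
        coords = rng.uniform(0, 50, size=(5, 41, 3))
        ens = Ensemble(chains={"A": coords})
        fs = segment_features(ens, "A")
        for f in range(5):
            for p, (a, b) in enumerate(fs.pairs):
                sa, ea = fs.windows[a]
                sb, eb = fs.windows[b]
                d = np.linalg.norm(
                    coords[f, sa:ea, None, :] - coords[f, None, sb:eb, :], axis=-1
                ).min()
                assert fs.features[f, p] == pytest.approx(d)


class TestPCA:
    def test_planar_data_rank_deficiency(self):
        rng = np.random.default_rng(0)
        basis = rng.normal(size=(2, 10))
        x = rng.normal(size=(50, 2)) @ basis
        model = reduce_pca(x, n_components=6)
        assert model.explained_variance[2:].max() < 1e-20
        assert np.all(np.diff(model.explained_variance) <= 1e-12)

    def test_constant_features_dropped(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(30, 5))
        x[:, 2] = 7.0
        model = reduce_pca(x, n_components=4)
        assert 2 not in model.kept_features

    def test_nested_projection_errors(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(60, 20))
        m50 = reduce_pca(x, n_components=15)
        m10 = reduce_pca(x, n_components=5)
        err = lambda m: np.sum(  # noqa: E731
            (x - x.mean(0) - m.pc_coords @ m.pca.components_) ** 2
        )
        assert err(m50) <= err(m10) + 1e-9


def two_blob_features(n_per=60, dim=12, sep=50.0, seed=0):
    rng = np.random.default_rng(seed)
    a = rng.normal(size=(n_per, dim))
    b = rng.normal(size=(n_per, dim))
    b[:, 0] += sep
    labels = np.array([0] * n_per + [1] * n_per)
    return np.vstack([a, b]), labels


class TestUMAP:
    def test_two_blobs_separate_in_embedding(self):
        x, labels = two_blob_features()
        model = reduce_pca(x, n_components=5)
        model = embed_umap(model, subsample_fraction=0.5, seed=3)
        e = model.embedding
        centers = np.array([e[labels == k].mean(axis=0) for k in (0, 1)])
        inter = np.linalg.norm(centers[0] - centers[1])
        intra = max(
            np.percentile(np.linalg.norm(e[labels == k] - centers[k], axis=1), 95)
            for k in (0, 1)
        )
        assert inter > intra

    def test_deterministic_under_seed(self):
        x, _ = two_blob_features(n_per=60)
        m1 = embed_umap(reduce_pca(x, 5), subsample_fraction=0.9, seed=7)
        m2 = embed_umap(reduce_pca(x, 5), subsample_fraction=0.9, seed=7)
        assert np.array_equal(m1.embedding, m2.embedding)

    def test_training_frames_keep_fitted_coordinates(self):
        x, _ = two_blob_features(n_per=60)
        model = embed_umap(reduce_pca(x, 5), subsample_fraction=0.6, seed=1)
        assert model.train_idx is not None
        # training coordinates come straight from the fitted embedding
        refit = model.reducer.embedding_
        assert np.allclose(model.embedding[model.train_idx], refit)


class TestClustering:
    def test_two_blobs_give_two_clusters_matching_truth(self):
        x, labels = two_blob_features()
        model = reduce_pca(x, n_components=5)
        assignment = cluster_conformations(model, seed=0)
        assert assignment.n_clusters == 2
        report = validate_clustering(assignment.labels, labels, n_shuffles=10)
        assert report.ari == pytest.approx(1.0)

    def test_identical_frames_single_cluster(self):
        model = reduce_pca(np.full((40, 6), 3.7), n_components=2)
        assignment = cluster_conformations(model, seed=0)
        assert assignment.n_clusters == 1

    def test_deterministic_under_seed(self):
        x, _ = two_blob_features(n_per=50, sep=8.0)
        model = reduce_pca(x, 5)
        a1 = cluster_conformations(model, seed=4).labels
        a2 = cluster_conformations(model, seed=4).labels
        assert np.array_equal(a1, a2)


class TestContributions:
    def test_uniform_weights_equal_cluster_sizes(self):
        from idpre.landscape import ClusterAssignment

        assignment = ClusterAssignment(np.repeat([0, 1, 2, 3], 5), "test")
        df = cluster_contributions(assignment, np.full(20, 0.05))
        assert np.allclose(df["contribution"], 0.25)

    def test_all_weight_in_one_cluster(self):
        from idpre.landscape import ClusterAssignment

        w = np.zeros(10)
        w[3] = 1.0
        assignment = ClusterAssignment(np.repeat([0, 1], 5), "test")
        df = cluster_contributions(assignment, w)
        assert df["contribution"].iloc[0] == pytest.approx(1.0)
        assert int(df["top"].sum()) == 1

    def test_contributions_sum_to_one_for_any_weights(self):
        from idpre.landscape import ClusterAssignment

        rng = np.random.default_rng(6)
        w = rng.dirichlet(np.ones(30))
        assignment = ClusterAssignment(rng.integers(0, 5, size=30), "test")
        df = cluster_contributions(assignment, w)
        assert df["contribution"].sum() == pytest.approx(1.0)


class TestValidation:
    def test_identical_partitions_score_one(self):
        labels = np.repeat([0, 1, 2], 20)
        r = validate_clustering(labels, labels, n_shuffles=50, seed=0)
        assert r.ari == pytest.approx(1.0)
        assert r.ami == pytest.approx(1.0)

    def test_null_mean_near_zero(self):
        rng = np.random.default_rng(0)
        a = rng.integers(0, 4, size=600)
        b = rng.integers(0, 4, size=600)
        r = validate_clustering(a, b, n_shuffles=1000, seed=1)
        # chance-corrected index has zero expectation under permutation
        se = r.null_ari_sd / np.sqrt(r.n_shuffles)
        assert abs(r.null_ari_mean) < 3 * se + 1e-4

    def test_degenerate_single_cluster_flagged(self):
        r = validate_clustering(np.zeros(10), np.repeat([0, 1], 5), n_shuffles=5)
        assert r.degenerate
        assert np.isnan(r.ari)


class TestRadiusOfGyration:
    def test_coincident_points_zero(self):
        ens = Ensemble(chains={"A": np.zeros((3, 7, 3))})
        rg, _ = radius_of_gyration(ens)
        assert np.allclose(rg, 0.0)

    def test_two_equal_masses_half_distance(self):
        coords = np.zeros((1, 2, 3))
        coords[0, 1, 0] = 6.0
        ens = Ensemble(chains={"A": coords})
        rg, _ = radius_of_gyration(ens)
        assert rg[0] == pytest.approx(3.0)

    def test_weighted_mean_uses_weights(self):
        coords = np.zeros((2, 2, 3))
        coords[0, 1, 0] = 2.0   # Rg 1
        coords[1, 1, 0] = 10.0  # Rg 5
        ens = Ensemble(chains={"A": coords})
        _, summ = radius_of_gyration(ens, weights=np.array([0.75, 0.25]))
        assert summ["all"]["mean"] == pytest.approx(0.75 * 1 + 0.25 * 5)

    def test_empty_selection_errors(self):
        ens = Ensemble(chains={"A": np.zeros((1, 2, 3))})
        with pytest.raises(ValueError):
            radius_of_gyration(ens, chains=[])


def test_weighted_quantile_matches_numpy_for_uniform_weights():
    rng = np.random.default_rng(2)
    x = rng.normal(size=501)
    w = np.full(501, 1 / 501)
    for q in (0.25, 0.5, 0.75):
        assert weighted_quantile(x, w, q)[0] == pytest.approx(
            np.quantile(x, q), abs=0.02
        )
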