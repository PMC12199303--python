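"""t-SNE clustering protocol: conditionals, embedding, silhouettes, scan."""

import numpy as np
import pytest

import idpens as ip
from idpens.clustering import _euclidean


def _blob_distance_matrix(seed=0, sizes=(50, 50), sep=10.0):
    """Euclidean distance matrix of planted 2-D Gaussian blobs."""
    rng = np.random.default_rng(seed)
    pts = np.concatenate([rng.normal(i * sep, 1.0, size=(n, 2))
                          for i, n in enumerate(sizes)])
    d = _euclidean(pts)
    labels = np.repeat(np.arange(len(sizes)), sizes)
    return ip.DistanceMatrix(d, np.array(["x"] * len(labels)),
                             np.arange(len(labels))), labels


class TestDistanceMatrix:
    def test_duplicate_frame_zero_distance(self, coil_ensemble):
        ens, _ = coil_ensemble
        dup = ens.subset(np.array([0, 0, 1]), renormalize=True)
        dm = ip.rmsd_matrix(dup)
        assert dm.values[0, 1] < 1e-9
        assert dm.values[0, 2] > 0.01

    def test_rigid_copy_zero_distance(self, coil_ensemble):
        from idpens import _geometry as g
        ens, _ = coil_ensemble
        rng = np.random.default_rng(0)
        two = ens.subset(np.array([0, 0]))
        moved = two.coordinates.copy()
        moved[1] = moved[1] @ g.random_rotation(rng).T + rng.normal(size=3)
        two = ip.Ensemble(two.topology, moved)
        dm = ip.rmsd_matrix(two)
        assert dm.values[0, 1] < 1e-6

    def test_symmetry_and_diagonal(self, planted_families):
        helical, extended, _ = planted_families
        dm = ip.rmsd_matrix([helical.subset(np.arange(10)),
                             extended.subset(np.arange(10))], ["h", "e"])
        assert np.allclose(dm.values, dm.values.T)
        assert np.allclose(np.diag(dm.values), 0.0)

    def test_mismatched_chain_lengths_rejected(self):
        a = ip.build_ideal_helix(10)
        b = ip.build_ideal_helix(12)
        with pytest.raises(ValueError):
            ip.rmsd_matrix([a, b], ["a", "b"])


class TestDownsample:
    def test_identity_when_target_equals_frames(self, coil_ensemble):
        ens, _ = coil_ensemble
        sub, idx = ip.downsample(ens, ens.n_frames)
        assert np.array_equal(idx, np.arange(ens.n_frames))

    def test_stride_deterministic_random_seeded(self, coil_ensemble):
        ens, _ = coil_ensemble
        _, i1 = ip.downsample(ens, 10, mode="stride")
        _, i2 = ip.downsample(ens, 10, mode="stride")
        assert np.array_equal(i1, i2)
        _, r1 = ip.downsample(ens, 10, seed=3, mode="random")
        _, r2 = ip.downsample(ens, 10, seed=3, mode="random")
        assert np.array_equal(r1, r2)

    def test_oversampling_rejected(self, coil_ensemble):
        ens, _ = coil_ensemble
        with pytest.raises(ValueError):
            ip.downsample(ens, ens.n_frames + 1)


class TestConditionals:
    def test_simplex_symmetry_forces_uniform(self):
        # 4 mutually equidistant points: p(j|i) = 1/3 regardless of sigma
        d = np.ones((4, 4)) - np.eye(4)
        dm = ip.DistanceMatrix(d, np.array(["x"] * 4), np.arange(4))
        model = ip.calibrate_conditionals(dm, perplexity=3.0)
        off = model.conditional[~np.eye(4, dtype=bool)]
        np.testing.assert_allclose(off, 1 / 3, atol=1e-12)

    def test_entropy_matches_perplexity(self):
        dm, _ = _blob_distance_matrix()
        model = ip.calibrate_conditionals(dm, perplexity=15.0)
        np.testing.assert_allclose(model.entropy_bits, np.log2(15.0),
                                   atol=1e-5)

    def test_joint_matrix_contracts(self):
        dm, _ = _blob_distance_matrix(seed=1)
        model = ip.calibrate_conditionals(dm, perplexity=10.0)
        np.testing.assert_allclose(model.conditional.sum(1), 1.0, atol=1e-12)
        assert model.joint.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.allclose(model.joint, model.joint.T)
        assert np.allclose(np.diag(model.conditional), 0.0)

    def test_perplexity_out_of_range_rejected(self):
        dm, _ = _blob_distance_matrix()
        with pytest.raises(ValueError):
            ip.calibrate_conditionals(dm, perplexity=0.5)
        with pytest.raises(ValueError):
            ip.calibrate_conditionals(dm, perplexity=200.0)


class TestEmbedding:
    def test_kl_nonnegative_and_improving(self):
        dm, _ = _blob_distance_matrix(seed=2)
        model = ip.calibrate_conditionals(dm, 15.0)
        emb = ip.tsne_embed(model, seed=0, n_iter=400, exaggeration_iter=100)
        assert emb.kl >= 0.0
        # post-exaggeration trend: final KL not worse than iteration 150
        assert emb.kl_trace[-1] <= emb.kl_trace[150] + 1e-6

    def test_deterministic_under_seed(self):
        dm, _ = _blob_distance_matrix(seed=3, sizes=(25, 25))
        model = ip.calibrate_conditionals(dm, 10.0)
        a = ip.tsne_embed(model, seed=5, n_iter=150, exaggeration_iter=50)
        b = ip.tsne_embed(model, seed=5, n_iter=150, exaggeration_iter=50)
        assert np.array_equal(a.coordinates, b.coordinates)

    def test_planted_blobs_linearly_separable(self):
        dm, labels = _blob_distance_matrix(seed=4, sizes=(100, 100), sep=20.0)
        model = ip.calibrate_conditionals(dm, 30.0)
        emb = ip.tsne_embed(model, seed=0, n_iter=500, exaggeration_iter=125)
        # nearest-centroid classification in the embedding is error-free
        c0 = emb.coordinates[labels == 0].mean(0)
        c1 = emb.coordinates[labels == 1].mean(0)
        d0 = np.linalg.norm(emb.coordinates - c0, axis=1)
        d1 = np.linalg.norm(emb.coordinates - c1, axis=1)
        assert np.array_equal((d1 < d0).astype(int), labels)


class TestKMeans:
    def test_two_blob_recovery(self):
        dm, labels = _blob_distance_matrix(seed=5, sizes=(40, 40))
        pts = np.concatenate([np.zeros((40, 2)), np.full((40, 2), 5.0)])
        pts += np.random.default_rng(0).normal(0, 0.2, pts.shape)
        got = ip.kmeans_partition(pts, 2, seed=0)
        agree = max((got == labels).mean(), (got != labels).mean())
        assert agree == 1.0

    def test_n_equals_points_zero_inertia(self):
        pts = np.random.default_rng(1).normal(size=(6, 2))
        labels = ip.kmeans_partition(pts, 6, seed=0)
        assert len(set(labels)) == 6

    def test_seed_reproducibility(self):
        pts = np.random.default_rng(2).normal(size=(30, 2))
        assert np.array_equal(ip.kmeans_partition(pts, 3, seed=4),
                              ip.kmeans_partition(pts, 3, seed=4))


def brute_force_silhouette(labels, D):
    """Independent O(n^2) double-loop silhouette."""
    n = len(labels)
    out = np.zeros(n)
    for i in range(n):
        same = [j for j in range(n) if labels[j] == labels[i] and j != i]
        if not same:
            continue
        a = sum(D[i, j] for j in same) / len(same)
        b = min(np.mean([D[i, j] for j in range(n) if labels[j] == c])
                for c in set(labels) if c != labels[i])
        out[i] = (b - a) / max(a, b)
    return out


class TestSilhouette:
    def test_two_tight_pairs_perfect_score(self):
        D = np.array([[0, 0, 5, 5], [0, 0, 5, 5],
                      [5, 5, 0, 0], [5, 5, 0, 0]], dtype=float)
        _, mean = ip.silhouette_from_distances(np.array([0, 0, 1, 1]), D)
        assert mean == pytest.approx(1.0)

    def test_random_labels_near_zero(self):
        rng = np.random.default_rng(6)
        pts = rng.normal(size=(120, 2))
        D = _euclidean(pts)
        labels = rng.integers(0, 3, 120)
        _, mean = ip.silhouette_from_distances(labels, D)
        assert abs(mean) < 0.1

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        for n, k in ((30, 2), (80, 4), (150, 5)):
            pts = rng.normal(size=(n, 2)) + rng.integers(0, 3, (n, 1)) * 2.0
            D = _euclidean(pts)
            labels = rng.integers(0, k, n)
            if len(set(labels.tolist())) < 2:
                continue
            per, _ = ip.silhouette_from_distances(labels, D)
            np.testing.assert_allclose(per, brute_force_silhouette(labels, D),
                                       atol=1e-12)

    def test_matches_sklearn(self):
        from sklearn.metrics import silhouette_samples
        rng = np.random.default_rng(8)
        pts = rng.normal(size=(60, 2))
        D = _euclidean(pts)
        labels = rng.integers(0, 3, 60)
        per, _ = ip.silhouette_from_distances(labels, D)
        np.testing.assert_allclose(
            per, silhouette_samples(D, labels, metric="precomputed"),
            atol=1e-10)

    def test_single_cluster_rejected(self):
        with pytest.raises(ValueError):
            ip.silhouette_from_distances(np.zeros(5, int), np.zeros((5, 5)))


class TestIntegratedScore:
    def test_perfect_clustering_both_spaces(self):
        D = np.kron(np.array([[0.0, 5.0], [5.0, 0.0]]), np.ones((3, 3)))
        np.fill_diagonal(D, 0.0)
        dm = ip.DistanceMatrix(D, np.array(["x"] * 6), np.arange(6))
        Y = np.concatenate([np.zeros((3, 2)), np.full((3, 2), 4.0)])
        Y += np.random.default_rng(0).normal(0, 1e-3, Y.shape)
        labels = np.array([0, 0, 0, 1, 1, 1])
        s_ld, s_hd, s_i = ip.integrated_silhouette(labels, Y, dm)
        assert s_i == pytest.approx(s_ld * s_hd)
        assert s_i > 0.95

    def test_structurally_unclustered_data_drags_score_down(self):
        # good embedding clusters, but flat high-dimensional distances
        rng = np.random.default_rng(9)
        n = 40
        D = np.full((n, n), 3.0) + rng.normal(0, 0.01, (n, n))
        D = (D + D.T) / 2
        np.fill_diagonal(D, 0.0)
        dm = ip.DistanceMatrix(D, np.array(["x"] * n), np.arange(n))
        Y = np.concatenate([np.zeros((20, 2)), np.full((20, 2), 8.0)])
        labels = np.array([0] * 20 + [1] * 20)
        s_ld, s_hd, s_i = ip.integrated_silhouette(labels, Y, dm)
        assert s_ld > 0.9
        assert abs(s_hd) < 0.1
        assert s_i < 0.1

    def test_double_negative_flagged(self):
        rng = np.random.default_rng(10)
        pts = rng.normal(size=(20, 2))
        D = _euclidean(pts)
        dm = ip.DistanceMatrix(D, np.array(["x"] * 20), np.arange(20))
        # adversarial labels: points paired across blobs
        labels = np.arange(20) % 2
        s_ld, s_hd, s_i = ip.integrated_silhouette(labels, pts, dm)
        if s_ld < 0 and s_hd < 0:
            assert s_i > 0  # documented pitfall: flagged by warning


class TestScan:
    def test_argmax_contract_and_determinism(self):
        dm, _ = _blob_distance_matrix(seed=11, sizes=(30, 30))
        kw = {"n_iter": 200, "exaggeration_iter": 60}
        best, table = ip.hyperparameter_scan(dm, [10.0, 20.0], [2, 3],
                                             seed=0, tsne_kwargs=kw)
        assert best.integrated_score == pytest.approx(
            table["integrated_score"].max())
        _, table2 = ip.hyperparameter_scan(dm, [10.0, 20.0], [2, 3],
                                           seed=0, tsne_kwargs=kw)
        assert table.equals(table2)

    def test_empty_grids_rejected(self):
        dm, _ = _blob_distance_matrix(seed=12, sizes=(10, 10))
        with pytest.raises(ValueError):
            ip.hyperparameter_scan(dm, [], [2])


def test_permutation_equivariance(planted_families):
    """Permuting input frames permutes cluster labels accordingly."""
    helical, extended, _ = planted_families
    sub_h = helical.subset(np.arange(30))
    sub_e = extended.subset(np.arange(30))
    dm = ip.rmsd_matrix([sub_h, sub_e], ["h", "e"])
    rng = np.random.default_rng(13)
    perm = rng.permutation(60)
    dm_p = ip.DistanceMatrix(dm.values[np.ix_(perm, perm)],
                             dm.sources[perm], dm.frame_indices[perm])
    kw = {"n_iter": 250, "exaggeration_iter": 80}
    a = ip.cluster_model(dm, 2.0 + 10, 2, seed=0, tsne_kwargs=kw)
    b = ip.cluster_model(dm_p, 2.0 + 10, 2, seed=0, tsne_kwargs=kw)
    # label identities may swap; partition structure must match
    same_a = a.labels[:, None] == a.labels[None, :]
    same_b = b.labels[:, None] == b.labels[None, :]
    agreement = (same_a[np.ix_(perm, perm)] == same_b).mean()
    assert agreement > 0.9


def test_cluster_report_single_source_consistency(liganded_ensemble):
    ens, _ = liganded_ensemble
    dm = ip.rmsd_matrix([ens], ["only"])
    model = ip.cluster_model(dm, 8.0, 2, seed=0,
                             tsne_kwargs={"n_iter": 200,
                                          "exaggeration_iter": 60})
    report = ip.cluster_report({"only": ens}, model, dm)
    assert list(report.columns) == ["Cluster", "source", "p", "BF",
                                    "p_Glob", "HF"]
    merged = report[report["source"] == "merged"]
    single = report[report["source"] == "only"]
    # single-source merge: per-source equals merged
    for col in ("p", "BF", "p_Glob", "HF"):
        np.testing.assert_allclose(
            merged[col].astype(float).to_numpy(),
            single[col].astype(float).to_numpy(), atol=1e-9)
    assert merged["p"].astype(float).sum() == pytest.approx(1.0)
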