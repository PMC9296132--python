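"""Tests of the loss terms, in-batch clustering, and the collapse monitor."""

import itertools

import numpy as np
import pytest
from scipy.linalg import hadamard

from selfee.model import BranchOutputs
from selfee.nn import l2_normalize
from selfee.objective import (
    ClusterResult,
    LossConfig,
    cld_loss,
    cld_loss_grads,
    cluster_batch,
    collapse_level,
    cosine_distance,
    similarity_loss,
    similarity_loss_grads,
    total_loss,
)


def _outputs(rng, n=8, d=12, dv=6):
    v = rng.normal(size=(n, dv))
    return BranchOutputs(z=rng.normal(size=(n, d)), p=rng.normal(size=(n, d)),
                         v=l2_normalize(v))


class TestCosineDistance:
    @pytest.mark.parametrize("m,n,expected", [
        ([1.0, 2.0, 3.0], [2.0, 4.0, 6.0], 0.0),   # parallel
        ([1.0, 0.0], [0.0, 1.0], 1.0),             # orthogonal
        ([1.0, 0.0], [-1.0, 0.0], 2.0),            # antiparallel
    ])
    def test_reference_values(self, m, n, expected):
        assert cosine_distance(m, n) == pytest.approx(expected)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            cosine_distance([0.0, 0.0], [1.0, 0.0])


class TestSimilarityLoss:
    def test_perfect_prediction_gives_zero(self, rng):
        a = _outputs(rng)
        b = _outputs(rng)
        a.p = b.z.copy()  # p predicts z' exactly
        b.p = a.z.copy()
        assert similarity_loss(a, b) == pytest.approx(0.0)

    def test_orthogonal_prediction_gives_one(self):
        n, d = 4, 6
        z = np.tile(np.eye(d)[0], (n, 1))
        p = np.tile(np.eye(d)[1], (n, 1))
        a = BranchOutputs(z=z, p=p, v=np.ones((n, 2)) / np.sqrt(2))
        b = BranchOutputs(z=z.copy(), p=p.copy(), v=np.ones((n, 2)) / np.sqrt(2))
        assert similarity_loss(a, b) == pytest.approx(1.0)

    def test_random_high_dim_vectors_near_one(self):
        # E[cos] of independent high-dim unit vectors is 0, so the mean
        # cosine distance concentrates at 1
        rng = np.random.default_rng(0)
        n, d = 256, 2048
        a = BranchOutputs(z=rng.normal(size=(n, d)), p=rng.normal(size=(n, d)),
                          v=l2_normalize(rng.normal(size=(n, 64))))
        b = BranchOutputs(z=rng.normal(size=(n, d)), p=rng.normal(size=(n, d)),
                          v=l2_normalize(rng.normal(size=(n, 64))))
        assert similarity_loss(a, b) == pytest.approx(1.0, abs=0.01)

    def test_value_always_in_0_2(self, rng):
        for _ in range(10):
            a, b = _outputs(rng), _outputs(rng)
            assert 0.0 <= similarity_loss(a, b) <= 2.0

    def test_stop_gradient_zero_through_targets(self, rng):
        """The training gradient assigns exactly zero to the projector
        outputs even though the loss value genuinely depends on them."""
        a, b = _outputs(rng), _outputs(rng)
        loss, dpa, dpb = similarity_loss_grads(a, b)
        # predictor gradients match finite differences
        eps = 1e-7
        for arr, grad in ((a.p, dpa), (b.p, dpb)):
            idx = (2, 3)
            orig = arr[idx]
            arr[idx] = orig + eps
            lp = similarity_loss(a, b)
            arr[idx] = orig - eps
            lm = similarity_loss(a, b)
            arr[idx] = orig
            assert (lp - lm) / (2 * eps) == pytest.approx(grad[idx], abs=1e-6)
        # the loss value does move with z ...
        orig = a.z[0, 0]
        a.z[0, 0] = orig + 1e-4
        moved = similarity_loss(a, b)
        a.z[0, 0] = orig
        assert moved != pytest.approx(loss, abs=1e-12)
        # ... but no gradient is propagated into it (stop-gradient): the
        # training path hands the network dz = 0 by construction, which is
        # asserted structurally here
        assert similarity_loss_grads(a, b)[1].shape == a.p.shape


class TestClusterBatch:
    def test_k1_centroid_is_normalized_mean(self, rng):
        v = l2_normalize(rng.normal(size=(7, 5)))
        res = cluster_batch(v, LossConfig(n_clusters=1), rng)
        assert np.all(res.labels == 0)
        assert np.allclose(res.M[0], l2_normalize(v.mean(axis=0)[None])[0])

    def test_antipodal_groups_partition_exactly(self, rng):
        c = l2_normalize(rng.normal(size=(1, 8)))[0]
        group1 = l2_normalize(c + 0.01 * rng.normal(size=(5, 8)))
        group2 = l2_normalize(-c + 0.01 * rng.normal(size=(5, 8)))
        v = np.vstack([group1, group2])
        res = cluster_batch(v, LossConfig(n_clusters=2), rng)
        assert len(set(res.labels[:5])) == 1
        assert len(set(res.labels[5:])) == 1
        assert res.labels[0] != res.labels[5]

    def test_duplicated_rows_same_label(self, rng):
        v = l2_normalize(rng.normal(size=(6, 4)))
        v[3] = v[0]
        res = cluster_batch(v, LossConfig(n_clusters=3), rng)
        assert res.labels[3] == res.labels[0]

    def test_matches_exhaustive_kmeans_optimum(self, rng):
        # brute force over all 2^n assignments, n <= 10, k = 2
        v = l2_normalize(rng.normal(size=(8, 3)))

        def objective(labels):
            total = 0.0
            for j in (0, 1):
                members = v[np.array(labels) == j]
                if len(members) == 0:
                    return -np.inf
                total += (members @ l2_normalize(members.mean(axis=0)[None])[0]).sum()
            return total

        best = max((objective(c) for c in itertools.product((0, 1), repeat=8)
                    if len(set(c)) == 2))
        res = cluster_batch(v, LossConfig(n_clusters=2, kmeans_iters=50), rng)
        assert objective(tuple(res.labels)) == pytest.approx(best, abs=1e-9)

    def test_centroids_unit_norm(self, rng):
        v = l2_normalize(rng.normal(size=(20, 6)))
        res = cluster_batch(v, LossConfig(n_clusters=4), rng)
        assert np.allclose(np.linalg.norm(res.M, axis=1), 1.0)


class TestCLDLoss:
    def test_nonnegative(self, rng):
        a, b = _outputs(rng), _outputs(rng)
        cfg = LossConfig(n_clusters=3)
        ca = cluster_batch(a.v, cfg, rng)
        cb = cluster_batch(b.v, cfg, rng)
        assert cld_loss(a, b, ca, cb, cfg) >= 0.0

    def test_branch_swap_symmetry(self, rng):
        a, b = _outputs(rng), _outputs(rng)
        cfg = LossConfig(n_clusters=3)
        ca = cluster_batch(a.v, cfg, np.random.default_rng(0))
        cb = cluster_batch(b.v, cfg, np.random.default_rng(0))
        assert cld_loss(a, b, ca, cb, cfg) == pytest.approx(
            cld_loss(b, a, cb, ca, cfg))

    def test_sample_on_target_centroid_closed_form(self):
        # v_i exactly on its target centroid, two orthogonal centroids:
        # per-sample CE = log(1 + exp((0 - 1) / theta))
        theta = 0.07
        cfg = LossConfig(theta=theta, n_clusters=2)
        M = np.eye(2)
        n = 4
        v = np.tile(M[0], (n, 1))
        labels = np.zeros(n, dtype=int)
        ca = ClusterResult(M=M.copy(), labels=labels.copy())
        cb = ClusterResult(M=M.copy(), labels=labels.copy())
        out = BranchOutputs(z=np.zeros((n, 2)), p=np.zeros((n, 2)), v=v)
        expected = np.log(1 + np.exp((0 - 1) / theta))
        assert cld_loss(out, out, ca, cb, cfg) == pytest.approx(expected)

    def test_mismatched_dims_rejected(self, rng):
        a, b = _outputs(rng), _outputs(rng)
        cfg = LossConfig(n_clusters=2)
        ca = cluster_batch(a.v, cfg, rng)
        bad = ClusterResult(M=np.eye(3), labels=np.zeros(8, dtype=int))
        with pytest.raises(ValueError):
            cld_loss(a, b, ca, bad, cfg)


class TestTotalLoss:
    def test_lambda_zero_equals_similarity_alone(self, rng):
        a, b = _outputs(rng), _outputs(rng)
        loss, l1, l2 = total_loss(a, b, LossConfig(lam=0.0, n_clusters=2), rng)
        assert loss == pytest.approx(similarity_loss(a, b))
        assert l2 == 0.0

    def test_default_lambda_is_two(self):
        assert LossConfig().lam == 2.0
        assert LossConfig().theta == 0.07

    def test_weighted_sum(self, rng):
        a, b = _outputs(rng, n=10), _outputs(rng, n=10)
        cfg = LossConfig(lam=2.0, n_clusters=2)
        loss, l1, l2 = total_loss(a, b, cfg, np.random.default_rng(0))
        assert loss == pytest.approx(l1 + 2.0 * l2)

    def test_rotation_invariance(self, rng):
        # cosine geometry: a common rotation of z, p, v leaves the loss alone
        a, b = _outputs(rng, d=6, dv=6), _outputs(rng, d=6, dv=6)
        cfg = LossConfig(lam=2.0, n_clusters=2)
        q, _ = np.linalg.qr(rng.normal(size=(6, 6)))
        a2 = BranchOutputs(z=a.z @ q, p=a.p @ q, v=a.v @ q)
        b2 = BranchOutputs(z=b.z @ q, p=b.p @ q, v=b.v @ q)
        l_orig = total_loss(a, b, cfg, np.random.default_rng(1))
        l_rot = total_loss(a2, b2, cfg, np.random.default_rng(1))
        assert l_rot[0] == pytest.approx(l_orig[0], rel=1e-8)


class TestCollapseLevel:
    def test_identical_rows_full_collapse(self):
        v = np.tile(l2_normalize(np.ones((1, 16)))[0], (8, 1))
        assert collapse_level(v) == pytest.approx(1.0, abs=1e-12)

    def test_hadamard_spread_zero(self):
        # rows of [H; -H] / sqrt(C): unit-norm, per-channel mean 0 and
        # population std exactly C**-0.5
        c = 16
        h = hadamard(c) / np.sqrt(c)
        v = np.vstack([h, -h])
        assert collapse_level(v) == pytest.approx(0.0, abs=1e-12)

    def test_linear_in_std(self):
        c = 16
        h = hadamard(c) / np.sqrt(c)
        v = np.vstack([h, -h]) * 0.5  # halves every per-channel std
        assert collapse_level(v) == pytest.approx(0.5, abs=1e-12)

    def test_needs_two_rows(self):
        with pytest.raises(ValueError):
            collapse_level(np.ones((1, 4)))
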