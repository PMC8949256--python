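"""Attention core of the texture transformer against brute-force oracles,
plus gradient checks of the autodiff engine."""

import numpy as np
import pytest

from ppgdenoise.exceptions import ContractError, ParameterError
from ppgdenoise.npd import autodiff as ad
from ppgdenoise.npd.autodiff import Tensor
from ppgdenoise.npd.network import (
    ModelConfig,
    NPDNet,
    downsample,
    hard_soft_attention,
    prepare_inputs,
    relevance_embedding,
    transfer_textures,
    upsample,
)


# ---------------------------------------------------------------------------
# Brute-force oracles

def brute_relevance(Q, K, p):
    """Double-loop normalized patch inner products."""
    C, Lq = Q.shape
    _, Lk = K.shape
    nq, nk = Lq - p + 1, Lk - p + 1
    rel = np.zeros((nq, nk))
    for i in range(nq):
        qi = Q[:, i:i + p].ravel()
        qi = qi / max(np.linalg.norm(qi), 1e-30)
        for j in range(nk):
            kj = K[:, j:j + p].ravel()
            kj = kj / max(np.linalg.norm(kj), 1e-30)
            rel[i, j] = qi @ kj
    return rel


def brute_transfer(V, H, p):
    """Gather V patches by H, scatter-add, divide by coverage counts."""
    C, L = V.shape
    n = len(H)
    out_len = n + p - 1
    acc = np.zeros((C, out_len))
    counts = np.zeros(out_len)
    for i, j in enumerate(H):
        acc[:, i:i + p] += V[:, j:j + p]
        counts[i:i + p] += 1
    return acc / counts


class TestRelevanceEmbedding:
    def test_self_similarity_diagonal_is_one(self):
        rng = np.random.default_rng(0)
        Q = rng.normal(size=(4, 20))
        rel = relevance_embedding(Q, Q, patch_size=3)
        np.testing.assert_allclose(np.diag(rel), 1.0, atol=1e-12)

    def test_orthogonal_patches_score_zero(self):
        Q = np.zeros((2, 3))
        K = np.zeros((2, 3))
        Q[0, :] = [1.0, 0.0, 0.0]
        K[1, :] = [0.0, 1.0, 0.0]
        rel = relevance_embedding(Q, K, patch_size=3)
        np.testing.assert_allclose(rel, 0.0, atol=1e-12)

    def test_entries_bounded_by_one(self):
        rng = np.random.default_rng(1)
        rel = relevance_embedding(rng.normal(size=(8, 40)),
                                  rng.normal(size=(8, 32)), patch_size=3)
        assert np.all(np.abs(rel) <= 1.0 + 1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        Q = rng.normal(size=(3, 32))
        K = rng.normal(size=(3, 24))
        rel = relevance_embedding(Q, K, patch_size=3)
        np.testing.assert_allclose(rel, brute_relevance(Q, K, 3), atol=1e-6)

    def test_patch_longer_than_features_rejected(self):
        with pytest.raises(ParameterError):
            relevance_embedding(np.zeros((2, 4)), np.zeros((2, 4)),
                                patch_size=5)


class TestHardSoftAttention:
    def test_identity_like_matrix(self):
        rel = np.full((5, 5), 0.2)
        np.fill_diagonal(rel, 1.0)
        maps = hard_soft_attention(rel)
        np.testing.assert_array_equal(maps.H, np.arange(5))
        np.testing.assert_allclose(maps.S, 1.0)

    def test_tie_breaks_to_lowest_index(self):
        rel = np.full((3, 7), 0.5)
        maps = hard_soft_attention(rel)
        np.testing.assert_array_equal(maps.H, 0)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_scan(self, seed):
        rng = np.random.default_rng(seed)
        rel = rng.normal(size=(20, 30))
        maps = hard_soft_attention(rel)
        for i in range(20):
            j_best = max(range(30), key=lambda j: (rel[i, j], -j))
            assert maps.H[i] == j_best
            assert maps.S[i] == rel[i, j_best]

    def test_empty_matrix_rejected(self):
        with pytest.raises(ContractError):
            hard_soft_attention(np.zeros((0, 0)))


class TestTransferTextures:
    def test_identity_map_reconstructs_v(self):
        rng = np.random.default_rng(2)
        V = rng.normal(size=(4, 12))
        H = np.arange(12 - 3 + 1)
        T = transfer_textures(V, H, patch_size=3)
        np.testing.assert_allclose(T, V, atol=1e-12)

    def test_constant_v_gives_constant_t(self):
        V = np.full((2, 10), 0.7)
        H = np.random.default_rng(3).integers(0, 8, size=8)
        T = transfer_textures(V, H, patch_size=3)
        np.testing.assert_allclose(T, 0.7, atol=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_gather_average_oracle(self, seed):
        rng = np.random.default_rng(seed)
        V = rng.normal(size=(3, 8))
        H = rng.integers(0, 6, size=6)
        T = transfer_textures(V, H, patch_size=3)
        np.testing.assert_allclose(T, brute_transfer(V, H, 3), atol=1e-12)

    def test_out_of_range_index_rejected(self):
        with pytest.raises(ContractError):
            transfer_textures(np.zeros((2, 8)), np.array([99]), patch_size=3)


class TestPrepareInputs:
    def test_scale_one_round_trip_is_identity(self):
        rng = np.random.default_rng(4)
        noisy, ref = rng.normal(size=(2, 300))
        _, _, rdu, nup = prepare_inputs(noisy, ref, scale_factor=1)
        np.testing.assert_allclose(rdu, ref, atol=1e-12)
        np.testing.assert_allclose(nup, noisy, atol=1e-12)

    def test_all_outputs_aligned_to_input_length(self):
        rng = np.random.default_rng(5)
        outs = prepare_inputs(rng.normal(size=300), rng.normal(size=300), 4)
        assert all(len(o) == 300 for o in outs)

    def test_downsample_by_four_gives_75_samples(self):
        assert len(downsample(np.zeros(300), 4)) == 75

    def test_upsample_inverts_downsample_on_linear_signal(self):
        x = np.linspace(0, 1, 301)  # piecewise-linear is exactly recoverable
        np.testing.assert_allclose(upsample(downsample(x, 4), 4, 301), x,
                                   atol=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ContractError):
            prepare_inputs(np.zeros(300), np.zeros(299), 4)


class TestSharedEncoder:
    def test_identical_inputs_give_identical_q_and_k(self):
        net = NPDNet(ModelConfig(channels=4, levels=2, seed=0))
        x = np.random.default_rng(6).normal(size=(1, 1, 40))
        q = net.encode(Tensor(x)).data
        k = net.encode(Tensor(x)).data
        np.testing.assert_array_equal(q, k)

    def test_encoder_depends_on_weights(self):
        x = np.random.default_rng(7).normal(size=(1, 1, 40))
        a = NPDNet(ModelConfig(channels=4, levels=2, seed=0))
        b = NPDNet(ModelConfig(channels=4, levels=2, seed=1))
        assert not np.allclose(a.encode(Tensor(x)).data,
                               b.encode(Tensor(x)).data)

    def test_feature_length_tracks_input_length(self):
        net = NPDNet(ModelConfig(channels=4, levels=2, seed=0))
        for L in (20, 37, 300):
            x = np.zeros((1, 1, L))
            assert net.encode(Tensor(x)).data.shape == (1, 4, L)


class TestForwardContracts:
    def test_output_geometry_and_range(self, clean_segments):
        net = NPDNet(ModelConfig(channels=8, levels=2, seed=0))
        noisy = clean_segments[0].samples
        ref = clean_segments[1].samples
        out = net.denoise(noisy, ref)
        assert out.shape == (300,)
        assert out.min() >= -1.0 and out.max() <= 1.0

    def test_forward_is_pure(self, clean_segments):
        net = NPDNet(ModelConfig(channels=8, levels=2, seed=0))
        noisy = clean_segments[0].samples
        ref = clean_segments[1].samples
        assert np.array_equal(net.denoise(noisy, ref), net.denoise(noisy, ref))

    def test_soft_gate_zero_disables_transfer_branch(self):
        net = NPDNet(ModelConfig(channels=4, levels=2, seed=0))
        rng = np.random.default_rng(8)
        F = Tensor(rng.normal(size=(1, 4, 30)))
        T1 = Tensor(rng.normal(size=(1, 4, 30)))
        T2 = Tensor(rng.normal(size=(1, 4, 30)))
        S0 = Tensor(np.zeros((1, 1, 30)))
        out1 = net.fuse(F, T1, S0).data
        out2 = net.fuse(F, T2, S0).data
        np.testing.assert_array_equal(out1, out2)


class TestGradients:
    def test_analytic_gradients_match_numeric(self):
        """Central-difference check of d(loss)/d(weight) through the full
        forward pass, including the attention path."""
        cfg = ModelConfig(channels=3, levels=2, scale_factor=2, seed=0)
        net = NPDNet(cfg)
        rng = np.random.default_rng(9)
        noisy = rng.uniform(-0.8, 0.8, size=(2, 24))
        ref = rng.uniform(-0.8, 0.8, size=(2, 24))
        target = rng.uniform(-0.8, 0.8, size=(2, 24))

        def loss_value():
            restored, _ = net.forward(noisy, ref)
            return float(
                ad.mean_(ad.absval(ad.sub(restored, Tensor(target)))).data)

        restored, _ = net.forward(noisy, ref)
        loss = ad.mean_(ad.absval(ad.sub(restored, Tensor(target))))
        for p in net.params.values():
            p.zero_grad()
        loss.backward()

        eps = 1e-6
        checked = 0
        for name, p in net.params.items():
            flat = p.data.ravel()
            idxs = rng.choice(flat.size, size=min(3, flat.size), replace=False)
            for i in idxs:
                orig = flat[i]
                flat[i] = orig + eps
                up = loss_value()
                flat[i] = orig - eps
                down = loss_value()
                flat[i] = orig
                numeric = (up - down) / (2 * eps)
                analytic = p.grad.ravel()[i]
                denom = max(abs(numeric), abs(analytic), 1e-8)
                assert abs(numeric - analytic) / denom < 1e-3, \
                    f"gradient mismatch in {name}[{i}]"
                checked += 1
        assert checked >= 20
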