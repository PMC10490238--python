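"""CBAM attention against hand-computed oracles; encoder contracts."""

import numpy as np
import pytest

from sleepalign.autodiff import Tensor
from sleepalign.eeg_encoder import (CBAM, ChannelAttention, EEGEncoder,
                                    EncoderConfig, SpatialAttention,
                                    apply_channel_attention, channel_attention,
                                    encode_epochs, spatial_attention)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


class TestChannelAttention:
    def _hand_module(self, rng):
        # 2 channels, squeeze to 1 hidden unit, hand-set weights
        mod = ChannelAttention(2, 2, rng)
        mod.w0.w.data = np.array([[0.5], [-0.25]])
        mod.w0.b.data = np.array([0.1])
        mod.w1.w.data = np.array([[1.0, -2.0]])
        mod.w1.b.data = np.array([0.2, 0.3])
        return mod

    def test_matches_hand_computed_oracle(self, rng):
        mod = self._hand_module(rng)
        F = np.array([[[1.0, 2.0, 3.0], [-1.0, 0.0, 4.0]]])  # (1, 2, 3)
        got = channel_attention(F, mod)
        # brute-force evaluation: pool positions, shared squeeze/expand MLP
        # (ReLU between the layers), sum the two pooled scores, sigmoid
        avg = F.mean(axis=2)[0]
        mx = F.max(axis=2)[0]

        def mlp(v):
            h = np.maximum(v @ mod.w0.w.data + mod.w0.b.data, 0)
            return h @ mod.w1.w.data + mod.w1.b.data

        expected = _sigmoid(mlp(avg) + mlp(mx))
        assert got.shape == (1, 2, 1)
        assert np.allclose(got[0, :, 0], expected, atol=1e-12)

    def test_zero_input_gives_sigmoid_of_twice_mlp_at_zero(self, rng):
        mod = ChannelAttention(4, 2, rng)
        got = channel_attention(np.zeros((2, 4, 10)), mod)
        # avg and max pools agree on zeros, so the map is sigmoid(2*MLP(0))
        h = np.maximum(mod.w0.b.data, 0)
        mlp0 = h @ mod.w1.w.data + mod.w1.b.data
        assert np.allclose(got[0, :, 0], _sigmoid(2 * mlp0))
        assert np.allclose(got[0], got[1])

    def test_values_strictly_in_unit_interval(self, rng):
        mod = ChannelAttention(8, 4, rng)
        F = rng.normal(size=(1000, 8, 5))
        got = channel_attention(F, mod)
        assert np.all((got > 0) & (got < 1))

    def test_reduction_ratio_too_large_rejected(self, rng):
        with pytest.raises(ValueError, match="reduction_ratio"):
            ChannelAttention(4, 8, rng)


class TestApplyChannelAttention:
    def test_unit_map_is_identity(self, rng):
        F = rng.normal(size=(2, 3, 5))
        assert np.allclose(apply_channel_attention(F, np.ones((2, 3, 1))), F)

    def test_half_map_halves(self, rng):
        F = rng.normal(size=(2, 3, 5))
        assert np.allclose(apply_channel_attention(F, np.full((2, 3, 1), 0.5)),
                           F / 2)

    def test_elementwise_oracle(self, rng):
        F = rng.normal(size=(3, 4, 6))
        Mc = rng.uniform(0.01, 0.99, size=(3, 4, 1))
        out = apply_channel_attention(F, Mc)
        for i in range(3):
            for c in range(4):
                for t in range(6):
                    assert out[i, c, t] == Mc[i, c, 0] * F[i, c, t]

    def test_shape_mismatch_is_error(self, rng):
        with pytest.raises(ValueError):
            apply_channel_attention(rng.normal(size=(2, 3, 5)),
                                    rng.uniform(size=(2, 4, 1)))


class TestSpatialAttention:
    def test_matches_direct_convolution(self, rng):
        mod = SpatialAttention(7, rng)
        kernel = np.array([[0.2, -0.1, 0.4, 0.0, -0.3, 0.1, 0.25],
                           [-0.2, 0.3, 0.0, 0.1, 0.2, -0.1, 0.05]])
        mod.conv.w.data = kernel[None, :, :]
        mod.conv.b.data = np.array([0.12])
        F = rng.normal(size=(1, 1, 9))
        got = spatial_attention(F, mod)
        # brute force: channel-pool to (avg, max), width-7 same-pad convolution
        avg, mx = F.mean(axis=1)[0], F.max(axis=1)[0]
        padded = np.pad(np.stack([avg, mx]), ((0, 0), (3, 3)))
        expected = np.empty(9)
        for t in range(9):
            expected[t] = _sigmoid((padded[:, t:t + 7] * kernel).sum() + 0.12)
        assert got.shape == (1, 1, 9)
        assert np.allclose(got[0, 0], expected, atol=1e-12)

    def test_constant_input_constant_away_from_edges(self, rng):
        mod = SpatialAttention(7, rng)
        got = spatial_attention(np.full((1, 4, 30), 2.5), mod)
        interior = got[0, 0, 3:-3]
        assert np.allclose(interior, interior[0])

    def test_values_strictly_in_unit_interval(self, rng):
        mod = SpatialAttention(7, rng)
        got = spatial_attention(rng.normal(size=(1000, 3, 8)), mod)
        assert np.all((got > 0) & (got < 1))

    def test_too_short_position_axis_rejected(self, rng):
        mod = SpatialAttention(7, rng)
        with pytest.raises(ValueError, match="shorter"):
            spatial_attention(np.zeros((1, 2, 5)), mod)


class TestCBAM:
    def test_preserves_shape(self, rng):
        cbam = CBAM(8, 4, 7, rng)
        for shape in [(1, 8, 12), (3, 8, 40), (2, 8, 7)]:
            F = rng.normal(size=shape)
            assert cbam(Tensor(F)).shape == shape


class TestEncoderConfig:
    def test_receptive_windows_at_defaults(self):
        cfg = EncoderConfig()
        cfg.validate()
        assert cfg.small_window_s == pytest.approx(0.64)
        assert cfg.large_window_s == pytest.approx(5.12)


class TestEncodeEpochs:
    def test_embeddings_unit_norm(self, tiny_encoder_config, rng):
        enc = EEGEncoder(tiny_encoder_config, rng)
        batch = rng.normal(size=(5, 3000))
        S = encode_epochs(batch, enc)
        assert S.shape == (5, tiny_encoder_config.embed_dim)
        assert np.allclose(np.linalg.norm(S, axis=1), 1.0, atol=1e-5)

    def test_duplicate_epochs_get_identical_embeddings(self, tiny_encoder_config, rng):
        enc = EEGEncoder(tiny_encoder_config, rng)
        epoch = rng.normal(size=3000)
        S = encode_epochs(np.stack([epoch, epoch, rng.normal(size=3000)]), enc)
        assert np.array_equal(S[0], S[1])
        assert not np.array_equal(S[0], S[2])

    def test_batch_permutation_equivariance(self, tiny_encoder_config, rng):
        enc = EEGEncoder(tiny_encoder_config, rng)
        batch = rng.normal(size=(6, 3000))
        perm = rng.permutation(6)
        S = encode_epochs(batch, enc)
        S_perm = encode_epochs(batch[perm], enc)
        assert np.allclose(S[perm], S_perm, atol=1e-12)

    def test_wrong_epoch_length_rejected(self, tiny_encoder_config, rng):
        enc = EEGEncoder(tiny_encoder_config, rng)
        with pytest.raises(ValueError, match="3000"):
            encode_epochs(rng.normal(size=(2, 2999)), enc)
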