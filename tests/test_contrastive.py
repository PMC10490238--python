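"""Similarity, symmetric cross-entropy, training loop, and prediction."""

import numpy as np
import pytest

from sleepalign.autodiff import Tensor
from sleepalign.contrastive import (ContrastiveStager, TrainConfig,
                                    contrastive_loss, cosine_similarity,
                                    load_checkpoint, save_checkpoint,
                                    similarity_matrix, train)
from sleepalign.eeg_encoder import EncoderConfig
from sleepalign.io_edf import StageLabel
from sleepalign.label_encoder import TransformerConfig
from sleepalign.preprocess import EpochDataset, SignalEpoch


def _tiny_model(seed=0, steps=5):
    return ContrastiveStager(
        encoder_config=EncoderConfig(filters=8, reduction_ratio=4, embed_dim=16),
        transformer_config=TransformerConfig(layers=1, hidden_dim=8, heads=2,
                                             embed_dim=16),
        train_config=TrainConfig(steps=steps, seed=seed), seed=seed)


def _dataset(rng, n_per_stage=3):
    epochs = []
    for code in range(5):
        for _ in range(n_per_stage):
            # crude stage-specific structure: distinct dominant frequency
            t = np.arange(3000) / 100.0
            f = [10.0, 6.0, 13.0, 1.5, 2.5][code]
            sig = np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
            sig += 0.3 * rng.normal(size=3000)
            sig = (sig - sig.mean()) / sig.std()
            epochs.append(SignalEpoch(sig, StageLabel(code), 0))
    return EpochDataset(epochs)


class TestCosineSimilarity:
    def test_identical_vectors(self):
        v = np.array([1.0, 2.0, 3.0])
        assert cosine_similarity(v, v) == pytest.approx(1.0)

    def test_orthogonal_vectors(self):
        assert cosine_similarity([1, 0], [0, 1]) == pytest.approx(0.0)

    def test_hand_computed_value(self):
        # (1,2,2)·(2,1,2) / (3*3) = 8/9
        assert cosine_similarity([1, 2, 2], [2, 1, 2]) == pytest.approx(8 / 9)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            cosine_similarity([0, 0], [1, 0])


class TestSimilarityMatrix:
    def test_orthonormal_identity(self):
        S = np.eye(3)
        M = similarity_matrix(S, S, tau=1.0)
        assert np.allclose(M, np.eye(3))

    def test_single_pair(self):
        M = similarity_matrix([[1.0, 0.0]], [[0.0, 1.0]], tau=2.0)
        assert M.shape == (1, 1)
        assert M[0, 0] == pytest.approx(0.0)

    def test_elementwise_oracle(self, rng):
        S = rng.normal(size=(3, 4))
        L = rng.normal(size=(3, 4))
        tau = 3.7
        M = similarity_matrix(S, L, tau)
        for i in range(3):
            for j in range(3):
                assert M[i, j] == pytest.approx(
                    tau * cosine_similarity(S[i], L[j]), abs=1e-12)

    def test_empty_batch_rejected(self):
        with pytest.raises(ValueError):
            similarity_matrix(np.empty((0, 4)), np.empty((0, 4)), 1.0)

    def test_unit_inputs_bounded_by_tau(self, rng):
        for _ in range(1000):
            S = rng.normal(size=(2, 8))
            L = rng.normal(size=(2, 8))
            M = similarity_matrix(S, L, tau=1.0)
            assert np.all(np.abs(M) <= 1.0 + 1e-12)


class TestContrastiveLoss:
    def test_one_by_one_is_zero(self):
        assert contrastive_loss(np.array([[3.7]])) == pytest.approx(0.0)

    def test_dominant_diagonal_limit(self):
        M = np.full((4, 4), -50.0)
        np.fill_diagonal(M, 50.0)
        assert contrastive_loss(M) == pytest.approx(0.0, abs=1e-10)

    def test_hand_computed_2x2(self):
        # [[2,0],[0,2]]: both directions give -log(e^2/(e^2+1))
        M = np.array([[2.0, 0.0], [0.0, 2.0]])
        expected = -np.log(np.exp(2) / (np.exp(2) + 1))
        assert contrastive_loss(M) == pytest.approx(expected, abs=1e-12)

    def test_brute_force_oracle_random(self, rng):
        M = rng.normal(size=(4, 4)) * 3
        # independent softmax cross-entropy in both directions
        def direction(A):
            p = np.exp(A) / np.exp(A).sum(axis=1, keepdims=True)
            return -np.mean(np.log(np.diag(p)))
        expected = 0.5 * (direction(M) + direction(M.T))
        assert contrastive_loss(M) == pytest.approx(expected, abs=1e-9)

    def test_nonsquare_rejected(self, rng):
        with pytest.raises(ValueError):
            contrastive_loss(rng.normal(size=(2, 3)))

    def test_pair_relabeling_invariance(self, rng):
        M = rng.normal(size=(5, 5))
        for _ in range(10):
            perm = rng.permutation(5)
            assert contrastive_loss(M[np.ix_(perm, perm)]) == pytest.approx(
                contrastive_loss(M), abs=1e-12)

    def test_nonnegative(self, rng):
        for _ in range(50):
            assert contrastive_loss(rng.normal(size=(3, 3)) * 5) >= 0

    def test_gradient_matches_finite_differences(self, rng):
        M0 = rng.normal(size=(3, 3))
        Mt = Tensor(M0, requires_grad=True)
        contrastive_loss(Mt).backward()
        eps = 1e-6
        for i in range(3):
            for j in range(3):
                Mp, Mm = M0.copy(), M0.copy()
                Mp[i, j] += eps
                Mm[i, j] -= eps
                fd = (contrastive_loss(Mp) - contrastive_loss(Mm)) / (2 * eps)
                assert Mt.grad[i, j] == pytest.approx(fd, abs=1e-4)

    def test_multi_positive_mask_counts_all_positives(self, rng):
        M = rng.normal(size=(3, 3))
        mask = np.eye(3, dtype=bool)
        mask[0, 1] = mask[1, 0] = True  # rows 0 and 1 share a label
        got = contrastive_loss(M, positive_mask=mask)

        def direction(A, mk):
            e = np.exp(A - A.max(axis=1, keepdims=True))
            p = e / e.sum(axis=1, keepdims=True)
            return -np.mean(np.log((p * mk).sum(axis=1)))

        expected = 0.5 * (direction(M, mask) + direction(M.T, mask.T))
        assert got == pytest.approx(expected, abs=1e-9)


class TestTraining:
    def test_zero_steps_leaves_weights_unchanged(self, rng):
        model = _tiny_model(steps=0)
        before = {k: v.data.copy() for k, v in model.parameters().items()}
        result = train(_dataset(rng), model, TrainConfig(steps=0, seed=0))
        assert result.loss_trace.size == 0
        for k, v in model.parameters().items():
            assert np.array_equal(before[k], v.data)

    def test_same_seed_reproduces_loss_trace(self, rng):
        ds = _dataset(rng)
        m1 = _tiny_model(seed=3)
        t1 = train(ds, m1, TrainConfig(steps=15, seed=3)).loss_trace
        m2 = _tiny_model(seed=3)
        t2 = train(ds, m2, TrainConfig(steps=15, seed=3)).loss_trace
        assert np.array_equal(t1, t2)

    def test_loss_trend_decreases_on_separable_data(self, rng):
        ds = _dataset(rng, n_per_stage=6)
        model = _tiny_model(seed=0)
        trace = train(ds, model, TrainConfig(steps=120, seed=0)).loss_trace
        assert trace[-20:].mean() < trace[:20].mean()

    def test_missing_stage_named_in_error(self, rng):
        ds = _dataset(rng)
        ds = EpochDataset([ep for ep in ds.epochs if ep.label != StageLabel.N3])
        with pytest.raises(ValueError, match="N3"):
            train(ds, _tiny_model(), TrainConfig(steps=1, seed=0))


class TestPredict:
    def test_epoch_matching_prototype_is_recovered(self, rng):
        model = _tiny_model()
        protos = model.prototypes()
        # scores computed against prototypes: a synthetic score vector equal to
        # a prototype row must argmax at that row
        scores = protos @ protos.T
        assert scores[3].argmax() == 3

    def test_tie_break_goes_to_lowest_stage_code(self):
        scores = np.zeros((2, 5))
        assert scores.argmax(axis=1).tolist() == [0, 0]

    def test_predictions_elementwise(self, rng):
        model = _tiny_model()
        epochs = rng.normal(size=(6, 3000))
        codes_all, scores_all = model.predict(epochs)
        codes_one, scores_one = model.predict(epochs[2:3])
        assert codes_all[2] == codes_one[0]
        assert np.allclose(scores_all[2], scores_one[0], atol=1e-12)


class TestCheckpoint:
    def test_round_trip_preserves_weights_and_predictions(self, tmp_path, rng):
        ds = _dataset(rng)
        model = _tiny_model(seed=5)
        train(ds, model, TrainConfig(steps=10, seed=5))
        epochs = rng.normal(size=(4, 3000))
        codes, scores = model.predict(epochs)
        path = tmp_path / "model.npz"
        save_checkpoint(path, model)
        loaded = load_checkpoint(path)
        codes2, scores2 = loaded.predict(epochs)
        assert np.array_equal(codes, codes2)
        assert np.allclose(scores, scores2, atol=1e-12)
        assert loaded.tau == pytest.approx(model.tau)

    def test_non_checkpoint_rejected(self, tmp_path):
        path = tmp_path / "junk.npz"
        np.savez(path, meta='{"magic": "something-else"}')
        with pytest.raises(ValueError, match="checkpoint"):
            load_checkpoint(path)


def test_fixed_temperature_option():
    model = ContrastiveStager(
        encoder_config=EncoderConfig(filters=8, reduction_ratio=4, embed_dim=16),
        transformer_config=TransformerConfig(layers=1, hidden_dim=8, heads=2,
                                             embed_dim=16),
        train_config=TrainConfig(temperature="fixed:1.0"), seed=0)
    assert model.tau == 1.0
    assert "log_tau" not in model.parameters()
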