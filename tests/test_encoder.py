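"""Feature extractors, the modal discriminator, and the adversarial losses."""

import numpy as np
import pytest

from neurofuse import (DataError, ModalityBlock, RunConfig, adversarial_loss,
                       classification_loss, encoder_objective, extract_features,
                       inverted_targets)
from neurofuse.autodiff import Tensor
from neurofuse.encoder import Discriminator, ModalityExtractor


class FixedDisc:
    """Stub discriminator emitting preset probability rows (for exact anchors)."""

    def __init__(self, probs_per_modality):
        self.outputs = [np.asarray(p, dtype=float) for p in probs_per_modality]
        self.K = self.outputs[0].shape[1]
        self._i = 0

    def probs(self, emb):
        out = Tensor(self.outputs[self._i % len(self.outputs)])
        self._i += 1
        return out


def make_block(n, d, seed=0, name="m"):
    rng = np.random.default_rng(seed)
    return ModalityBlock(name, [f"S{i}" for i in range(n)],
                         rng.standard_normal((n, d)), [f"f{j}" for j in range(d)])


class TestExtractor:
    def test_zero_params_give_zero_embeddings(self):
        ext = ModalityExtractor("m", 3, 4, np.random.default_rng(0))
        for p in ext.params:
            p.data[:] = 0.0
        block = make_block(5, 3)
        np.testing.assert_array_equal(extract_features(ext, block), np.zeros((5, 4)))

    def test_leaky_relu_identity_on_positives(self):
        """Pass-through weights on a positive scalar input leave it unchanged."""
        ext = ModalityExtractor("m", 1, 1, np.random.default_rng(0))
        ext.W1.data = np.array([[1.0]])
        ext.b1.data[:] = 0.0
        ext.W2.data = np.array([[1.0]])
        ext.b2.data[:] = 0.0
        block = ModalityBlock("m", ["a", "b"], np.array([[2.0], [7.0]]), ["f0"])
        np.testing.assert_allclose(extract_features(ext, block), [[2.0], [7.0]])

    def test_forward_matches_hand_computation(self):
        ext = ModalityExtractor("m", 3, 2, np.random.default_rng(7))
        block = make_block(4, 3, seed=8)
        out = extract_features(ext, block)

        def lrelu(v):
            return np.where(v > 0, v, 0.01 * v)

        h = lrelu(block.features @ ext.W1.data + ext.b1.data)
        expected = lrelu(h @ ext.W2.data + ext.b2.data)
        np.testing.assert_allclose(out, expected, atol=1e-6)

    def test_dimension_mismatch(self):
        ext = ModalityExtractor("m", 3, 2, np.random.default_rng(0))
        with pytest.raises(DataError, match="features"):
            ext.embed(Tensor(np.zeros((2, 5))))


class TestInvertedTargets:
    def test_flip_at_two_modalities(self):
        z = np.array([[1.0, 0.0], [0.0, 1.0]])
        np.testing.assert_array_equal(inverted_targets(z),
                                      [[0.0, 1.0], [1.0, 0.0]])

    def test_uniform_over_wrong_at_four(self):
        z = np.zeros((1, 4))
        z[0, 2] = 1.0
        zh = inverted_targets(z)
        np.testing.assert_allclose(zh, [[1 / 3, 1 / 3, 0.0, 1 / 3]])
        assert zh.sum() == pytest.approx(1.0)
        assert (zh * z).sum() == 0.0

    def test_random_wrong_avoids_true_modality(self):
        rng = np.random.default_rng(0)
        z = np.tile(np.array([[0.0, 1.0, 0.0]]), (50, 1))
        zh = inverted_targets(z, "random_wrong", rng)
        assert (zh * z).sum() == 0.0
        np.testing.assert_array_equal(zh.sum(axis=1), np.ones(50))


class TestAdversarialLoss:
    def test_zero_at_perfect_true_label_discrimination(self):
        # two modalities, N=3 each; discriminator outputs exact one-hots
        disc = FixedDisc([np.tile([1.0, 0.0], (3, 1)), np.tile([0.0, 1.0], (3, 1))])
        embs = [Tensor(np.zeros((3, 2))), Tensor(np.zeros((3, 2)))]
        loss = adversarial_loss(disc, embs, use_inverted=False)
        assert float(loss.data) == pytest.approx(0.0, abs=1e-12)

    def test_uniform_output_half_per_modality(self):
        # K=2, N=1, output (0.5, 0.5): per-modality squared error 0.5, total 1.0
        disc = FixedDisc([np.array([[0.5, 0.5]]), np.array([[0.5, 0.5]])])
        embs = [Tensor(np.zeros((1, 2))), Tensor(np.zeros((1, 2)))]
        loss = adversarial_loss(disc, embs, use_inverted=False)
        assert float(loss.data) == pytest.approx(1.0, abs=1e-12)

    def test_inverted_label_penalizes_correctness_by_two(self):
        # perfect true-label outputs scored against flipped targets: 2.0/sample
        disc = FixedDisc([np.tile([1.0, 0.0], (4, 1)), np.tile([0.0, 1.0], (4, 1))])
        embs = [Tensor(np.zeros((4, 2))), Tensor(np.zeros((4, 2)))]
        loss = adversarial_loss(disc, embs, use_inverted=True)
        assert float(loss.data) == pytest.approx(4.0, abs=1e-12)  # 2.0 x K modalities

    def test_nonnegative_for_random_outputs(self):
        rng = np.random.default_rng(3)
        disc = Discriminator(4, 3, rng)
        embs = [Tensor(rng.standard_normal((6, 4))) for _ in range(3)]
        for inverted in (False, True):
            assert float(adversarial_loss(disc, embs, inverted).data) >= 0.0


class TestClassificationLoss:
    def _extractors(self, K=2, d=3, d_c=4, seed=0):
        rng = np.random.default_rng(seed)
        return [ModalityExtractor(f"m{k}", d, d_c, rng) for k in range(K)]

    def test_uniform_heads_give_ln2_per_modality(self):
        exts = self._extractors()
        for e in exts:
            e.Wh.data[:] = 0.0
            e.bh.data[:] = 0.0
        embs = [Tensor(np.zeros((5, 4))) for _ in exts]
        y = np.array([0, 1, 0, 1, 1])
        loss = classification_loss(exts, embs, y, np.arange(5), tau=0.0)
        assert float(loss.data) == pytest.approx(2 * np.log(2), abs=1e-12)

    def test_confident_correct_heads_give_near_zero(self):
        exts = self._extractors(K=1)
        y = np.array([0, 1, 0, 1])
        # craft logits +/-30 directly through the head on fixed embeddings
        emb = np.zeros((4, 4))
        emb[:, 0] = np.where(y == 1, 1.0, -1.0)
        exts[0].Wh.data[:] = 0.0
        exts[0].Wh.data[0, 1] = 30.0
        exts[0].Wh.data[0, 0] = -30.0
        exts[0].bh.data[:] = 0.0
        loss = classification_loss(exts, [Tensor(emb)], y, np.arange(4), tau=0.0)
        assert float(loss.data) < 1e-6

    def test_zero_weights_zero_penalty(self):
        exts = self._extractors()
        for e in exts:
            for p in e.params:
                p.data[:] = 0.0
        embs = [Tensor(np.zeros((2, 4))) for _ in exts]
        with_tau = classification_loss(exts, embs, np.array([0, 1]),
                                       np.arange(2), tau=0.5)
        without = classification_loss(exts, embs, np.array([0, 1]),
                                      np.arange(2), tau=0.0)
        assert float(with_tau.data) == pytest.approx(float(without.data), abs=1e-12)

    def test_empty_mask_rejected(self):
        exts = self._extractors()
        embs = [Tensor(np.zeros((2, 4))) for _ in exts]
        with pytest.raises(DataError, match="mask"):
            classification_loss(exts, embs, np.array([0, 1]), np.array([]), 0.0)


class TestEncoderObjective:
    def test_beta_zero_reduces_to_classification_loss(self, tiny_dataset):
        rng = np.random.default_rng(0)
        exts = [ModalityExtractor(b.name, b.n_features, 4, rng)
                for b in tiny_dataset.blocks]
        disc = Discriminator(4, 2, rng)
        embs = [e.embed(Tensor(b.features)) for e, b in zip(exts, tiny_dataset.blocks)]
        cfg = RunConfig(beta=0.0, tau=0.004)
        f_loss, d_loss = encoder_objective(exts, disc, embs, tiny_dataset.labels,
                                           np.arange(6), cfg)
        direct = classification_loss(exts, embs, tiny_dataset.labels,
                                     np.arange(6), cfg.tau)
        assert float(f_loss.data) == pytest.approx(float(direct.data), abs=1e-12)
        assert float(d_loss.data) >= 0.0

    def test_linear_combination_exact(self, tiny_dataset):
        rng = np.random.default_rng(1)
        exts = [ModalityExtractor(b.name, b.n_features, 4, rng)
                for b in tiny_dataset.blocks]
        disc = Discriminator(4, 2, rng)
        embs = [e.embed(Tensor(b.features)) for e, b in zip(exts, tiny_dataset.blocks)]
        cfg = RunConfig(beta=0.03)
        f_loss, _ = encoder_objective(exts, disc, embs, tiny_dataset.labels,
                                      np.arange(6), cfg)
        a = float(classification_loss(exts, embs, tiny_dataset.labels,
                                      np.arange(6), cfg.tau).data)
        b = float(adversarial_loss(disc, embs, use_inverted=True).data)
        assert float(f_loss.data) == pytest.approx(a + 0.03 * b, abs=1e-12)


class TestDiscriminatorLearning:
    def test_reduces_loss_on_frozen_embeddings(self):
        """On fixed, well-separated embeddings the discriminator's squared
        loss falls substantially within a few hundred Adam steps."""
        from neurofuse.autodiff import Adam, clip_global_norm

        rng = np.random.default_rng(0)
        offsets = [np.array([3.0, 0, 0, 0]), np.array([0, 3.0, 0, 0]),
                   np.array([0, 0, 3.0, 0])]
        embs = [Tensor(rng.standard_normal((60, 4)) + off) for off in offsets]
        disc = Discriminator(4, 3, rng)
        opt = Adam(disc.params, 0.001)
        first = None
        for step in range(400):
            opt.zero_grad()
            loss = adversarial_loss(disc, embs, use_inverted=False)
            loss.backward()
            clip_global_norm(disc.params, 5.0)
            opt.step()
            if first is None:
                first = float(loss.data)
        assert float(loss.data) < 0.5 * first
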