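"""Per-modality feature extractors and the adversarial modal discriminator.

Each modality gets its own extractor: two fully connected layers with
leaky-ReLU activations mapping the d_k input features into a common
d_c-dimensional space, plus a one-layer classification head producing two
diagnosis logits.  A single discriminator maps any d_c embedding to a
K-way modality probability vector; training it against the extractors (which
in turn chase inverted modality targets) aligns the modality distributions.

Loss conventions:

* discriminator loss: squared error between the softmax output and the
  one-hot modality target, summed over the K entries, averaged over subjects
  and summed over modalities;
* extractor adversarial term: the same squared loss against the *inverted*
  target (the flipped one-hot at K = 2; for K > 2 the uniform distribution
  over the K-1 wrong modalities, or a random wrong one-hot, configurable);
* supervised term: per-modality-head cross-entropy on training subjects plus
  tau times the sum of squared extractor weights.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor
from .data import DataError, ModalityBlock, MultimodalDataset, RunConfig

__all__ = [
    "ModalityExtractor",
    "Discriminator",
    "inverted_targets",
    "extract_features",
    "adversarial_loss",
    "classification_loss",
    "encoder_objective",
]

_LEAKY_SLOPE = 0.01


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    bound = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-bound, bound, size=(fan_in, fan_out))


class ModalityExtractor:
    """Two hidden layers (widths max(d_k, d_c) then d_c) plus a 2-logit head."""

    def __init__(self, name: str, d_in: int, d_c: int, rng: np.random.Generator):
        self.name = name
        self.d_in, self.d_c = d_in, d_c
        h = max(d_in, d_c)
        self.W1 = Tensor(_glorot(rng, d_in, h), requires_grad=True)
        self.b1 = Tensor(np.zeros(h), requires_grad=True)
        self.W2 = Tensor(_glorot(rng, h, d_c), requires_grad=True)
        self.b2 = Tensor(np.zeros(d_c), requires_grad=True)
        self.Wh = Tensor(_glorot(rng, d_c, 2), requires_grad=True)
        self.bh = Tensor(np.zeros(2), requires_grad=True)

    @property
    def params(self) -> list[Tensor]:
        return [self.W1, self.b1, self.W2, self.b2, self.Wh, self.bh]

    @property
    def weight_matrices(self) -> list[Tensor]:
        # biases are excluded from the weight penalty
        return [self.W1, self.W2, self.Wh]

    def embed(self, x: Tensor | np.ndarray) -> Tensor:
        x = x if isinstance(x, Tensor) else Tensor(x)
        if x.shape[1] != self.d_in:
            raise DataError(
                f"extractor {self.name!r} expects {self.d_in} features, got {x.shape[1]}"
            )
        h = (x @ self.W1 + self.b1).leaky_relu(_LEAKY_SLOPE)
        return (h @ self.W2 + self.b2).leaky_relu(_LEAKY_SLOPE)

    def head_logits(self, emb: Tensor) -> Tensor:
        return emb @ self.Wh + self.bh


class Discriminator:
    """One hidden layer of width d_c, leaky-ReLU, softmax over K modalities."""

    def __init__(self, d_c: int, n_modalities: int, rng: np.random.Generator):
        self.d_c, self.K = d_c, n_modalities
        self.W1 = Tensor(_glorot(rng, d_c, d_c), requires_grad=True)
        self.b1 = Tensor(np.zeros(d_c), requires_grad=True)
        self.W2 = Tensor(_glorot(rng, d_c, n_modalities), requires_grad=True)
        self.b2 = Tensor(np.zeros(n_modalities), requires_grad=True)

    @property
    def params(self) -> list[Tensor]:
        return [self.W1, self.b1, self.W2, self.b2]

    def probs(self, emb: Tensor) -> Tensor:
        h = (emb @ self.W1 + self.b1).leaky_relu(_LEAKY_SLOPE)
        return (h @ self.W2 + self.b2).softmax(axis=1)


def inverted_targets(one_hot: np.ndarray, strategy: str = "uniform",
                     rng: np.random.Generator | None = None) -> np.ndarray:
    """Inverted modality targets: mass moved entirely off the true modality.

    At K = 2 both strategies reduce to flipping the one-hot.  For K > 2,
    `uniform` spreads 1/(K-1) over the wrong modalities; `random_wrong` picks
    one wrong modality per row (needs `rng`).
    """
    one_hot = np.asarray(one_hot, dtype=np.float64)
    K = one_hot.shape[1]
    if K < 2:
        raise DataError("inverted targets need at least two modalities")
    if strategy == "uniform":
        return (1.0 - one_hot) / (K - 1)
    if strategy == "random_wrong":
        if rng is None:
            raise DataError("random_wrong strategy needs an rng")
        out = np.zeros_like(one_hot)
        true_idx = one_hot.argmax(axis=1)
        for i, t in enumerate(true_idx):
            choices = [k for k in range(K) if k != t]
            out[i, choices[rng.integers(len(choices))]] = 1.0
        return out
    raise DataError(f"unknown invert strategy {strategy!r}")


def extract_features(extractor: ModalityExtractor, block: ModalityBlock) -> np.ndarray:
    """Embed one modality block; plain ndarray output for inspection."""
    return extractor.embed(Tensor(block.features)).data


def adversarial_loss(disc: Discriminator, embeddings: list[Tensor],
                     use_inverted: bool = False, strategy: str = "uniform",
                     rng: np.random.Generator | None = None) -> Tensor:
    """Squared modality-identification loss, Sum_k mean_i ||d(f) - target||^2."""
    K = len(embeddings)
    if K != disc.K:
        raise DataError(f"discriminator expects {disc.K} modalities, got {K}")
    total = None
    for k, emb in enumerate(embeddings):
        n = emb.shape[0]
        z = np.zeros((n, K))
        z[:, k] = 1.0
        target = inverted_targets(z, strategy, rng) if use_inverted else z
        p = disc.probs(emb)
        term = ((p - Tensor(target)) ** 2).sum() / float(n)
        total = term if total is None else total + term
    return total


def classification_loss(extractors: list[ModalityExtractor],
                        embeddings: list[Tensor], labels: np.ndarray,
                        train_idx: np.ndarray, tau: float) -> Tensor:
    """Per-modality supervised loss on training subjects plus weight penalty."""
    train_idx = np.asarray(train_idx)
    if train_idx.size == 0:
        raise DataError("empty training mask")
    y = np.asarray(labels)[train_idx]
    onehot = np.zeros((train_idx.size, 2))
    onehot[np.arange(train_idx.size), y] = 1.0
    total = None
    for ext, emb in zip(extractors, embeddings):
        logits = ext.head_logits(emb).take_rows(train_idx)
        lp = logits.log_softmax(axis=1)
        ce = -(lp * Tensor(onehot)).sum() / float(train_idx.size)
        total = ce if total is None else total + ce
    if tau > 0:
        penalty = None
        for ext in extractors:
            for W in ext.weight_matrices:
                sq = (W**2).sum()
                penalty = sq if penalty is None else penalty + sq
        total = total + tau * penalty
    return total


def encoder_objective(extractors: list[ModalityExtractor], disc: Discriminator,
                      embeddings: list[Tensor], labels: np.ndarray,
                      train_idx: np.ndarray, config: RunConfig) -> tuple[Tensor, Tensor]:
    """The two scalar objectives of the adversarial game.

    Returns ``(f_loss, d_loss)``: the extractors minimize the supervised loss
    plus beta times the inverted-label adversarial term; the discriminator
    minimizes the true-label adversarial term.
    """
    d_loss = adversarial_loss(disc, embeddings, use_inverted=False)
    f_sup = classification_loss(extractors, embeddings, labels, train_idx, config.tau)
    if config.beta > 0:
        f_adv = adversarial_loss(disc, embeddings, use_inverted=True,
                                 strategy=config.invert_strategy)
        f_loss = f_sup + config.beta * f_adv
    else:
        f_loss = f_sup
    return f_loss, d_loss
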