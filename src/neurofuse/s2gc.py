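"""Simple Spectral Graph Convolution over the fused patient graph.

The fused adjacency is renormalized with self-loops,

    T = (D + I)^{-1/2} (A + I) (D + I)^{-1/2},

which bounds its spectrum by 1, and node features are propagated by the
Markov-diffusion average of the first C powers with an alpha-weighted
teleport back to the raw features:

    logits = (1/C) sum_{c=1..C} ((1 - alpha) T^c X + alpha X) W.

Powers are never formed explicitly: T^c X is computed by iterated
multiplication.  The default head is this single linear map (softmax output);
a two-layer graph-convolution head with ReLU and a final linear layer is
available as a configuration switch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor
from .data import DataError

__all__ = [
    "PropagationOperator",
    "S2GCHead",
    "GCN2Head",
    "normalize_adjacency",
    "propagate",
    "s2gc_forward",
    "graph_loss",
]


@dataclass
class PropagationOperator:
    """The renormalized diffusion operator with its hop count and teleport."""

    T_tilde: Tensor
    alpha: float
    C: int

    def __post_init__(self):
        if self.C < 1:
            raise DataError(f"hop count C must be >= 1, got {self.C}")
        if not 0.0 <= self.alpha <= 1.0:
            raise DataError(f"alpha must be in [0,1], got {self.alpha}")


def normalize_adjacency(fused: Tensor | np.ndarray, alpha: float = 0.05,
                        C: int = 4) -> PropagationOperator:
    """Renormalization trick: T = (D+I)^{-1/2} (A+I) (D+I)^{-1/2}.

    D is the diagonal degree matrix of the fused adjacency, which must be
    symmetric with nonnegative entries (negative similarities are removed by
    thresholding upstream); D + I is then positive definite and the inverse
    square root is well-defined.  Differentiable in the adjacency.
    """
    A = fused if isinstance(fused, Tensor) else Tensor(fused)
    data = A.data
    if data.ndim != 2 or data.shape[0] != data.shape[1]:
        raise DataError("adjacency must be square")
    if abs(data - data.T).max() > 1e-10:
        raise DataError("adjacency must be symmetric")
    if data.min() < -1e-12:
        raise DataError("adjacency must be nonnegative (threshold first)")
    n = data.shape[0]
    deg = A.sum(axis=1)
    d_inv_sqrt = (deg + 1.0) ** -0.5
    left = d_inv_sqrt.reshape(n, 1)
    right = d_inv_sqrt.reshape(1, n)
    from .graph import _eye

    T = left * (A + Tensor(_eye(n))) * right
    return PropagationOperator(T, alpha=alpha, C=C)


def propagate(op: PropagationOperator, features: Tensor | np.ndarray) -> Tensor:
    """(1/C) sum_c ((1-alpha) T^c X + alpha X) by iterated multiplication."""
    X = features if isinstance(features, Tensor) else Tensor(features)
    acc = None
    cur = X
    for _ in range(op.C):
        cur = op.T_tilde @ cur
        acc = cur if acc is None else acc + cur
    return (1.0 - op.alpha) * (acc / float(op.C)) + op.alpha * X


class S2GCHead:
    """Single linear layer on the propagated features (the default head)."""

    def __init__(self, d_in: int, rng: np.random.Generator):
        bound = np.sqrt(6.0 / (d_in + 2))
        self.W = Tensor(rng.uniform(-bound, bound, size=(d_in, 2)), requires_grad=True)
        self.b = Tensor(np.zeros(2), requires_grad=True)

    @property
    def params(self) -> list[Tensor]:
        return [self.W, self.b]

    def logits(self, op: PropagationOperator, X: Tensor) -> Tensor:
        return propagate(op, X) @ self.W + self.b


class GCN2Head:
    """Two graph-convolution layers with ReLU, then a linear classifier."""

    def __init__(self, d_in: int, rng: np.random.Generator, hidden: int = 32):
        def glorot(i, o):
            bound = np.sqrt(6.0 / (i + o))
            return Tensor(rng.uniform(-bound, bound, size=(i, o)), requires_grad=True)

        self.W1, self.b1 = glorot(d_in, hidden), Tensor(np.zeros(hidden), requires_grad=True)
        self.W2, self.b2 = glorot(hidden, hidden), Tensor(np.zeros(hidden), requires_grad=True)
        self.W3, self.b3 = glorot(hidden, 2), Tensor(np.zeros(2), requires_grad=True)

    @property
    def params(self) -> list[Tensor]:
        return [self.W1, self.b1, self.W2, self.b2, self.W3, self.b3]

    def logits(self, op: PropagationOperator, X: Tensor) -> Tensor:
        h1 = (op.T_tilde @ X @ self.W1 + self.b1).relu()
        h2 = (op.T_tilde @ h1 @ self.W2 + self.b2).relu()
        return h2 @ self.W3 + self.b3


def s2gc_forward(op: PropagationOperator, features: Tensor | np.ndarray,
                 head: S2GCHead | GCN2Head) -> Tensor:
    """Class probabilities per subject, rows summing to 1."""
    X = features if isinstance(features, Tensor) else Tensor(features)
    if X.shape[1] != head.params[0].shape[0]:
        raise DataError(
            f"feature dimension {X.shape[1]} does not match head input "
            f"{head.params[0].shape[0]}"
        )
    return head.logits(op, X).softmax(axis=1)


def graph_loss(probs: Tensor | np.ndarray, labels: np.ndarray,
               train_idx: np.ndarray) -> Tensor:
    """Mean cross-entropy over the masked (training) subjects only.

    Transductive contract: subjects outside the mask sit in the graph but
    contribute nothing to the loss.
    """
    train_idx = np.asarray(train_idx)
    if train_idx.size == 0:
        raise DataError("empty training mask")
    P = probs if isinstance(probs, Tensor) else Tensor(probs)
    y = np.asarray(labels)[train_idx]
    onehot = np.zeros((train_idx.size, P.shape[1]))
    onehot[np.arange(train_idx.size), y] = 1.0
    # gather the true-class probability before the log so that a certain and
    # correct prediction contributes exactly 0 (0 * log 0 never arises)
    p_true = (P.take_rows(train_idx) * Tensor(onehot)).sum(axis=1)
    return -(p_true.log().sum()) / float(train_idx.size)


def masked_logit_loss(logits: Tensor, labels: np.ndarray,
                      train_idx: np.ndarray) -> Tensor:
    """Numerically stable variant of :func:`graph_loss` working on logits."""
    train_idx = np.asarray(train_idx)
    if train_idx.size == 0:
        raise DataError("empty training mask")
    y = np.asarray(labels)[train_idx]
    onehot = np.zeros((train_idx.size, logits.shape[1]))
    onehot[np.arange(train_idx.size), y] = 1.0
    lp = logits.take_rows(train_idx).log_softmax(axis=1)
    return -(lp * Tensor(onehot)).sum() / float(train_idx.size)
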