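"""Learnable patient-similarity graphs and their weighted fusion.

One similarity graph per modality is computed from the aligned embeddings
with a learnable cosine: both embeddings are projected through a trainable
square matrix W_A before the cosine is taken, so the metric itself adapts
during training.  Sub-threshold (and hence all negative) similarities are
zeroed, self-similarity is kept at 1, and the K thresholded graphs are fused
into one global adjacency by a softmax-constrained learned convex
combination — the fusion weights double as a per-modality importance score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, concat
from .data import DataError

_EYE_CACHE: dict[int, np.ndarray] = {}


def _eye(n: int) -> np.ndarray:
    if n not in _EYE_CACHE:
        _EYE_CACHE[n] = np.eye(n)
    return _EYE_CACHE[n]


__all__ = [
    "GraphLearnerParams",
    "GraphBundle",
    "learn_similarity",
    "apply_threshold",
    "fuse_graphs",
    "concat_features",
    "raw_cosine_fused",
]


class GraphLearnerParams:
    """Trainable graph-construction parameters: W_A and the fusion logits."""

    def __init__(self, d_c: int, n_modalities: int, rng: np.random.Generator,
                 shared_wa: bool = True):
        self.shared_wa = shared_wa
        n_mats = 1 if shared_wa else n_modalities
        # near-identity start: the initial metric is close to plain cosine
        self.W_A = [
            Tensor(np.eye(d_c) + 0.01 * rng.standard_normal((d_c, d_c)), requires_grad=True)
            for _ in range(n_mats)
        ]
        self.fusion_logits = Tensor(np.zeros(n_modalities), requires_grad=True)

    def wa_for(self, k: int) -> Tensor:
        return self.W_A[0] if self.shared_wa else self.W_A[k]

    @property
    def params(self) -> list[Tensor]:
        return [*self.W_A, self.fusion_logits]


@dataclass
class GraphBundle:
    """All graph artifacts of one forward pass (plain arrays, for reporting)."""

    per_modality: list[np.ndarray]
    fused: np.ndarray
    fusion_weights: np.ndarray
    fused_features: np.ndarray


def learn_similarity(W_A: Tensor | np.ndarray, embeddings: Tensor | np.ndarray,
                     subject_ids: list[str] | None = None) -> Tensor:
    """Learnable cosine similarity: A_ij = cos(W_A f_i, W_A f_j).

    Differentiable in both W_A and the embeddings.  A row whose projection is
    (numerically) the zero vector has no direction, so it is an error.
    """
    W_A = W_A if isinstance(W_A, Tensor) else Tensor(W_A)
    emb = embeddings if isinstance(embeddings, Tensor) else Tensor(embeddings)
    z = emb @ W_A.T
    sq_norms = (z**2).sum(axis=1, keepdims=True)
    bad = np.nonzero(np.sqrt(sq_norms.data[:, 0]) < 1e-12)[0]
    if bad.size:
        who = subject_ids[bad[0]] if subject_ids else f"row {bad[0]}"
        raise DataError(f"degenerate embedding: subject {who} projects to ~zero under W_A")
    norms = sq_norms.sqrt()
    return (z @ z.T) / (norms @ norms.T)


def apply_threshold(A: Tensor | np.ndarray, theta: float) -> Tensor:
    """Zero off-diagonal similarities below theta; pin the diagonal at 1.

    The mask is treated as a constant, so gradients flow only through the
    surviving edges.  theta >= 0 implies all negative cosines are removed.
    """
    if not 0.0 <= theta < 1.0:
        raise DataError(f"theta must be in [0,1), got {theta}")
    A = A if isinstance(A, Tensor) else Tensor(A)
    n = A.shape[0]
    keep = (A.data >= theta).astype(np.float64)
    np.fill_diagonal(keep, 0.0)
    return A * Tensor(keep) + Tensor(_eye(n))


def fuse_graphs(adjacencies: list[Tensor | np.ndarray],
                fusion_logits: Tensor | np.ndarray) -> tuple[Tensor, Tensor]:
    """Fuse K graphs: A_fused = sum_k w_k A_k with w = softmax(logits)."""
    adjs = [a if isinstance(a, Tensor) else Tensor(a) for a in adjacencies]
    logits = fusion_logits if isinstance(fusion_logits, Tensor) else Tensor(fusion_logits)
    if len(adjs) != logits.shape[0]:
        raise DataError(f"{len(adjs)} graphs but {logits.shape[0]} fusion logits")
    shape = adjs[0].shape
    for a in adjs:
        if a.shape != shape:
            raise DataError("all adjacencies must share one shape")
    w = logits.softmax(axis=0)
    fused = None
    for k, a in enumerate(adjs):
        term = a * w.take_rows(np.array([k])).reshape(1, 1)
        fused = term if fused is None else fused + term
    return fused, w


def concat_features(embeddings: list[Tensor | np.ndarray]) -> Tensor:
    """Concatenate K aligned N x d_c embeddings into the fused N x (K d_c)."""
    embs = [e if isinstance(e, Tensor) else Tensor(e) for e in embeddings]
    n, d = embs[0].shape
    for e in embs:
        if e.shape != (n, d):
            raise DataError("all embeddings must be N x d_c with equal shapes")
    return concat(embs, axis=1)


def raw_cosine_fused(feature_blocks: list[np.ndarray], theta: float) -> np.ndarray:
    """Reference graph from raw features: plain cosine per block, thresholded,
    uniformly averaged.  Used as the no-learning baseline in graph-recovery
    comparisons."""
    fused = None
    for x in feature_blocks:
        norms = np.linalg.norm(x, axis=1, keepdims=True)
        norms = np.where(norms > 0, norms, 1.0)
        a = (x / norms) @ (x / norms).T
        a = apply_threshold(a, theta).data
        fused = a if fused is None else fused + a
    return fused / len(feature_blocks)
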