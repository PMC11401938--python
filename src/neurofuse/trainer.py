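"""Alternating optimization of the full model.

Each epoch performs, in order:

1. one discriminator update, minimizing the true-label squared modality loss
   (the extractors are held fixed by detaching the embeddings);
2. one extractor update, minimizing the supervised loss plus beta times the
   inverted-label adversarial term (the discriminator's parameters are
   frozen — they receive gradient but are not stepped);
3. one joint update, minimizing L_g + eta * (L_f + beta * L_inv), stepping
   the graph learner (W_A, fusion logits), the classifier head, and the
   extractors (whose parameters the joint loss depends on through both the
   embeddings and L_f).  The discriminator stays frozen throughout.

All steps are full-batch: the method is transductive over one patient graph.
Four Adam optimizers at the configured learning rates drive (f, d, graph
learner, head); gradients are clipped at global norm 5 per group to keep the
adversarial dynamics stable.  Model selection keeps the parameter snapshot
with the best validation AUC when a validation mask is given.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Adam, Tensor, clip_global_norm
from .data import DataError, MultimodalDataset, RunConfig, zscore_normalize
from .encoder import (Discriminator, ModalityExtractor, adversarial_loss,
                      classification_loss)
from .graph import (GraphBundle, GraphLearnerParams, apply_threshold,
                    concat_features, fuse_graphs, learn_similarity)
from .s2gc import (GCN2Head, S2GCHead, masked_logit_loss, normalize_adjacency)

__all__ = ["Model", "TrainState", "train_epoch", "fit"]


@dataclass
class TrainState:
    """Loss trace and bookkeeping of one training run."""

    epoch: int = 0
    trace: list[dict] = field(default_factory=list)
    best_val_auc: float = -np.inf
    best_epoch: int = -1

    def append(self, **losses) -> None:
        for name, v in losses.items():
            if v is not None and not np.isfinite(v):
                raise FloatingPointError(
                    f"non-finite loss term {name!r} ({v}) at epoch {self.epoch}"
                )
        self.trace.append(losses)

    def write_trace(self, path) -> None:
        import csv

        keys = ["epoch", "d_loss", "f_loss", "graph_loss", "joint_loss", "val_auc"]
        with open(path, "w", newline="") as fh:
            w = csv.DictWriter(fh, fieldnames=keys)
            w.writeheader()
            for row in self.trace:
                w.writerow({k: row.get(k, "") for k in keys})


class Model:
    """All trainable parts plus the forward passes tying them together."""

    def __init__(self, dataset: MultimodalDataset, config: RunConfig,
                 variant: str = "full"):
        if variant not in ("full", "no_discriminator", "no_fusion", "extractor_only"):
            raise DataError(f"unknown variant {variant!r}")
        self.config = config
        self.variant = variant
        self.modalities = [b.name for b in dataset.blocks]
        K = len(dataset.blocks)
        root = np.random.SeedSequence(config.seed)
        r_ext, r_disc, r_graph, r_head = (np.random.default_rng(s) for s in root.spawn(4))
        self.extractors = [
            ModalityExtractor(b.name, b.n_features, config.d_c, r_ext)
            for b in dataset.blocks
        ]
        self.discriminator = Discriminator(config.d_c, K, r_disc)
        self.uses_graph = variant in ("full", "no_discriminator")
        # a single modality leaves the discriminator with nothing to tell apart
        self.uses_discriminator = variant == "full" and config.beta > 0 and K >= 2
        self.graph_params = (
            GraphLearnerParams(config.d_c, K, r_graph, shared_wa=config.shared_wa)
            if self.uses_graph else None
        )
        d_fused = K * config.d_c
        if variant == "extractor_only":
            self.head = None
        elif self.uses_graph and config.classifier == "gcn2":
            self.head = GCN2Head(d_fused, r_head)
        else:
            self.head = S2GCHead(d_fused, r_head)

    # ------------------------------------------------------------------ parts
    @property
    def f_params(self) -> list[Tensor]:
        return [p for e in self.extractors for p in e.params]

    def snapshot(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self._all_params()]

    def restore(self, snap: list[np.ndarray]) -> None:
        for p, d in zip(self._all_params(), snap):
            p.data = d.copy()

    def _all_params(self) -> list[Tensor]:
        ps = self.f_params + self.discriminator.params
        if self.graph_params is not None:
            ps += self.graph_params.params
        if self.head is not None:
            ps += self.head.params
        return ps

    # --------------------------------------------------------------- forwards
    def embeddings(self, dataset: MultimodalDataset, detach: bool = False) -> list[Tensor]:
        embs = [e.embed(Tensor(b.features)) for e, b in zip(self.extractors, dataset.blocks)]
        return [Tensor(e.data) for e in embs] if detach else embs

    def graph_forward(self, embeddings: list[Tensor]) -> tuple[Tensor, Tensor, Tensor, list[Tensor]]:
        """(fused adjacency, fusion weights, fused features, per-modality A)."""
        cfg = self.config
        adjs = []
        for k, emb in enumerate(embeddings):
            A = learn_similarity(self.graph_params.wa_for(k), emb)
            adjs.append(apply_threshold(A, cfg.theta))
        fused, w = fuse_graphs(adjs, self.graph_params.fusion_logits)
        fhat = concat_features(embeddings)
        return fused, w, fhat, adjs

    def logits(self, dataset: MultimodalDataset) -> Tensor:
        """Diagnosis logits for every subject under the current parameters."""
        embs = self.embeddings(dataset)
        if self.variant == "extractor_only":
            stacked = None
            for ext, emb in zip(self.extractors, embs):
                lg = ext.head_logits(emb)
                stacked = lg if stacked is None else stacked + lg
            return stacked / float(len(embs))
        if not self.uses_graph:  # no_fusion: plain head on concatenated embeddings
            return concat_features(embs) @ self.head.W + self.head.b
        fused, _, fhat, _ = self.graph_forward(embs)
        op = normalize_adjacency(fused, alpha=self.config.alpha, C=self.config.C)
        return self.head.logits(op, fhat)

    def predict_proba(self, dataset: MultimodalDataset) -> np.ndarray:
        """(N, 2) class probabilities, rows summing to one."""
        return self.logits(dataset).softmax(axis=1).data

    def graph_bundle(self, dataset: MultimodalDataset) -> GraphBundle:
        if not self.uses_graph:
            raise DataError(f"variant {self.variant!r} builds no graph")
        embs = self.embeddings(dataset, detach=True)
        fused, w, fhat, adjs = self.graph_forward(embs)
        return GraphBundle(
            per_modality=[a.data for a in adjs],
            fused=fused.data,
            fusion_weights=w.data,
            fused_features=fhat.data,
        )


def _val_auc(probs: np.ndarray, labels: np.ndarray, val_idx: np.ndarray) -> float | None:
    if val_idx is None or len(val_idx) == 0:
        return None
    y = labels[val_idx]
    if len(np.unique(y)) < 2:
        return None
    from sklearn.metrics import roc_auc_score

    return float(roc_auc_score(y, probs[val_idx, 1]))


class _Optimizers:
    def __init__(self, model: Model, config: RunConfig):
        lr_f, lr_d, lr_wa, lr_g = config.learning_rates
        self.f = Adam(model.f_params, lr_f)
        self.d = Adam(model.discriminator.params, lr_d)
        self.wa = Adam(model.graph_params.params, lr_wa) if model.graph_params else None
        self.g = Adam(model.head.params, lr_g) if model.head is not None else None

    def zero_all(self) -> None:
        for opt in (self.f, self.d, self.wa, self.g):
            if opt is not None:
                opt.zero_grad()


def train_epoch(model: Model, opts: _Optimizers, dataset: MultimodalDataset,
                config: RunConfig, train_idx: np.ndarray,
                val_idx: np.ndarray | None, state: TrainState) -> TrainState:
    """Run one alternating epoch and append its losses to the trace."""
    y = dataset.labels
    d_loss_val = None

    # --- step 1: discriminator (true labels, extractors detached)
    if model.uses_discriminator:
        opts.zero_all()
        embs = model.embeddings(dataset, detach=True)
        d_loss = adversarial_loss(model.discriminator, embs, use_inverted=False)
        d_loss.backward()
        clip_global_norm(model.discriminator.params, 5.0)
        opts.d.step()
        d_loss_val = float(d_loss.data)

    # --- step 2: extractors (supervised + beta * inverted adversarial term)
    opts.zero_all()
    embs = model.embeddings(dataset)
    f_sup = classification_loss(model.extractors, embs, y, train_idx, config.tau)
    if model.uses_discriminator:
        f_adv = adversarial_loss(model.discriminator, embs, use_inverted=True,
                                 strategy=config.invert_strategy)
        f_loss = f_sup + config.beta * f_adv
    else:
        f_loss = f_sup
    f_loss.backward()
    clip_global_norm(model.f_params, 5.0)
    opts.f.step()
    f_loss_val = float(f_loss.data)

    # --- step 3: joint graph/classifier update (discriminator frozen)
    graph_loss_val = None
    joint_loss_val = None
    val_probs = None
    if model.variant != "extractor_only":
        opts.zero_all()
        embs = model.embeddings(dataset)
        if model.uses_graph:
            fused, _, fhat, _ = model.graph_forward(embs)
            op = normalize_adjacency(fused, alpha=config.alpha, C=config.C)
            logits = model.head.logits(op, fhat)
        else:
            logits = concat_features(embs) @ model.head.W + model.head.b
        l_g = masked_logit_loss(logits, y, train_idx)
        if config.eta > 0:
            f_sup2 = classification_loss(model.extractors, embs, y, train_idx, config.tau)
            if model.uses_discriminator:
                f_adv2 = adversarial_loss(model.discriminator, embs, use_inverted=True,
                                          strategy=config.invert_strategy)
                joint = l_g + config.eta * (f_sup2 + config.beta * f_adv2)
            else:
                joint = l_g + config.eta * f_sup2
        else:
            joint = l_g
        joint.backward()
        groups = model.f_params + model.head.params
        if model.graph_params is not None:
            groups += model.graph_params.params
        clip_global_norm(groups, 5.0)
        opts.f.step()
        if opts.wa is not None:
            opts.wa.step()
        opts.g.step()
        graph_loss_val = float(l_g.data)
        joint_loss_val = float(joint.data)
        val_probs = logits.softmax(axis=1).data
    else:
        probs_parts = [ext.head_logits(e).softmax(axis=1).data
                       for ext, e in zip(model.extractors, embs)]
        val_probs = np.mean(probs_parts, axis=0)

    state.epoch += 1
    va = _val_auc(val_probs, y, val_idx)
    state.append(epoch=state.epoch, d_loss=d_loss_val, f_loss=f_loss_val,
                 graph_loss=graph_loss_val, joint_loss=joint_loss_val, val_auc=va)
    return state


def fit(dataset: MultimodalDataset, config: RunConfig,
        train_idx: np.ndarray, val_idx: np.ndarray | None = None,
        variant: str = "full",
        normalize: bool | None = None) -> tuple[Model, TrainState]:
    """Train the model for ``config.epochs`` epochs; return the selected snapshot.

    With a validation mask, the parameters with the best validation AUC are
    restored at the end; otherwise the final parameters are kept.  With
    ``config.epochs == 0`` the freshly initialized model is returned.
    """
    train_idx = np.asarray(train_idx)
    if train_idx.size == 0:
        raise DataError("empty training mask")
    if val_idx is not None:
        val_idx = np.asarray(val_idx)
        if np.intersect1d(train_idx, val_idx).size:
            raise DataError("train and validation masks overlap")
    do_norm = config.normalize if normalize is None else normalize
    if do_norm:
        dataset = zscore_normalize(dataset)
    model = Model(dataset, config, variant=variant)
    opts = _Optimizers(model, config)
    state = TrainState()
    best_snap = None
    for _ in range(config.epochs):
        train_epoch(model, opts, dataset, config, train_idx, val_idx, state)
        # ties broken toward the later epoch: small validation folds saturate
        # AUC early, before the probability scale around the cutoff settles
        va = state.trace[-1].get("val_auc")
        if va is not None and va >= state.best_val_auc:
            state.best_val_auc = va
            state.best_epoch = state.epoch
            best_snap = model.snapshot()
    if best_snap is not None:
        model.restore(best_snap)
    model._trained_on_normalized = do_norm
    return model, state
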