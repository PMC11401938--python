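"""Cross-validated evaluation, diagnostics and experiment runners.

The evaluation design is transductive: in every fold all subjects inhabit the
patient graph, only the training-fold labels enter any loss, 10% of the
training fold (stratified) is carved off as a validation set for model
selection, and the held-out fold supplies the reported metrics.

Metrics follow the conventional definitions — sensitivity is the
true-positive rate among cases, specificity the true-negative rate among
controls, both at a fixed probability cutoff — and AUC is the Mann–Whitney
rank statistic (ties counted one half).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.metrics import silhouette_score as _sk_silhouette
from sklearn.model_selection import StratifiedKFold, train_test_split

from .data import DataError, MultimodalDataset, RunConfig, zscore_normalize
from .trainer import Model, fit

__all__ = [
    "FoldResult",
    "CVReport",
    "stratified_kfold",
    "compute_metrics",
    "two_sample_t_test",
    "silhouette_score",
    "run_cv",
    "run_ablation",
    "run_modality_combinations",
    "modality_probe_accuracy",
]

ABLATION_VARIANTS = ("full", "no_discriminator", "no_fusion", "extractor_only")


@dataclass
class FoldResult:
    fold: int
    test_idx: np.ndarray
    scores: np.ndarray  # probability of class 1 on the test fold
    acc: float
    auc: float
    sen: float
    spe: float
    fusion_weights: np.ndarray | None = None

    def as_dict(self) -> dict:
        d = {"fold": self.fold, "acc": self.acc, "auc": self.auc,
             "sen": self.sen, "spe": self.spe}
        if self.fusion_weights is not None:
            d["fusion_weights"] = [float(w) for w in self.fusion_weights]
        return d


@dataclass
class CVReport:
    folds: list[FoldResult]
    seed: int
    modalities: list[str]
    variant: str = "full"

    def _values(self, name: str) -> np.ndarray:
        return np.array([getattr(f, name) for f in self.folds])

    def mean(self, name: str) -> float:
        return float(self._values(name).mean())

    def std(self, name: str) -> float:
        return float(self._values(name).std(ddof=1)) if len(self.folds) > 1 else 0.0

    def summary(self) -> dict:
        out = {"seed": self.seed, "variant": self.variant, "k": len(self.folds),
               "modalities": self.modalities}
        for m in ("acc", "auc", "sen", "spe"):
            out[f"{m}_mean"] = self.mean(m)
            out[f"{m}_std"] = self.std(m)
        out["folds"] = [f.as_dict() for f in self.folds]
        return out

    def to_json(self, path=None) -> str:
        text = json.dumps(self.summary(), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def table(self) -> str:
        """Aligned text table, percentages as mean ± sd with two decimals."""
        lines = [f"{'metric':<8}{'mean ± sd (%)':>18}"]
        for m in ("acc", "auc", "sen", "spe"):
            lines.append(
                f"{m.upper():<8}{100 * self.mean(m):>10.2f} ± {100 * self.std(m):.2f}"
            )
        return "\n".join(lines)


# ------------------------------------------------------------------- metrics

def stratified_kfold(labels: np.ndarray, k: int, seed: int) -> list[tuple[np.ndarray, np.ndarray]]:
    """Deterministic stratified k-fold index pairs (train_idx, test_idx)."""
    labels = np.asarray(labels)
    if k < 2:
        raise DataError(f"need k >= 2 folds, got {k}")
    counts = np.bincount(labels, minlength=2)
    if counts.min() < k:
        raise DataError(f"smallest class has {counts.min()} members, fewer than k={k}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [(tr, te) for tr, te in skf.split(np.zeros(len(labels)), labels)]


def compute_metrics(y_true: np.ndarray, scores: np.ndarray,
                    cutoff: float = 0.5) -> tuple[float, float, float, float]:
    """(ACC, AUC, SEN, SPE) at the given cutoff; AUC is threshold-free."""
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=np.float64)
    if len(np.unique(y_true)) < 2:
        raise DataError("both classes must be present to compute metrics")
    pred = (scores >= cutoff).astype(int)
    tp = int(((pred == 1) & (y_true == 1)).sum())
    tn = int(((pred == 0) & (y_true == 0)).sum())
    fp = int(((pred == 1) & (y_true == 0)).sum())
    fn = int(((pred == 0) & (y_true == 1)).sum())
    acc = (tp + tn) / len(y_true)
    sen = tp / (tp + fn)
    spe = tn / (tn + fp)
    auc = float(roc_auc_score(y_true, scores))
    return float(acc), auc, float(sen), float(spe)


def two_sample_t_test(a, b) -> tuple[float, float]:
    """Welch's unequal-variance two-sample t-test, two-sided."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise DataError("each sample needs at least two values")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0  # degenerate: identical constants
        raise DataError("zero variance in both samples with unequal means")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def silhouette_score(embeddings: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette, Euclidean distance; singleton clusters score 0."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise DataError("silhouette needs at least two clusters")
    return float(_sk_silhouette(np.asarray(embeddings), labels, metric="euclidean"))


def roc_coordinates(y_true: np.ndarray, scores: np.ndarray) -> np.ndarray:
    """(fpr, tpr, threshold) rows for plotting a fold's ROC curve."""
    fpr, tpr, thr = roc_curve(y_true, scores)
    return np.column_stack([fpr, tpr, thr])


# ---------------------------------------------------------------- experiment

def _carve_validation(train_idx: np.ndarray, labels: np.ndarray,
                      seed: int, frac: float = 0.1) -> tuple[np.ndarray, np.ndarray]:
    """Stratified 10% validation split carved from the training indices."""
    y = labels[train_idx]
    tr, va = train_test_split(train_idx, test_size=frac, stratify=y, random_state=seed)
    return np.sort(tr), np.sort(va)


def run_cv(dataset: MultimodalDataset, config: RunConfig, k: int = 10,
           variant: str = "full",
           folds: list[tuple[np.ndarray, np.ndarray]] | None = None) -> CVReport:
    """Stratified k-fold evaluation of the transductive model."""
    if folds is None:
        folds = stratified_kfold(dataset.labels, k, config.seed)
    ds = zscore_normalize(dataset) if config.normalize else dataset
    results = []
    for fold_id, (train_all, test_idx) in enumerate(folds):
        fold_seed = int(np.random.SeedSequence([config.seed, fold_id]).generate_state(1)[0] % (2**31))
        tr, va = _carve_validation(train_all, ds.labels, fold_seed)
        cfg = RunConfig(**{**_cfg_dict(config), "seed": fold_seed})
        model, _ = fit(ds, cfg, tr, va, variant=variant, normalize=False)
        probs = model.predict_proba(ds)[:, 1]
        y_test = ds.labels[test_idx]
        acc, auc, sen, spe = compute_metrics(y_test, probs[test_idx], config.cutoff)
        fw = None
        if model.uses_graph:
            fw = model.graph_bundle(ds).fusion_weights
        results.append(FoldResult(fold_id, test_idx, probs[test_idx],
                                  acc, auc, sen, spe, fw))
    return CVReport(results, seed=config.seed,
                    modalities=[b.name for b in dataset.blocks], variant=variant)


def _cfg_dict(config: RunConfig) -> dict:
    import dataclasses

    return dataclasses.asdict(config)


def run_ablation(dataset: MultimodalDataset, config: RunConfig,
                 variants: list[str] = ("full", "no_discriminator", "no_fusion"),
                 k: int = 10) -> dict:
    """Evaluate model variants on identical folds; Welch-test the AUC gaps."""
    for v in variants:
        if v not in ABLATION_VARIANTS:
            raise DataError(f"unknown variant {v!r}; choose from {ABLATION_VARIANTS}")
    folds = stratified_kfold(dataset.labels, k, config.seed)
    reports = {v: run_cv(dataset, config, k, variant=v, folds=folds) for v in variants}
    comparisons = {}
    base = variants[0]
    for v in variants[1:]:
        a = reports[base]._values("auc")
        b = reports[v]._values("auc")
        if np.array_equal(a, b):
            t, p = 0.0, 1.0
        else:
            t, p = two_sample_t_test(a, b)
        comparisons[f"{base}_vs_{v}"] = {
            "auc_diff_mean": float((a - b).mean()), "t": t, "p": p,
            "per_fold_diff": [float(d) for d in (a - b)],
        }
    return {"reports": reports, "comparisons": comparisons}


def run_modality_combinations(dataset: MultimodalDataset, config: RunConfig,
                              subsets: list[list[str]], k: int = 10) -> dict:
    """run_cv per modality subset with shared folds; weights for the full set."""
    folds = stratified_kfold(dataset.labels, k, config.seed)
    out: dict = {"subsets": {}}
    all_names = [b.name for b in dataset.blocks]
    for subset in subsets:
        if not subset:
            raise DataError("empty modality subset")
        sub = dataset.subset_modalities(list(subset))
        rep = run_cv(sub, config, k, folds=folds)
        out["subsets"]["+".join(subset)] = rep
        if list(subset) == all_names:
            w = np.mean([f.fusion_weights for f in rep.folds], axis=0)
            out["fusion_weights"] = {n: float(x) for n, x in zip(all_names, w)}
    return out


# ----------------------------------------------------------------- diagnostics

def modality_probe_accuracy(model: Model, dataset: MultimodalDataset,
                            seed: int = 0, test_frac: float = 0.3) -> float:
    """Held-out accuracy of a logistic probe predicting an embedding's modality.

    Subjects (not samples) are split, so all K embeddings of one subject land
    on the same side.  Chance level is 1/K; values near chance mean the
    modalities are aligned in the common space.
    """
    ds = zscore_normalize(dataset) if getattr(model, "_trained_on_normalized", True) else dataset
    embs = [e.data for e in model.embeddings(ds, detach=True)]
    n = ds.n_subjects
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_test = int(round(test_frac * n))
    test_subj, train_subj = perm[:n_test], perm[n_test:]
    Xtr = np.vstack([e[train_subj] for e in embs])
    Xte = np.vstack([e[test_subj] for e in embs])
    ytr = np.concatenate([np.full(len(train_subj), k) for k in range(len(embs))])
    yte = np.concatenate([np.full(len(test_subj), k) for k in range(len(embs))])
    probe = LogisticRegression(max_iter=2000, random_state=seed)
    probe.fit(Xtr, ytr)
    return float((probe.predict(Xte) == yte).mean())
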