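"""Multimodal dataset containers and delimited-table / config I/O.

A cohort is a set of per-modality feature tables sharing one subject index,
plus a binary diagnosis label per subject.  Tables are plain delimited text
(CSV or TSV, auto-detected) with a header row and an explicit subject-ID
column; matching across tables is by ID, never by row order, so per-site file
ordering cannot silently misalign modalities.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "DataError",
    "ModalityBlock",
    "MultimodalDataset",
    "RunConfig",
    "load_modality_table",
    "write_modality_table",
    "load_labels_table",
    "assemble_dataset",
    "zscore_normalize",
    "export_adjacency_dense",
    "export_adjacency_edgelist",
]


class DataError(ValueError):
    """Raised for malformed or inconsistent input data."""


@dataclass
class ModalityBlock:
    """One modality's feature matrix: N subjects x d features, with IDs."""

    name: str
    subject_ids: list[str]
    features: np.ndarray  # (N, d) float64
    feature_names: list[str]

    def __post_init__(self):
        self.features = np.asarray(self.features, dtype=np.float64)
        self.subject_ids = [str(s) for s in self.subject_ids]
        n, d = self.features.shape
        if n < 2:
            raise DataError(f"modality {self.name!r}: need at least 2 subjects, got {n}")
        if d < 1:
            raise DataError(f"modality {self.name!r}: need at least 1 feature")
        if len(self.subject_ids) != n:
            raise DataError(f"modality {self.name!r}: {len(self.subject_ids)} IDs for {n} rows")
        if len(set(self.subject_ids)) != n:
            dup = sorted({s for s in self.subject_ids if self.subject_ids.count(s) > 1})
            raise DataError(f"modality {self.name!r}: duplicate subject IDs {dup}")
        if len(self.feature_names) != d:
            raise DataError(f"modality {self.name!r}: feature_names length mismatch")
        if not np.isfinite(self.features).all():
            raise DataError(f"modality {self.name!r}: non-finite feature values")

    @property
    def n_subjects(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]


@dataclass
class MultimodalDataset:
    """K aligned modality blocks plus binary labels (1 = case)."""

    blocks: list[ModalityBlock]
    labels: np.ndarray  # (N,) int, values in {0, 1}

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if len(self.blocks) < 1:
            raise DataError("dataset needs at least one modality block")
        ids = self.blocks[0].subject_ids
        for b in self.blocks[1:]:
            if b.subject_ids != ids:
                raise DataError(f"modality {b.name!r} has different subject IDs/order")
        if self.labels.shape != (len(ids),):
            raise DataError("labels length does not match subject count")
        bad = set(np.unique(self.labels)) - {0, 1}
        if bad:
            raise DataError(f"labels outside {{0,1}}: {sorted(bad)}")
        if len(np.unique(self.labels)) < 2:
            raise DataError("both classes must be present")

    @property
    def subject_ids(self) -> list[str]:
        return self.blocks[0].subject_ids

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_modalities(self) -> int:
        return len(self.blocks)

    def subset_modalities(self, names: list[str]) -> "MultimodalDataset":
        by_name = {b.name: b for b in self.blocks}
        missing = [n for n in names if n not in by_name]
        if missing:
            raise DataError(f"unknown modalities: {missing}")
        return MultimodalDataset([by_name[n] for n in names], self.labels.copy())


@dataclass
class RunConfig:
    """Hyperparameters of one training run.

    Defaults follow the published training recipe: Adam learning rates
    (0.004, 0.001, 0.001, 0.001) for the extractors, the discriminator, the
    graph learner and the classifier respectively; adversarial trade-off
    beta = 0.03, weight penalty tau = 0.004, joint-loss balance eta = 1,
    teleport alpha = 0.05, 500 epochs and a 0.5 decision cutoff.
    """

    d_c: int = 16
    theta: float = 0.3
    alpha: float = 0.05
    C: int = 4
    beta: float = 0.03
    tau: float = 0.004
    eta: float = 1.0
    learning_rates: tuple[float, float, float, float] = (0.004, 0.001, 0.001, 0.001)
    epochs: int = 500
    seed: int = 0
    cutoff: float = 0.5
    normalize: bool = True
    classifier: str = "s2gc"  # or "gcn2": two GCN layers + ReLU + linear head
    shared_wa: bool = True  # one similarity projection shared across modalities
    invert_strategy: str = "uniform"  # inverted-label target for K>2

    def __post_init__(self):
        if not 0.0 <= self.theta < 1.0:
            raise DataError(f"theta must be in [0,1), got {self.theta}")
        if not 0.0 <= self.alpha <= 1.0:
            raise DataError(f"alpha must be in [0,1], got {self.alpha}")
        if self.C < 1:
            raise DataError(f"C must be >= 1, got {self.C}")
        if self.beta < 0 or self.tau < 0 or self.eta < 0:
            raise DataError("beta, tau, eta must be nonnegative")
        if not 0.0 < self.cutoff < 1.0:
            raise DataError(f"cutoff must be in (0,1), got {self.cutoff}")
        if self.epochs < 0:
            raise DataError("epochs must be nonnegative")
        self.learning_rates = tuple(float(r) for r in self.learning_rates)
        if len(self.learning_rates) != 4 or any(r <= 0 for r in self.learning_rates):
            raise DataError("learning_rates must be four positive values")
        if self.classifier not in ("s2gc", "gcn2"):
            raise DataError(f"unknown classifier {self.classifier!r}")

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["learning_rates"] = list(self.learning_rates)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise DataError(f"config file {path} is not a key/value mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(raw) - known)
        if unknown:
            raise DataError(f"unknown config keys: {unknown}")
        if "learning_rates" in raw:
            raw["learning_rates"] = tuple(raw["learning_rates"])
        return cls(**raw)


# --------------------------------------------------------------------- tables

def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise DataError(f"file not found: {path}")
    # sep=None sniffs the delimiter (comma or tab)
    return pd.read_csv(path, sep=None, engine="python", dtype=str)


def load_modality_table(path: str | Path, id_column: str = "subject_id",
                        name: str | None = None) -> ModalityBlock:
    """Read one modality's delimited table into a :class:`ModalityBlock`.

    Row order is preserved; every non-ID cell must parse as a finite number.
    """
    df = _read_table(path)
    if id_column not in df.columns:
        raise DataError(f"{path}: missing ID column {id_column!r}")
    ids = df[id_column].astype(str).tolist()
    feats = df.drop(columns=[id_column])
    if feats.shape[1] == 0:
        raise DataError(f"{path}: no feature columns besides {id_column!r}")
    values = np.empty(feats.shape, dtype=np.float64)
    for j, col in enumerate(feats.columns):
        cells = feats[col].to_numpy()
        for i, cell in enumerate(cells):
            try:
                # float() round-trips repr output exactly (pandas' fast
                # parser can be one ulp off)
                values[i, j] = float(cell)
            except (TypeError, ValueError):
                raise DataError(
                    f"{path}: non-numeric cell at row {i + 2} (subject "
                    f"{ids[i]!r}), column {col!r}: {cell!r}"
                ) from None
        if not np.isfinite(values[:, j]).all():
            i = int(np.nonzero(~np.isfinite(values[:, j]))[0][0])
            raise DataError(
                f"{path}: non-finite cell at row {i + 2} (subject {ids[i]!r}), "
                f"column {col!r}"
            )
    block_name = name if name is not None else Path(path).stem
    return ModalityBlock(block_name, ids, values, list(feats.columns))


def write_modality_table(block: ModalityBlock, path: str | Path,
                         id_column: str = "subject_id") -> None:
    """Write a block back to CSV so that a re-load is value-identical."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(",".join([id_column, *block.feature_names]) + "\n")
        for sid, row in zip(block.subject_ids, block.features):
            # repr round-trips float64 exactly
            fh.write(",".join([sid, *(repr(float(v)) for v in row)]) + "\n")


def load_labels_table(path: str | Path, id_column: str = "subject_id",
                      label_column: str = "label") -> dict[str, int]:
    df = _read_table(path)
    for col in (id_column, label_column):
        if col not in df.columns:
            raise DataError(f"{path}: missing column {col!r}")
    out: dict[str, int] = {}
    for sid, lab in zip(df[id_column].astype(str), df[label_column]):
        try:
            v = int(float(lab))
        except (TypeError, ValueError):
            raise DataError(f"{path}: non-numeric label {lab!r} for subject {sid!r}") from None
        if v not in (0, 1):
            raise DataError(f"{path}: label {v} outside {{0,1}} for subject {sid!r}")
        out[sid] = v
    return out


def assemble_dataset(blocks: list[ModalityBlock],
                     labels: dict[str, int] | str | Path,
                     id_column: str = "subject_id",
                     label_column: str = "label") -> MultimodalDataset:
    """Align blocks and labels on their common subject IDs (sorted order).

    Subjects absent from any block or the label table are dropped; the
    resulting order is deterministic (sorted IDs) regardless of the input
    block or file order.
    """
    if not blocks:
        raise DataError("need at least one modality block")
    if not isinstance(labels, dict):
        labels = load_labels_table(labels, id_column=id_column, label_column=label_column)
    common = set(blocks[0].subject_ids) & set(labels)
    for b in blocks[1:]:
        common &= set(b.subject_ids)
    if not common:
        raise DataError("no subject IDs shared by all blocks and the labels table")
    order = sorted(common)
    aligned = []
    for b in blocks:
        pos = {s: i for i, s in enumerate(b.subject_ids)}
        idx = np.array([pos[s] for s in order])
        aligned.append(ModalityBlock(b.name, order, b.features[idx], list(b.feature_names)))
    y = np.array([labels[s] for s in order], dtype=np.int64)
    return MultimodalDataset(aligned, y)


def zscore_normalize(dataset: MultimodalDataset) -> MultimodalDataset:
    """Standardize each feature column to mean 0, population SD 1.

    Computed over the full cohort (the model is transductive: all subjects
    share one graph, so normalization may see them all).  Zero-variance
    columns map to all-zeros.
    """
    blocks = []
    for b in dataset.blocks:
        x = b.features
        mu = x.mean(axis=0)
        sd = x.std(axis=0)  # population SD (ddof=0)
        centered = x - mu
        with np.errstate(invalid="ignore", divide="ignore"):
            z = np.where(sd > 0, centered / np.where(sd > 0, sd, 1.0), 0.0)
        blocks.append(ModalityBlock(b.name, list(b.subject_ids), z, list(b.feature_names)))
    return MultimodalDataset(blocks, dataset.labels.copy())


# ---------------------------------------------------------------- adjacency IO

def export_adjacency_dense(adj: np.ndarray, subject_ids: list[str],
                           path: str | Path) -> None:
    """Write an N x N adjacency as a dense CSV with a subject-ID header."""
    adj = np.asarray(adj)
    df = pd.DataFrame(adj, columns=subject_ids)
    df.insert(0, "subject_id", subject_ids)
    df.to_csv(path, index=False)


def export_adjacency_edgelist(adj: np.ndarray, subject_ids: list[str],
                              path: str | Path) -> None:
    """Write the nonzero upper-triangle as (id_i, id_j, weight) rows."""
    adj = np.asarray(adj)
    n = adj.shape[0]
    rows = []
    iu, ju = np.triu_indices(n, k=1)
    for i, j in zip(iu, ju):
        w = adj[i, j]
        if w != 0.0:
            rows.append((subject_ids[i], subject_ids[j], w))
    pd.DataFrame(rows, columns=["id_i", "id_j", "weight"]).to_csv(path, index=False)
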