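"""Synthetic multimodal cohorts with planted class structure.

The generator emulates the situation the model is built for: K feature
blocks over one subject index, all derived from a shared low-dimensional
latent factor that carries the diagnosis signal, but each observed through a
different random linear map and shifted by a modality-specific offset.  The
offset plays the role of the cross-modal distribution gap the adversarial
encoder must remove; the latent factor is the common patient structure a good
learned similarity graph should recover.

Generative model, per subject i with class y_i in {0, 1}:

    z_i ~ Normal(mu_{y_i}, I_latent),  mu_y = +/- (class_sep / 2) * u

for a fixed unit direction u, and for modality k

    x_i^k = M_k z_i + s_k + eps,  eps ~ Normal(0, noise_sd^2 I)

where M_k is a fixed random map (its component along u is projected out for
modalities declared non-informative, so they carry no class signal) and s_k
is a random offset of norm `modality_shift`.

Draw order from the root seed is fixed and documented in the code: class
direction u, then per-modality (M_k, s_k), then latents z, then noise per
modality.  The same spec therefore always yields the same cohort.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .data import DataError, ModalityBlock, MultimodalDataset, write_modality_table

__all__ = ["SyntheticSpec", "generate_synthetic", "planted_similarity_oracle", "write_cohort"]

_DEFAULT_DIMS = (20, 30, 40, 120)


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic cohort.

    Defaults mirror a small multimodal clinical cohort: three low-dimensional
    blocks (< 50 features, like phenotypic and QC tables) and one block above
    100 features (like a flattened connectivity vector), balanced classes.
    """

    n_subjects: int = 400
    n_modalities: int = 4
    dims: tuple[int, ...] = _DEFAULT_DIMS
    class_sep: float = 4.0
    modality_shift: float = 5.0
    noise_sd: float = 1.0
    latent_dim: int = 10
    informative_modalities: tuple[int, ...] | None = None  # None = all
    seed: int = 0

    def __post_init__(self):
        self.dims = tuple(int(d) for d in self.dims)
        if len(self.dims) != self.n_modalities:
            raise DataError(
                f"dims has {len(self.dims)} entries for {self.n_modalities} modalities"
            )
        if self.noise_sd <= 0:
            raise DataError("noise_sd must be positive")
        if self.class_sep < 0 or self.modality_shift < 0:
            raise DataError("class_sep and modality_shift must be nonnegative")
        if self.informative_modalities is None:
            self.informative_modalities = tuple(range(self.n_modalities))
        else:
            self.informative_modalities = tuple(sorted(set(self.informative_modalities)))
        if not self.informative_modalities:
            raise DataError("informative_modalities must be nonempty")
        if any(k < 0 or k >= self.n_modalities for k in self.informative_modalities):
            raise DataError("informative_modalities index out of range")


def _streams(spec: SyntheticSpec):
    """Independent child generators in a fixed, documented order."""
    ss = np.random.SeedSequence(spec.seed)
    kids = ss.spawn(3 + 2 * spec.n_modalities)
    structure = np.random.default_rng(kids[0])  # class direction u
    latent = np.random.default_rng(kids[1])     # z draws
    labels = np.random.default_rng(kids[2])     # label shuffling
    maps = [np.random.default_rng(kids[3 + k]) for k in range(spec.n_modalities)]
    noise = [np.random.default_rng(kids[3 + spec.n_modalities + k])
             for k in range(spec.n_modalities)]
    return structure, latent, labels, maps, noise


def _latents_and_labels(spec: SyntheticSpec):
    structure, latent, labels_rng, _, _ = _streams(spec)
    u = structure.standard_normal(spec.latent_dim)
    u /= np.linalg.norm(u)
    n = spec.n_subjects
    n_case = n // 2 + (n % 2)  # 50/50 within one subject
    y = np.array([1] * n_case + [0] * (n - n_case), dtype=np.int64)
    labels_rng.shuffle(y)
    z = latent.standard_normal((n, spec.latent_dim))
    z += np.where(y[:, None] == 1, spec.class_sep / 2.0, -spec.class_sep / 2.0) * u
    return u, z, y


def generate_synthetic(spec: SyntheticSpec) -> MultimodalDataset:
    """Draw one cohort from the generative model; reproducible from the seed."""
    _, _, _, maps_rng, noise_rng = _streams(spec)
    u, z, y = _latents_and_labels(spec)
    blocks = []
    for k, d in enumerate(spec.dims):
        rng = maps_rng[k]
        M = rng.standard_normal((spec.latent_dim, d)) / np.sqrt(spec.latent_dim)
        s_dir = rng.standard_normal(d)
        s = spec.modality_shift * s_dir / np.linalg.norm(s_dir)
        if k not in spec.informative_modalities:
            # project the class direction out of the map: no class signal
            M = M - np.outer(u, u @ M)
        x = z @ M + s + spec.noise_sd * noise_rng[k].standard_normal((spec.n_subjects, d))
        ids = [f"S{i:04d}" for i in range(spec.n_subjects)]
        names = [f"f{j}" for j in range(d)]
        blocks.append(ModalityBlock(f"MOD{k}", ids, x, names))
    return MultimodalDataset(blocks, y)


def planted_similarity_oracle(spec: SyntheticSpec,
                              dataset: MultimodalDataset) -> np.ndarray:
    """Cosine similarity of the planted latent vectors, N x N.

    This is the structure a well-learned patient graph should correlate with;
    it is recomputed from the spec's seed (same draw order as the generator),
    so the dataset must come from :func:`generate_synthetic` with this spec.
    """
    if dataset.n_subjects != spec.n_subjects:
        raise DataError(
            f"dataset has {dataset.n_subjects} subjects but spec says {spec.n_subjects}"
        )
    _, z, _ = _latents_and_labels(spec)
    norms = np.linalg.norm(z, axis=1, keepdims=True)
    zn = z / norms
    return zn @ zn.T


def write_cohort(spec: SyntheticSpec, out_dir: str | Path) -> MultimodalDataset:
    """Write the cohort as per-modality CSVs + labels.csv + manifest.yaml."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ds = generate_synthetic(spec)
    for b in ds.blocks:
        write_modality_table(b, out / f"{b.name}.csv")
    import pandas as pd

    pd.DataFrame({"subject_id": ds.subject_ids, "label": ds.labels}).to_csv(
        out / "labels.csv", index=False
    )
    manifest = {
        "n_subjects": spec.n_subjects,
        "n_modalities": spec.n_modalities,
        "dims": list(spec.dims),
        "class_sep": float(spec.class_sep),
        "modality_shift": float(spec.modality_shift),
        "noise_sd": float(spec.noise_sd),
        "latent_dim": spec.latent_dim,
        "informative_modalities": list(spec.informative_modalities),
        "seed": spec.seed,
        "modalities": [b.name for b in ds.blocks],
    }
    (out / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=True))
    return ds
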