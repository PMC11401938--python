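import numpy as np
import pytest

from neurofuse import (ModalityBlock, MultimodalDataset, RunConfig,
                       SyntheticSpec, generate_synthetic)


@pytest.fixture
def tiny_dataset() -> MultimodalDataset:
    """8 subjects, 2 modalities, deterministic values."""
    rng = np.random.default_rng(42)
    ids = [f"P{i}" for i in range(8)]
    blocks = [
        ModalityBlock("A", ids, rng.standard_normal((8, 3)), ["a0", "a1", "a2"]),
        ModalityBlock("B", ids, rng.standard_normal((8, 5)), [f"b{j}" for j in range(5)]),
    ]
    labels = np.array([0, 1, 0, 1, 0, 1, 0, 1])
    return MultimodalDataset(blocks, labels)


@pytest.fixture
def small_cohort() -> MultimodalDataset:
    """Separable synthetic cohort small enough for fast training tests."""
    spec = SyntheticSpec(n_subjects=80, n_modalities=3, dims=(8, 12, 30),
                         class_sep=6.0, modality_shift=5.0, seed=3)
    return generate_synthetic(spec)


@pytest.fixture
def fast_config() -> RunConfig:
    return RunConfig(epochs=40, seed=3, d_c=8)
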