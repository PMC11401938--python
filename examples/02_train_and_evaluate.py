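"""Train the full pipeline once and cross-validate it.

Runs a 3-fold stratified cross-validation on a separable synthetic cohort
and prints the diagnostic metrics (percent, mean over folds) plus the
learned per-modality fusion weights.
"""
import numpy as np

from neurofuse import RunConfig, SyntheticSpec, generate_synthetic, run_cv

spec = SyntheticSpec(n_subjects=120, n_modalities=3, dims=(20, 30, 120),
                     class_sep=6.0, modality_shift=5.0, seed=1)
ds = generate_synthetic(spec)
cfg = RunConfig(epochs=100, seed=1)
report = run_cv(ds, cfg, k=3)
print(report.table())
w = np.mean([f.fusion_weights for f in report.folds], axis=0)
for b, wk in zip(ds.blocks, w):
    print(f"fusion weight {b.name}: {wk:.3f}")
# high ACC/AUC: the graph classifier recovers the planted diagnosis signal;
# the fusion weights show how much each modality's graph contributes
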