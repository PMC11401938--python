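# neurofuse

Adversarially aligned multimodal patient-similarity graphs for transductive
diagnosis.

Clinical cohorts increasingly come with several feature tables per subject —
demographics, automated image-quality metrics, flattened functional-connectivity
vectors — whose distributions differ sharply across sources even though they
describe the same patients. `neurofuse` implements an end-to-end pipeline for
binary diagnosis from such data, built for method developers and applied
researchers who have per-subject feature tables (one per modality) and a
binary outcome:

1. **Adversarial-regularized encoder.** A per-modality extractor
   `f_k : R^{d_k} -> R^{d_c}` (two fully connected layers, leaky-ReLU) maps
   each modality into a common space; a modal discriminator `d(.)` tries to
   identify each embedding's source modality from its softmax output under a
   squared loss, while the extractors chase inverted modality targets — a
   minimax game `min_f L_f + beta * L̂_{d,f}, min_d L_{d,f}` that pressures the
   modality distributions toward each other. `L_f` adds per-modality supervised
   cross-entropy heads with an L2 weight penalty `tau * ||f||^2`.
2. **Learnable patient graphs and fusion.** Per modality, a similarity graph
   `A_ij = cos(W_A f_i, W_A f_j)` with a trainable projection `W_A`,
   thresholded at `theta`; the K graphs fuse into one global adjacency
   `A_fused = sum_k w_k A_k` with softmax-constrained learned weights `w`
   (readable as per-modality importance).
3. **Spectral graph classifier.** The renormalized operator
   `T = (D+I)^{-1/2} (A_fused + I) (D+I)^{-1/2}` propagates the concatenated
   embeddings by the averaged diffusion
   `(1/C) sum_{c=1..C} ((1-alpha) T^c X + alpha X) W` into two class logits
   (simple spectral graph convolution; a two-layer GCN head is available as a
   config switch).
4. **Joint training and evaluation.** Per epoch: one discriminator step, one
   extractor step, one joint step on `L_g + eta (L_f + beta L̂)`; four Adam
   optimizers at rates (0.004, 0.001, 0.001, 0.001). Evaluation is
   transductive, stratified k-fold: all subjects sit in the graph, only
   training labels enter losses, 10% of each training fold is carved off for
   model selection by validation AUC, and the held-out fold supplies
   ACC/AUC/SEN/SPE at a 0.5 cutoff.

Since real multimodal cohorts of this kind are not redistributable, the
package ships a first-class synthetic generator
(`neurofuse.synth`): K feature blocks observed from a shared latent diagnosis
factor through per-modality random maps, with controllable class separation,
cross-modal distribution shift and noise, plus a planted-similarity oracle
for graph-recovery checks. The training machinery runs on a compact
numpy reverse-mode autodiff engine (`neurofuse.autodiff`), gradient-checked
against finite differences; no GPU or deep-learning framework is required.

## Worked example

```bash
python examples/02_train_and_evaluate.py
```

trains the full pipeline with 3-fold stratified cross-validation on a
well-separated synthetic cohort (120 subjects, modalities of 20/30/120
features) and prints:

```
metric       mean ± sd (%)
ACC         100.00 ± 0.00
AUC         100.00 ± 0.00
SEN         100.00 ± 0.00
SPE         100.00 ± 0.00
fusion weight MOD0: 0.331
fusion weight MOD1: 0.331
fusion weight MOD2: 0.338
```

All four metrics reach 100% because the planted class separation (6 latent
standard deviations) is far above the noise floor; the fusion weights stay
near uniform because every modality observes the same latent signal. With a
genuinely uninformative modality the picture changes
(`examples/04_modality_combinations.py`):

```
MOD0               AUC  77.33 %
MOD1               AUC  45.08 %
MOD2               AUC  97.00 %
MOD0+MOD1+MOD2     AUC  94.25 %
```

MOD1 carries no diagnosis signal by construction and scores at chance alone,
while the informative wide block (MOD2) dominates — the same read-out the
modality-importance analysis provides on real cohorts. The other examples
cover cohort simulation (`01`) and the ablation comparison on shared folds
(`03`).

The same functionality is scriptable from a shell:

```bash
neurofuse simulate --out cohort/ --seed 7
neurofuse evaluate --data cohort/ --out report/ --folds 10
neurofuse ablate   --data cohort/ --out ablation/ --variants full,no_discriminator,no_fusion
neurofuse combos   --data cohort/ --out combos/ --subsets MOD0+MOD3,MOD3
```

Every command writes a `run_manifest.json` (config hash, seed, version) so a
run is reproducible from its manifest alone.

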