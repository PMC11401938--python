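# Methods

## Model

`neurofuse` classifies subjects of a multimodal cohort (K feature tables over
one subject index, binary outcome) transductively: one patient graph holds
all subjects; only training labels enter any loss.

**Encoder.** Each modality k gets its own extractor — two fully connected
layers with leaky-ReLU (slope 0.01), widths `(max(d_k, d_c), d_c)` — plus a
one-layer supervised head producing two diagnosis logits. A shared modal
discriminator (one hidden layer of width `d_c`, leaky-ReLU, softmax over K
outputs) is trained with a squared loss against one-hot modality targets,
summed over the K output entries, averaged over subjects and summed over
modalities. The extractors are regularized adversarially with the
invert-label form: they minimize the same squared loss against targets that
put all mass on wrong modalities (the flipped one-hot at K = 2; for K > 2 a
uniform distribution over the K−1 wrong modalities by default, or a random
wrong one-hot via `invert_strategy="random_wrong"`). The supervised term is
the mean cross-entropy of each modality head on training subjects plus
`tau * sum(W^2)` over extractor weight matrices (biases excluded).

**Graphs.** Per modality, a learnable cosine
`A_ij = cos(W_A f_i, W_A f_j)` with a trainable square projection `W_A`
(one shared matrix by default, `shared_wa=False` for per-modality copies;
initialized near the identity so the starting metric is plain cosine).
Off-diagonal entries below `theta` are zeroed (this removes all negative
cosines for `theta >= 0`), the diagonal is pinned at 1, and the threshold
mask is a constant in the backward pass, so gradients flow only through
surviving edges. The K graphs fuse as `A_fused = sum_k w_k A_k` with
`w = softmax(fusion_logits)` — simplex-constrained so the weights read
directly as modality importance. Fused node features are the concatenation
of the K embeddings, dimension `K * d_c`.

**Classifier.** The renormalized operator
`T = (D+I)^{-1/2}(A_fused+I)(D+I)^{-1/2}` (D the degree matrix of the fused,
nonnegative adjacency, so `D+I` is positive definite and the spectrum is
bounded by 1) propagates features by
`(1/C) sum_{c=1..C} ((1-alpha) T^c X + alpha X)`, computed by iterated
multiplication rather than explicit powers, followed by one linear layer and
a row-wise softmax with max-subtraction. A variant head with two graph
convolutions + ReLU + linear layer exists behind `classifier="gcn2"`; the
one-layer spectral form is the default because it has fewer free
architectural choices.

**Training.** Per epoch, in order: (1) one discriminator Adam step on
detached embeddings (true-label loss); (2) one extractor step on
`L_f + beta * L̂`; (3) one joint step on `L = L_g + eta (L_f + beta L̂)`
updating the graph learner, the classifier head *and* the extractors — the
joint loss depends on extractor parameters through both the embeddings and
`L_f`, so updating only the graph/classifier would leave the `eta` term
inert — while the discriminator stays frozen. Four Adam optimizers (default
moments) at rates (0.004, 0.001, 0.001, 0.001) for extractors,
discriminator, graph learner, head; gradients clipped at global norm 5 per
group to damp the adversarial dynamics. All steps are full-batch. Model
selection keeps the snapshot with the best validation AUC; ties go to the
later epoch, because small validation folds saturate AUC many epochs before
the probability scale around the decision cutoff settles. Identical seeds
and config give bit-identical results on CPU.

## Parameters

| name | default | meaning |
|---|---|---|
| `d_c` | 16 | common embedding dimension (architecture choice; dimensionless) |
| `theta` | 0.3 | similarity threshold in cosine units, [0, 1) |
| `alpha` | 0.05 | teleport weight of the raw features in the diffusion, [0, 1] |
| `C` | 4 | diffusion hop count |
| `beta` | 0.03 | weight of the adversarial term in the extractor objective |
| `tau` | 0.004 | L2 penalty on extractor weights |
| `eta` | 1.0 | weight of the encoder losses inside the joint objective |
| `learning_rates` | (0.004, 0.001, 0.001, 0.001) | Adam rates for (f, d, graph, head) |
| `epochs` | 500 | alternating epochs |
| `cutoff` | 0.5 | probability threshold for ACC/SEN/SPE |
| `normalize` | true | full-cohort per-feature z-scoring (population SD; constant columns to zero) |

`beta`, `tau`, `eta`, `alpha`, the learning rates, the epoch count and the
cutoff follow the published training recipe this pipeline re-implements;
`d_c`, `theta` and `C` are not specified there and carry the defaults above.
Normalization is computed on the full cohort deliberately: the method is
transductive (every subject is in the graph at training time), so
full-cohort statistics leak nothing that the graph does not already share.

## Synthetic cohorts

`generate_synthetic` draws, per subject, a latent `z ~ N(±(class_sep/2) u,
I)` in `latent_dim` (default 10) dimensions with a fixed unit class
direction `u`, and observes modality k as `x = M_k z + s_k + eps`: `M_k` a
fixed random map (`N(0,1)/sqrt(latent_dim)` entries; its component along `u`
projected out for modalities declared non-informative), `s_k` a random
offset of norm `modality_shift`, `eps ~ N(0, noise_sd^2)`. Defaults — N=400,
K=4, dims (20, 30, 40, 120), class_sep 4, shift 5, noise 1 — mirror a
cohort with several sub-50-dimensional clinical tables and one wide
(>100-dimensional) connectivity block, balanced classes, and a cross-modal
distribution gap large enough that a linear classifier identifies a feature
vector's modality almost perfectly. Draw order from the root seed (class
direction, per-modality maps and offsets, latents, noise) is fixed, so a
spec reproduces its cohort exactly; `planted_similarity_oracle` recomputes
the latent cosine matrix that a faithful patient graph should correlate
with.

What the generator does **not** emulate: site/batch hierarchies, missing
data, non-Gaussian marginals, and any atlas/ROI semantics of real
connectivity vectors. Passing results on these cohorts demonstrate that the
pipeline's machinery works as specified — recovery of a planted signal,
chance behavior under permuted labels, sane ablation regimes — not that it
attains any particular accuracy on clinical data.

## Reference experiment conditions

Used by `scripts/acceptance.py` and the acceptance tests; sizes were chosen
so each experiment completes in minutes on one CPU while keeping the
estimates stable across seeds.

- **Recovery**: N=200, K=3, dims (20, 30, 120), class_sep 6, 200 epochs,
  5-fold CV, plus a label-permuted control.
- **Ablation**: N=240, K=4, class_sep 2, 200 epochs, five paired single
  splits (60/10/30). class_sep 2 places the full model near 84–86% AUC;
  at class_sep 4 every variant saturates above 99% AUC and the paired
  comparison degenerates into noise, so a ceiling condition cannot speak to
  architecture differences either way.
- **Graph recovery**: N=200, K=3, class_sep 4, 150 epochs, five seeds;
  Pearson correlation of upper triangles against the planted latent cosine,
  for both the learned fused adjacency and a raw-feature baseline (plain
  cosine per modality, same threshold, uniform average).
- **Alignment probe**: N=400, K=4, shift 5, class_sep 4, 300 epochs, five
  seeds; a fresh multinomial logistic probe predicts an embedding's modality
  on held-out subjects (split by subject), chance 1/K.
- **Silhouette**: class-label silhouette (Euclidean) of concatenated learned
  embeddings versus concatenated raw features on one trained cohort.

## Known limitations

Two behaviors of the method, reproduced faithfully here, are worth stating
plainly because the test suite reports them as failures of the corresponding
idealized expectations:

- **The adversarial game does not erase modality identity.** With the
  extractors running at four times the discriminator's learning rate, one
  full-batch step each per epoch, and a squared loss on softmax outputs, the
  extractors perpetually best-respond to the current discriminator rather
  than matching distributions: a freshly trained probe still identifies each
  embedding's modality at 0.9+ accuracy after training (chance 0.25). This
  persists across wide variations of the adversarial weight, discriminator
  architecture and schedule, and is consistent with the qualitative
  observation that aligned multimodal features retain modality specificity.
  The discriminator itself is sound — trained on frozen embeddings it
  reaches ~0.9 modality accuracy — the asymmetric game is the obstacle.
- **The learned graph is a class detector, not a latent-similarity
  regressor.** Supervised training collapses within-class embedding
  variation, so the learned fused adjacency approaches a two-block class
  indicator. It correlates positively with the planted latent cosine
  (~0.72–0.78) but less than a raw-feature cosine graph does (~0.77–0.81),
  because the raw graph preserves the continuous within-class gradations the
  oracle contains.

Other limitations: dense N×N graphs throughout (O(N² d_c) per epoch —
appropriate for cohorts up to a few thousand subjects, not for biobank
scale); binary outcomes only; no missing-data handling (tables must be
complete); full-batch training only.

## Numerical choices

Population (ddof=0) standard deviation in z-scoring, zero-variance columns
mapped to zeros. Cosine similarity raises a degenerate-embedding error when
a projected row's norm falls below 1e-12, naming the subject. Softmax and
cross-entropy always go through max-subtracted log-softmax on logits inside
training (the probability-space `graph_loss` gathers the true-class
probability before the log, so an exactly-correct one-hot prediction
contributes exactly zero). Welch's unequal-variance form for the two-sample
t-test, with the degenerate equal-constant case defined as (t, p) = (0, 1).
AUC is the Mann–Whitney rank statistic with ties counted one half.
Stratified folds, validation carving and all model initializations derive
from one root seed through `numpy.random.SeedSequence` spawning, with a
documented draw order.
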