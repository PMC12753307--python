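# Methods

## Problem setting

Given up to three omics layers (mRNA expression, DNA methylation β-values,
miRNA expression) measured on the same patients with subtype labels, the
package predicts subtypes under two complications: small cohorts (tens of
training samples per class) and *complete modality missingness* — an entire
layer absent, not scattered missing values. Knowledge is transferred from
data-rich cohorts by pretraining shared components and finetuning per
cohort.

## Preprocessing

Features are reduced per modality by a two-step variance ranking:
zero-variance features are removed, the remainder ranked by sample
variance. Pretraining cohorts combine a *common* block — features with
non-zero variance in every cohort, ranked by the mean of per-cohort
variance ranks — with cohort-specific top-variance features; the common
block occupies the first columns in a shared order (the attribution
procedure relies on this). Evaluation cohorts use cohort-specific features
only; widths must match the pretraining widths. Expression layers are
log2(x+1)-transformed; every feature is then z-scored,
`x_std = (x - μ_g)/(σ_g + ε)` with ε = 1e-8; constant features map to
zero. Test samples replay the training-fold statistics (no leakage).
Ties in variance sorts break by original column index, for determinism.

Variance-based selection is not cosmetic here: after z-scoring all columns
have unit variance, so without prior selection the cosine similarities that
define the patient graph are dominated by uninformative features.

## Graphs

Per modality, pairwise cosine distances `d_ij = 1 - cos(x_i, x_j)` are
thresholded at the (k·N)-th smallest off-diagonal value (ordered pairs), so
each sample keeps ≈ k directed neighbours; surviving edges are weighted
`s_ij = max(1 - d_ij, 0)`, a self-loop of weight 1 is added, and rows are
L1-normalised. The default k = 10 was chosen because the graph averaging
doubles as denoising for the encoders; the degree contract is tested at
k ∈ {3, 5} as well. Evaluation is transductive: one graph over train+test
so test samples embed relative to training samples without using labels.

## Architecture

- Encoders: three GCN layers `LeakyReLU(A·H·W)` with widths
  input → 200 → 100 → 100, LeakyReLU slope 0.25, dropout 0.5 on the inputs
  during training (values follow the GCN-fusion lineage this architecture
  derives from).
- Decoder: latents of the observed modalities (fixed order mrna,
  methylation, mirna) are concatenated and passed through a 256-wide core
  (LeakyReLU) and a per-modality output head.
- Heads: one linear layer latent → logits per modality.
- VCDN fusion: per-head softmax probabilities are combined into the
  per-sample outer product (length `C^M`, rows sum to 1), then an MLP with
  one hidden layer of width `C^M` produces the fused logits.

### Latent standardization in the decoder

The reconstruction loss and the `Sim = 1/(1+MSE)` monitor operate on
*standardized* latents: per-dimension centering plus a single scale per
modality (the RMS of the per-dimension SDs), fixed from the decoder's
training fold and de-standardized on output. The raw latent scale of a
LeakyReLU GCN stack is arbitrary and small, which would compress all Sim
values toward 1 and make them incomparable across modalities; a
per-dimension scale would instead inflate pure-noise latent dimensions to
the same weight as structured ones. The single-scale choice keeps the
objective focused on high-variance (structured) dimensions while making
Sim scale-free: the mean-prediction baseline sits near 0.5 by
construction, and gains over it measure genuinely predictable latent
structure.

## Training curriculum

Phase 1 trains encoders, heads and fusion with the focal loss (γ = 2
default) on the fused logits plus each head's logits; class weights
`α_c = N/(C·n_c)` and per-sample weights `w_i = α_{y_i}` rescaled to mean
one mitigate imbalance. Encoders and the decoder are shared across
pretraining cohorts; heads and fusion are per-cohort (label sets differ).
Per-cohort losses are averaged and one full-batch Adam step is taken per
epoch; validation macro-F1 (mean over cohorts) drives plateau LR scheduling
(factor 0.7, patience 10), early stopping, and best-checkpoint selection.

Phase 2 freezes encoders and heads (enforced by parameter hashing) and
trains the decoder: each modality takes a turn as the masked target, the
loss is standardized-latent MSE on training rows, and the early-stopping
statistic is the mean validation Sim across cohorts and modalities. Adam
uses decoupled weight decay (1e-2) and 25 % dropout on the decoder input.

Phase 3 freezes the decoder; per epoch and cohort, with probability
P (default 1/3) one uniformly chosen modality is masked and replaced by the
decoder reconstruction; the loss adds λ·MSE (λ = 1) between the
reconstruction and the (detached) encoded latent. Early stopping is on
complete-input validation macro-F1.

Finetuning on a new cohort initializes fresh heads; the decoder is frozen;
encoders are frozen except the final (latent) layer — the smallest
trainable surface that can adapt latents to a new feature space. Where the
cohort's class count matches a pretraining cohort's, the VCDN is
warm-started from it with only its last linear layer trainable; otherwise
a fresh fully trainable VCDN is used. The objective is weighted
cross-entropy on the complete input plus, for each modality, a
weighted-CE term under the masked+decoder-reconstructed condition
(weight P) and the same latent-alignment MSE as phase 3: without this
exposure the fresh heads and fusion never see reconstructed latents and
behave erratically when the decoder is engaged at assessment. The best
epoch is chosen by the mean validation composite score
`0.2·ACC + 0.2·F1_weighted + 0.6·F1_macro` over those conditions, on a
stratified 25 % split carved from the training partition (never the test
set). Assessment builds the transductive union graph and reports metrics
on test rows only, with a missing modality either decoder-reconstructed or
zero-filled.

## Attribution

Biomarkers are ranked by input × gradient through the single-omics path
with identity adjacency: pseudo-labels are the model's own argmax
predictions, the per-sample loss is the cross-entropy at the pseudo-label,
and `s_g = (1/N) Σ_i |X_ig · ∂ℓ_i/∂X_ig|`. Scores are batch-size-invariant
and never mutate parameters (hash-checked). Shared biomarkers average
`s_g` over pretraining cohorts and restrict to the common block (the first
`d_shared` columns); tumor-specific biomarkers rank a finetuned cohort's
full feature set. Ties break by ascending feature index. The attribution
checkpoint is the finetune variant without masking and without decoder
substitution.

## Synthetic-data generator

Each class c has a latent mean `m_c ~ N(0, class_sep² I)` in a 10-d factor
space (class_sep = 2 by default — separable but not trivial). Sample i
with label y_i draws a shared factor `z_s = m_{y_i} + N(0, I)`; modality o
mixes it with a private factor and a ρ-scaled modality-specific class
mean:

    u_o = ρ·z_s + √(1-ρ²)·z_o + ρ·√(1-ρ²)·m_c^{(o)}

with ρ = `cross_modal_strength`. Informative columns (fraction 0.1) are
`u_o @ L_o` plus Gaussian noise (sd 1); the rest are pure noise. Three
deliberate design choices:

- *Structure is a property of the feature space, not the cohort*: cohorts
  sharing a `structure_seed` share informative-column positions and
  loadings. This mirrors the biological premise that the same molecules
  covary the same way across cancer types — and it is what makes a decoder
  pretrained on some cohorts transferable to an unseen one.
- *The two ρ limits are exact*: at ρ = 0 modalities are fully independent
  and carry no class signal (the negative control for decoder
  learnability); at ρ = 1 with vanishing noise each modality's informative
  block is an exact linear function of any other's.
- *Equal aggregate signal per view*: loadings scale with
  `1/√n_informative`, so the low-dimensional miRNA layer concentrates the
  same total signal in fewer, individually stronger features.

What the generator does not emulate: count overdispersion, β-value
bimodality, batch effects, feature-feature correlation beyond the latent
factors, or label noise. Passing benchmarks therefore demonstrate the
mechanics of the architecture — cross-modal latent recovery, imbalance
handling, attribution — not clinical performance on real cohorts.

## Benchmark problem sizes

The packaged benchmarks (`mogedn.benchmarks`) use two pretraining cohorts
of n = 200 and one evaluation cohort of n = 200 split 50/50, i.e.
n_train = 100 — the small-sample regime the method targets. Epoch budgets
are 250/400/200 for the three phases and 250 for finetuning with
early-stop patience 60. Attribution benchmarks use widths 400/400/200 (the
2:2:1 modality ratio at a scale where each modality plants at least 20
informative features, so a top-20 list is well-posed).

## Known limitations

- The decoder's output is a function of the observed modalities' latents,
  so against a *matched-trained* zero-fill ablation its advantage is an
  efficiency/conditioning effect, not an information gain. Empirically the
  advantage is large and reliable when the masked modality is
  load-bearing (see the worked example: +0.20 macro-F1 for missing mRNA)
  and vanishes into exact ties when the remaining layers already saturate
  the task, which on the synthetic benchmark is common for masked miRNA.
- Full-batch training: cohorts are assumed to fit in memory (hundreds to a
  few thousand samples).
- A single missing modality is supported at inference; two simultaneously
  missing layers are out of scope.
- Numerical safety: probabilities are clamped at 1e-12 before logs;
  near-dead latent dimensions are protected by a floor on the
  standardization scale.
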