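# mogedn

Multi-omics cancer-subtype classification that keeps working when an entire
omics layer is missing.

Molecular subtypes (e.g. BRCA LumA/LumB/Her2/Basal) are routinely predicted
from three omics layers measured on the same patients — mRNA expression,
DNA methylation β-values and miRNA expression — but real cohorts are small
(often n < 100) and frequently lack a whole layer for cost or technical
reasons. `mogedn` implements an encoder–decoder architecture for this
setting:

- **Per-omics GCN encoders** `E_o` embed each patient over a
  patient-similarity graph (cosine-distance thresholded to ≈ k neighbours,
  self-loops, row-L1-normalised) through widths `input → 200 → 100 → 100`.
- **A shared multi-head decoder** `D` reconstructs the 100-d latent of a
  missing modality from the concatenated latents of the observed ones:
  `Ẑ_o = D(concat(Z_j), j ≠ o)`, trained with latent MSE and monitored by
  `Sim = 1/(1 + MSE)`.
- **Single-omics heads** `C_o` and a **VCDN fusion classifier** combine
  per-modality class probabilities through their outer product
  (length `C^M`), capturing cross-omics class co-occurrence.
- **A three-phase curriculum**: (1) supervised pretraining of encoders,
  heads and fusion across several cohorts with the class- and
  sample-weighted focal loss
  `L_cls = -(1/N) Σ_i w_i Σ_c α_c y_ic (1 - p_ic)^γ log p_ic`;
  (2) decoder training on frozen-encoder latents; (3) joint adaptation
  under simulated missingness with the decoder frozen and
  `L_total = L_cls + λ L_recon`. A per-cohort finetune (weighted
  cross-entropy, most encoder layers frozen, epoch selection by
  `0.2·ACC + 0.2·F1_weighted + 0.6·F1_macro`) adapts the backbone to a new
  cohort; assessment is transductive (one train+test graph).
- **Biomarker identification** by input × gradient attribution
  `s_g = (1/N) Σ_i |X_ig · ∂ℓ_i/∂X_ig|` through the single-omics path with
  identity adjacency, yielding shared (cross-cohort) and tumor-specific
  rankings.

All networks run on a small reverse-mode autodiff engine over numpy
(`mogedn.autograd`), with hand-written Adam and plateau LR scheduling, so
fixed-seed runs are bit-reproducible on CPU. A seeded synthetic-cohort
generator (`mogedn.synthdata`) provides multi-class, class-imbalanced
multi-omics data with a tunable cross-modality dependence ρ, used by the
test-suite benchmarks. See `docs/methods.md` for the model and generator
details.

## Worked example

```python
from mogedn import SynthSpec, TrainConfig, make_corpus, make_eval_dataset
from mogedn.train_phases import run_pretraining
from mogedn.evaluate import finetune, scenario_sweep

corpus = make_corpus([SynthSpec(n_samples=200, seed=100),
                      SynthSpec(n_samples=200, seed=200)])
config = TrainConfig(max_epochs_phase1=250, max_epochs_phase2=400,
                     max_epochs_phase3=200, max_epochs_finetune=250,
                     early_stop_patience=60, seed=0)
pretrained = run_pretraining(corpus, config)
for phase, history in pretrained.histories.items():
    key = "val_sim" if phase == "phase2" else "val_f1_macro"
    print(f"{phase}: {len(history)} epochs, best {key} = "
          f"{max(h[key] for h in history):.3f}")

cohort, _, _, _ = make_eval_dataset(SynthSpec(n_samples=200, seed=300),
                                    test_fraction=0.5)
tuned = finetune(pretrained, cohort, config)
print(scenario_sweep(tuned.model, cohort).to_string(index=False))
```

prints (about a minute on one CPU core):

```
phase1: 87 epochs, best val_f1_macro = 0.986
phase2: 196 epochs, best val_sim = 0.800
phase3: 63 epochs, best val_f1_macro = 0.986
           scenario  use_decoder  acc  f1_weighted  f1_macro
           complete         True 0.89     0.891901  0.862203
       missing_mrna         True 0.89     0.889536  0.853007
       missing_mrna        False 0.64     0.650463  0.657276
missing_methylation         True 0.83     0.827962  0.765763
missing_methylation        False 0.80     0.786463  0.700605
      missing_mirna         True 0.90     0.901701  0.874150
      missing_mirna        False 0.90     0.901701  0.874150
```

Reading the table: with complete omics the finetuned model reaches 0.86
macro-F1 on the held-out test half (n = 100). When the mRNA layer is
missing entirely, zero-filling its latent collapses macro-F1 to 0.66, while
decoder reconstruction recovers it to 0.85 — the architecture's central
effect. When the remaining two layers already carry enough signal (here the
miRNA row), decoder and zero fill tie at the ceiling.

The same pipeline is scriptable from the shell: `mogedn synth`,
`mogedn pretrain`, `mogedn finetune`, `mogedn assess`, `mogedn attribute`
(see `mogedn --help`); every run writes a manifest with the config hash and
seed for exact reruns.

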