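"""Reproducible end-to-end benchmarks on synthetic cohorts.

Each function runs one self-contained experiment at desk scale: two
pretraining cohorts of n=200 samples (three modalities, three imbalanced
subtypes each) and, where applicable, one evaluation cohort of n=200 split
50/50 into train/test — the small-sample regime (n_train = 100) the method
targets.  Problem sizes and epoch budgets are fixed here so results are
comparable across seeds.
"""

from __future__ import annotations

import numpy as np

from .evaluate import EvalScenario, assess, finetune, scenario_sweep
from .synthdata import SynthSpec, generate, make_corpus, make_eval_dataset
from .train_phases import (TrainConfig, _frozen_latents, build_pretrain_models,
                           mean_baseline_sim, phase1, phase2, run_pretraining)

__all__ = ["phase2_sim_gain", "missing_omics_run", "attribution_recovery"]

MODALITIES = ("mrna", "methylation", "mirna")


def _config(seed: int, **kw) -> TrainConfig:
    base = dict(max_epochs_phase1=250, max_epochs_phase2=400,
                max_epochs_phase3=200, max_epochs_finetune=250,
                early_stop_patience=60, seed=seed)
    base.update(kw)
    return TrainConfig(**base)


def _corpus_specs(seed: int, rho: float = 0.9, n_samples: int = 200,
                  dims: dict | None = None) -> list[SynthSpec]:
    kw = {} if dims is None else {"dims": dict(dims)}
    return [SynthSpec(n_samples=n_samples, seed=100 + seed,
                      cross_modal_strength=rho, **kw),
            SynthSpec(n_samples=n_samples, seed=200 + seed,
                      cross_modal_strength=rho, **kw)]


def phase2_sim_gain(seed: int, rho: float) -> float:
    """Validation Sim of the trained decoder minus the mean-prediction
    baseline Sim, after phases 1-2 on a two-cohort corpus at the given
    cross-modality strength."""
    corpus = make_corpus(_corpus_specs(seed, rho))
    cfg = _config(seed, early_stop_patience=40)
    models = build_pretrain_models(corpus, cfg)
    phase1(corpus, models, cfg)
    history = phase2(corpus, models, cfg)
    shared = next(iter(models.values()))
    latents = _frozen_latents(models, corpus)
    baseline = float(np.mean([
        mean_baseline_sim(latents[c.name], c.val_idx, shared.decoder)
        for c in corpus.cohorts]))
    return max(h["val_sim"] for h in history) - baseline


def missing_omics_run(seed: int) -> dict:
    """Full curriculum + finetune on one evaluation cohort; returns the
    complete-omics test macro-F1 and, per masked modality, the macro-F1
    with decoder reconstruction vs zero fill."""
    corpus = make_corpus(_corpus_specs(seed))
    cfg = _config(seed)
    pretrain = run_pretraining(corpus, cfg)
    dataset, _, _, _ = make_eval_dataset(
        SynthSpec(n_samples=200, seed=300 + seed), test_fraction=0.5)
    ft = finetune(pretrain, dataset, cfg)
    table = scenario_sweep(ft.model, dataset)
    out = {"complete_f1_macro": float(
        table[table.scenario == "complete"].f1_macro.iloc[0])}
    for m in MODALITIES:
        rows = table[table.scenario == f"missing_{m}"]
        out[m] = {
            "decoder": float(rows[rows.use_decoder].f1_macro.iloc[0]),
            "zero_fill": float(rows[~rows.use_decoder].f1_macro.iloc[0]),
        }
    return out


ATTRIBUTION_DIMS = {"mrna": 400, "methylation": 400, "mirna": 200}


def attribution_recovery(seed: int, k_top: int = 20) -> dict[str, float]:
    """Fraction of the top-k tumor-specific attributions that are planted
    informative features, per modality, on a finetuned evaluation cohort.

    Widths follow the 2:2:1 modality ratio at a scale where each modality
    plants at least k informative features, so the top-k list is not
    truncated below the criterion by construction.
    """
    from .attribution import tumor_specific_biomarkers

    corpus = make_corpus(_corpus_specs(seed, dims=ATTRIBUTION_DIMS))
    cfg = _config(seed, max_epochs_phase1=200, max_epochs_phase2=60,
                  max_epochs_phase3=60, max_epochs_finetune=200,
                  early_stop_patience=40)
    pretrain = run_pretraining(corpus, cfg)
    dataset, raw, _, _ = make_eval_dataset(
        SynthSpec(n_samples=200, seed=300 + seed, dims=dict(ATTRIBUTION_DIMS)))
    # attribution checkpoint: selected without masking / decoder substitution
    ft = finetune(pretrain, dataset, cfg, mask_prob=0.0, align_lambda=0.0)
    results = tumor_specific_biomarkers(ft.model, dataset.train_views,
                                        k_top=k_top)
    out = {}
    for m in MODALITIES:
        planted = {raw.views[m].feature_names[i] for i in raw.informative[m]}
        top = set(results[m].top_features[:k_top])
        out[m] = len(top & planted) / k_top
    return out
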