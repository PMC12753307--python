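"""Per-cohort finetuning and assessment under missing-omics scenarios.

Finetuning initializes fresh single-omics heads and a VCDN for the target
cohort, keeps the pretrained decoder frozen, freezes all encoder layers
except the final (latent) layer, and trains with weighted cross-entropy.
Where the cohort's class count matches a pretraining cohort's, the VCDN is
warm-started from it and only its last linear layer remains trainable;
otherwise a fresh fully trainable VCDN is used.  The best epoch is chosen by
the composite score 0.2*ACC + 0.2*F1w + 0.6*F1m on a stratified validation
split carved from the training partition.

Assessment builds a transductive train+test graph per modality, runs the
forward pass with the scenario's missing modality either decoder-
reconstructed or zero-filled, and reports metrics on the test rows only.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from .autograd import Tensor, softmax
from .graphs import build_graph, build_transductive_graph
from .losses_metrics import (MetricReport, balanced_class_weights, metrics,
                             recon_loss, weighted_ce)
from .model import MogednModel, VCDN
from .nn import (Adam, Linear, ReduceLROnPlateau, clone_state, load_state,
                 params_hash)
from .preprocess import OmicsView
from .train_phases import PretrainResult, TrainConfig, _EarlyStopper

__all__ = ["EvalDataset", "EvalScenario", "FinetuneResult", "finetune",
           "assess", "scenario_sweep"]


@dataclass
class EvalDataset:
    """One evaluation cohort with a fixed train/test partition.

    Views are already normalized (test replayed with training statistics)
    and reduced to the model's input widths (tumor-specific mode).
    """

    name: str
    train_views: dict[str, OmicsView]
    test_views: dict[str, OmicsView]
    y_train: np.ndarray
    y_test: np.ndarray
    label_names: list[str]

    def __post_init__(self):
        self.y_train = np.asarray(self.y_train, dtype=int)
        self.y_test = np.asarray(self.y_test, dtype=int)

    @property
    def n_classes(self) -> int:
        return len(self.label_names)

    @property
    def modalities(self) -> list[str]:
        return list(self.train_views)


@dataclass
class EvalScenario:
    """missing_modality None = complete omics; use_decoder selects decoder
    reconstruction vs zero fill for the masked latent."""

    missing_modality: str | None = None
    use_decoder: bool = True
    seed: int = 0


@dataclass
class FinetuneResult:
    model: MogednModel
    history: list[dict]
    best_val: dict


def _build_finetune_model(pretrain: PretrainResult,
                          dataset: EvalDataset,
                          rng: np.random.Generator,
                          ) -> tuple[MogednModel, dict, bool]:
    """Deep-copy the shared backbone, attach fresh heads/fusion, and return
    (model, trainable param dict, fusion_warm_started)."""
    shared = pretrain.shared_model
    model = MogednModel(
        modalities=list(shared.modalities),
        encoders=copy.deepcopy(shared.encoders),
        decoder=copy.deepcopy(shared.decoder),
        heads={m: Linear(100, dataset.n_classes, rng)
               for m in shared.modalities},
        fusion=VCDN(dataset.n_classes, len(shared.modalities), rng),
        n_classes=dataset.n_classes,
    )
    warm = False
    for name, donor in pretrain.models.items():
        if donor.n_classes == dataset.n_classes:
            model.fusion = copy.deepcopy(donor.fusion)
            warm = True
            break
    trainable: dict[str, Tensor] = {}
    for m in model.modalities:  # only the final (latent) encoder layer adapts
        last = model.encoders[m].layers[-1]
        trainable.update(last.params(f"encoder_{m}.layer_last"))
    trainable.update(model.head_params())
    if warm:  # earlier fusion layers stay frozen; last linear layer adapts
        trainable.update(model.fusion.out.params("fusion.out"))
    else:
        trainable.update(model.fusion_params())
    return model, trainable, warm


def finetune(pretrain: PretrainResult, dataset: EvalDataset,
             config: TrainConfig, edge_per_node: int = 10,
             mask_prob: float | None = None,
             align_lambda: float | None = None) -> FinetuneResult:
    """Adapt the pretrained backbone to one cohort with weighted CE.

    With ``mask_prob`` > 0 (default: the config's mask probability), the
    per-epoch objective adds, on top of the complete-omics weighted CE, a
    weighted-CE term for each single-modality-masked condition with the
    frozen decoder's reconstruction substituted, scaled by ``mask_prob``.
    This exposes the new heads and fusion to reconstructed latents and pulls
    the trainable encoder layers toward decoder-compatible latents.  Epoch
    selection uses the mean validation composite over the same conditions.
    Pass ``mask_prob=0`` for the complete-omics-only variant used to select
    the attribution checkpoint.
    """
    if mask_prob is None:
        mask_prob = config.mask_prob
    if align_lambda is None:
        align_lambda = config.lambda_recon
    mask_weight = mask_prob  # weight of each masked-condition CE term
    rng = np.random.default_rng([config.seed, 11])
    model, trainable, _ = _build_finetune_model(pretrain, dataset, rng)
    dec_hash = params_hash(model.decoder_params())
    trainable_ids = {id(p) for p in trainable.values()}
    frozen_enc = {k: v for k, v in model.encoder_params().items()
                  if id(v) not in trainable_ids}
    frozen_hash = params_hash(frozen_enc)

    n_train = dataset.y_train.size
    missing_in_train = sorted(set(range(dataset.n_classes))
                              - set(dataset.y_train.tolist()))
    if missing_in_train:
        import warnings
        warnings.warn(f"classes {missing_in_train} absent from training fold; "
                      "they contribute 0 to macro-F1")
    tr_idx, val_idx = train_test_split(
        np.arange(n_train), test_size=0.25, stratify=dataset.y_train,
        random_state=config.seed % (2**32))
    graphs = {m: build_graph(dataset.train_views[m], edge_per_node)
              for m in dataset.modalities}
    alpha = balanced_class_weights(dataset.y_train[tr_idx])
    w_tr = alpha[dataset.y_train[tr_idx]]
    w_tr = w_tr / w_tr.mean()

    opt = Adam(trainable, lr=config.lr_finetune)
    sched = ReduceLROnPlateau(opt, mode="max", factor=config.scheduler_factor,
                              patience=config.scheduler_patience)
    stopper = _EarlyStopper(config.early_stop_patience, trainable)
    history: list[dict] = []
    best_val: dict = {}
    for epoch in range(config.max_epochs_finetune):
        opt.zero_grad()
        y_tr = dataset.y_train[tr_idx]
        conditions = [None] + (list(model.modalities) if mask_prob > 0 else [])
        loss = None
        for mask in conditions:
            z = {m: model.encode(dataset.train_views[m], graphs[m], m,
                                 training=True, rng=rng)
                 for m in model.modalities}
            align = None
            if mask is not None:
                others = {m: t for m, t in z.items() if m != mask}
                z_hat_std = model.decoder.decode_std(others, mask)
                if align_lambda > 0:
                    tgt_std = model.decoder.standardize(
                        Tensor(z[mask].data), mask)
                    align = recon_loss(z_hat_std[tr_idx], tgt_std[tr_idx])
                z[mask] = z_hat_std * Tensor(model.decoder.latent_sigma[mask]) \
                    + Tensor(model.decoder.latent_mu[mask])
            per_head = {m: model.classify_head(z[m], m)
                        for m in model.modalities}
            fused = model.vcdn_fuse([per_head[m] for m in model.modalities])
            term = weighted_ce(softmax(fused[tr_idx], axis=1), y_tr, w_tr)
            for m in model.modalities:
                term = term + weighted_ce(softmax(per_head[m][tr_idx], axis=1),
                                          y_tr, w_tr)
            if align is not None:
                term = term + align_lambda * align
            if mask is not None:
                term = term * mask_weight
            loss = term if loss is None else loss + term
        if not np.isfinite(loss.data):
            raise FloatingPointError(f"non-finite loss at finetune epoch {epoch}")
        loss.backward()
        opt.step()

        composites = []
        pred_val = None
        for mask in conditions:
            fused_eval, _, _ = model.forward(dataset.train_views, graphs,
                                             missing=mask, use_decoder=True,
                                             training=False)
            pred = fused_eval.data[val_idx].argmax(axis=1)
            rep = metrics(pred, dataset.y_train[val_idx],
                          n_classes=dataset.n_classes)
            composites.append(rep.composite)
            if mask is None:
                pred_val = pred
                rep_complete = rep
        val_score = float(np.mean(composites))
        sched.step(val_score)
        history.append({"epoch": epoch, "train_loss": float(loss.data),
                        "val_composite": rep_complete.composite,
                        "val_score": val_score,
                        "val_f1_macro": rep_complete.f1_macro, "lr": opt.lr})
        if val_score > stopper.best:
            best_val = {"epoch": epoch, "composite": rep_complete.composite,
                        "score": val_score, "pred": pred_val.tolist(),
                        "true": dataset.y_train[val_idx].tolist()}
        if stopper.update(val_score, epoch):
            break
    if history:
        stopper.restore()
        history[-1]["early_stop_epoch"] = stopper.best_epoch
    if params_hash(model.decoder_params()) != dec_hash:
        raise RuntimeError("decoder drifted during finetuning (freeze violated)")
    if params_hash(frozen_enc) != frozen_hash:
        raise RuntimeError("frozen encoder layers drifted during finetuning")
    return FinetuneResult(model=model, history=history, best_val=best_val)


def assess(model: MogednModel, dataset: EvalDataset,
           scenario: EvalScenario, edge_per_node: int = 10) -> MetricReport:
    """Transductive evaluation on the test partition under one scenario."""
    if (scenario.missing_modality is not None
            and scenario.missing_modality not in model.modalities):
        raise ValueError(f"unknown modality {scenario.missing_modality!r}")
    union_views: dict[str, OmicsView] = {}
    union_graphs = {}
    is_test = None
    for m in dataset.modalities:
        g, mask = build_transductive_graph(dataset.train_views[m],
                                           dataset.test_views[m],
                                           edge_per_node)
        union_graphs[m] = g
        is_test = mask
        tv, sv = dataset.train_views[m], dataset.test_views[m]
        union_views[m] = replace(
            tv, matrix=np.vstack([tv.matrix, sv.matrix]),
            sample_ids=list(tv.sample_ids) + list(sv.sample_ids))
    fused, _, _ = model.forward(union_views, union_graphs,
                                missing=scenario.missing_modality,
                                use_decoder=scenario.use_decoder,
                                training=False)
    pred = fused.data[is_test].argmax(axis=1)
    return metrics(pred, dataset.y_test, n_classes=dataset.n_classes)


def scenario_sweep(model: MogednModel, dataset: EvalDataset,
                   edge_per_node: int = 10) -> pd.DataFrame:
    """Complete omics plus {each single modality} x {decoder on/off}:
    2M + 1 rows for M modalities (7 for three)."""
    rows = []
    rep = assess(model, dataset, EvalScenario(None, True), edge_per_node)
    rows.append({"scenario": "complete", "use_decoder": True,
                 "acc": rep.acc, "f1_weighted": rep.f1_weighted,
                 "f1_macro": rep.f1_macro})
    for m in model.modalities:
        for use_dec in (True, False):
            rep = assess(model, dataset, EvalScenario(m, use_dec),
                         edge_per_node)
            rows.append({"scenario": f"missing_{m}", "use_decoder": use_dec,
                         "acc": rep.acc, "f1_weighted": rep.f1_weighted,
                         "f1_macro": rep.f1_macro})
    return pd.DataFrame(rows)
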