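"""Three-phase pretraining across multiple cohorts.

Phase 1 trains the per-omics GCN encoders, single-omics heads and VCDN
fusion with the class- and sample-weighted focal loss (fused logits plus the
per-head logits); early stopping monitors the mean validation macro-F1
across cohorts.  Phase 2 freezes encoders and heads and trains the shared
decoder to reconstruct each modality's latent from the others, monitored by
the mean latent similarity Sim = 1/(1+MSE).  Phase 3 freezes the decoder and
adapts encoders, heads and fusion under simulated missingness: each epoch,
with probability P, one modality per cohort is masked and its latent
replaced by the decoder reconstruction; the loss is L_cls + lambda*L_recon.

Encoders and the decoder are shared across cohorts; heads and fusion are
per-cohort (the cohorts' label sets differ).  Per-cohort losses are averaged
and one optimizer step is taken per epoch.  Freeze contracts are enforced by
hashing the frozen parameter groups across each phase.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, asdict

import numpy as np

from .autograd import Tensor, softmax
from .graphs import SampleGraph
from .losses_metrics import (LossConfig, balanced_class_weights, focal_loss,
                             metrics, recon_loss, sample_weights, similarity)
from .model import LATENT_DIM, MogednModel
from .nn import Adam, ReduceLROnPlateau, clone_state, load_state, params_hash
from .preprocess import OmicsView

__all__ = ["TrainConfig", "Cohort", "PretrainCorpus", "PretrainResult",
           "build_pretrain_models", "phase1", "phase2", "phase3",
           "run_pretraining"]


@dataclass
class TrainConfig:
    """Hyperparameters the training curriculum leaves open."""

    lr_phase1: float = 5e-3
    lr_phase2: float = 5e-3
    lr_phase3: float = 2e-3
    lr_finetune: float = 5e-3
    max_epochs_phase1: int = 500
    max_epochs_phase2: int = 300
    max_epochs_phase3: int = 300
    max_epochs_finetune: int = 300
    early_stop_patience: int = 30
    scheduler_factor: float = 0.7
    scheduler_patience: int = 10
    mask_prob: float = 1.0 / 3.0
    lambda_recon: float = 1.0
    decoder_weight_decay: float = 1e-2
    encoder_weight_decay: float = 1e-3
    gamma: float = 2.0
    seed: int = 0
    device: str = "cpu"  # hint only; this implementation is CPU numpy

    def __post_init__(self):
        if not 0.0 < self.scheduler_factor < 1.0:
            raise ValueError("scheduler_factor must lie in (0, 1)")
        if self.scheduler_patience < 1 or self.early_stop_patience < 1:
            raise ValueError("patience values must be >= 1")
        if not 0.0 <= self.mask_prob <= 1.0:
            raise ValueError("mask_prob must lie in [0, 1]")


@dataclass
class Cohort:
    """One pretraining cohort: normalized views, labels, graphs, split."""

    name: str
    views: dict[str, OmicsView]
    labels: np.ndarray
    label_names: list[str]
    graphs: dict[str, SampleGraph]
    train_idx: np.ndarray
    val_idx: np.ndarray

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        self.train_idx = np.asarray(self.train_idx, dtype=int)
        self.val_idx = np.asarray(self.val_idx, dtype=int)
        ids = None
        for v in self.views.values():
            if ids is None:
                ids = v.sample_ids
            elif v.sample_ids != ids:
                raise ValueError(f"{self.name}: modalities disagree on samples")
        if set(self.train_idx) & set(self.val_idx):
            raise ValueError(f"{self.name}: train/val splits overlap")

    @property
    def n_classes(self) -> int:
        return len(self.label_names)


@dataclass
class PretrainCorpus:
    cohorts: list[Cohort]

    def __post_init__(self):
        if not self.cohorts:
            raise ValueError("corpus must contain at least one cohort")

    @property
    def modalities(self) -> list[str]:
        return list(self.cohorts[0].views)


@dataclass
class PretrainResult:
    """Models + bookkeeping produced by the pretraining curriculum."""

    models: dict[str, MogednModel]  # per cohort; encoders/decoder shared
    config: TrainConfig
    histories: dict[str, list[dict]] = field(default_factory=dict)

    @property
    def shared_model(self) -> MogednModel:
        return next(iter(self.models.values()))


def build_pretrain_models(corpus: PretrainCorpus,
                          config: TrainConfig) -> dict[str, MogednModel]:
    """One model per cohort sharing encoder and decoder parameter objects."""
    rng = np.random.default_rng([config.seed, 0])
    in_dims = {m: corpus.cohorts[0].views[m].n_features
               for m in corpus.modalities}
    for c in corpus.cohorts:
        for m in corpus.modalities:
            if c.views[m].n_features != in_dims[m]:
                raise ValueError(
                    f"cohort {c.name} width mismatch for {m}: "
                    f"{c.views[m].n_features} != {in_dims[m]}")
    first = MogednModel.build(in_dims, corpus.cohorts[0].n_classes, rng)
    models = {corpus.cohorts[0].name: first}
    for c in corpus.cohorts[1:]:
        m = MogednModel.build(in_dims, c.n_classes, rng)
        m.encoders = first.encoders  # share parameters by reference
        m.decoder = first.decoder
        models[c.name] = m
    return models


def _loss_config(labels: np.ndarray, idx: np.ndarray,
                 config: TrainConfig) -> LossConfig:
    y = labels[idx]
    return LossConfig(gamma=config.gamma,
                      alpha=balanced_class_weights(y),
                      sample_weights=sample_weights(y),
                      lambda_recon=config.lambda_recon,
                      mask_prob=config.mask_prob)


def _onehot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    out = np.zeros((labels.size, n_classes))
    out[np.arange(labels.size), labels] = 1.0
    return out


def _classification_loss(model: MogednModel, cohort: Cohort,
                         fused, per_head, lcfg: LossConfig):
    idx = cohort.train_idx
    y = _onehot(cohort.labels[idx], cohort.n_classes)
    loss = focal_loss(softmax(fused[idx], axis=1), y, lcfg)
    for m in model.modalities:
        loss = loss + focal_loss(softmax(per_head[m][idx], axis=1), y, lcfg)
    return loss


def _val_f1_macro(model: MogednModel, cohort: Cohort) -> float:
    fused, _, _ = model.forward(cohort.views, cohort.graphs, training=False)
    pred = fused.data[cohort.val_idx].argmax(axis=1)
    rep = metrics(pred, cohort.labels[cohort.val_idx],
                  n_classes=cohort.n_classes)
    return rep.f1_macro


class _EarlyStopper:
    """Track the best monitored value and the trainable-parameter snapshot."""

    def __init__(self, patience: int, params: dict):
        self.patience = patience
        self.params = params
        self.best = -np.inf
        self.best_state = clone_state(params)
        self.best_epoch = -1
        self.bad = 0

    def update(self, value: float, epoch: int) -> bool:
        """Returns True when training should stop."""
        if value > self.best:
            self.best = value
            self.best_state = clone_state(self.params)
            self.best_epoch = epoch
            self.bad = 0
            return False
        self.bad += 1
        return self.bad >= self.patience

    def restore(self):
        load_state(self.params, self.best_state)


def phase1(corpus: PretrainCorpus, models: dict[str, MogednModel],
           config: TrainConfig) -> list[dict]:
    """Supervised pretraining of encoders, heads and fusion (decoder untouched)."""
    for c in corpus.cohorts:
        if len(np.unique(c.labels[c.train_idx])) < 2:
            raise ValueError(f"cohort {c.name} has a single class in training")
    rng = np.random.default_rng([config.seed, 1])
    shared = next(iter(models.values()))
    trainable = dict(shared.encoder_params())
    for name, model in models.items():
        for k, p in {**model.head_params(), **model.fusion_params()}.items():
            trainable[f"{name}:{k}"] = p
    decoder_hash = params_hash(shared.decoder_params())
    lcfgs = {c.name: _loss_config(c.labels, c.train_idx, config)
             for c in corpus.cohorts}

    opt = Adam(trainable, lr=config.lr_phase1,
               weight_decay=config.encoder_weight_decay)
    sched = ReduceLROnPlateau(opt, mode="max", factor=config.scheduler_factor,
                              patience=config.scheduler_patience)
    stopper = _EarlyStopper(config.early_stop_patience, trainable)
    history: list[dict] = []
    for epoch in range(config.max_epochs_phase1):
        opt.zero_grad()
        total = None
        for c in corpus.cohorts:
            model = models[c.name]
            fused, per_head, _ = model.forward(c.views, c.graphs,
                                               training=True, rng=rng)
            loss = _classification_loss(model, c, fused, per_head, lcfgs[c.name])
            total = loss if total is None else total + loss
        total = total / float(len(corpus.cohorts))
        if not np.isfinite(total.data):
            raise FloatingPointError(f"non-finite loss at phase-1 epoch {epoch}")
        total.backward()
        opt.step()
        val = float(np.mean([_val_f1_macro(models[c.name], c)
                             for c in corpus.cohorts]))
        sched.step(val)
        history.append({"epoch": epoch, "train_loss": float(total.data),
                        "val_f1_macro": val, "lr": opt.lr})
        if stopper.update(val, epoch):
            break
    if history:
        stopper.restore()
        history[-1]["early_stop_epoch"] = stopper.best_epoch
    if params_hash(shared.decoder_params()) != decoder_hash:
        raise RuntimeError("decoder drifted during phase 1")
    return history


def _frozen_latents(models: dict[str, MogednModel],
                    corpus: PretrainCorpus) -> dict[str, dict[str, np.ndarray]]:
    out = {}
    for c in corpus.cohorts:
        model = models[c.name]
        out[c.name] = {m: model.encode(c.views[m], c.graphs[m], m).data
                       for m in model.modalities}
    return out


def mean_baseline_sim(latents: dict[str, np.ndarray], idx: np.ndarray,
                      decoder=None) -> float:
    """Sim of predicting each latent entry by its training-fold mean — the
    no-cross-modal-information baseline a decoder must beat.  When a decoder
    is given, the comparison happens in its standardized latent space (the
    space the reconstruction loss uses); the training mean is then zero."""
    sims = []
    for m, z in latents.items():
        z = z[idx]
        if decoder is not None:
            z = (z - decoder.latent_mu[m]) / decoder.latent_sigma[m]
            mse = float((z**2).mean())
        else:
            mse = float(((z - z.mean(axis=0)) ** 2).mean())
        sims.append(similarity(mse))
    return float(np.mean(sims))


def phase2(corpus: PretrainCorpus, models: dict[str, MogednModel],
           config: TrainConfig) -> list[dict]:
    """Decoder pretraining on frozen-encoder latents (latent reconstruction)."""
    shared = next(iter(models.values()))
    enc_hash = params_hash(shared.encoder_params())
    latents = _frozen_latents(models, corpus)
    for m in shared.modalities:
        pooled = np.vstack([latents[c.name][m][c.train_idx]
                            for c in corpus.cohorts])
        shared.decoder.set_latent_stats(m, pooled.mean(axis=0),
                                        pooled.std(axis=0))

    rng = np.random.default_rng([config.seed, 2])
    opt = Adam(shared.decoder_params(), lr=config.lr_phase2,
               weight_decay=config.decoder_weight_decay)
    sched = ReduceLROnPlateau(opt, mode="max", factor=config.scheduler_factor,
                              patience=config.scheduler_patience)
    stopper = _EarlyStopper(config.early_stop_patience, opt.params)
    history: list[dict] = []
    for epoch in range(config.max_epochs_phase2):
        opt.zero_grad()
        total = None
        for c in corpus.cohorts:
            z = {m: Tensor(latents[c.name][m]) for m in shared.modalities}
            for target in shared.modalities:
                others = {m: t for m, t in z.items() if m != target}
                z_hat = shared.decoder.decode_std(others, target,
                                                  training=True, rng=rng)
                tgt = shared.decoder.standardize(z[target], target)
                loss = recon_loss(z_hat[c.train_idx], tgt[c.train_idx])
                total = loss if total is None else total + loss
        total = total / float(len(corpus.cohorts) * len(shared.modalities))
        if not np.isfinite(total.data):
            raise FloatingPointError(f"non-finite loss at phase-2 epoch {epoch}")
        total.backward()
        opt.step()

        sims = []
        for c in corpus.cohorts:
            z = {m: Tensor(latents[c.name][m]) for m in shared.modalities}
            for target in shared.modalities:
                others = {m: t for m, t in z.items() if m != target}
                z_hat = shared.decoder.decode_std(others, target)
                tgt = shared.decoder.standardize(z[target], target)
                mse = recon_loss(z_hat.data[c.val_idx], tgt.data[c.val_idx])
                sims.append(similarity(mse))
        val = float(np.mean(sims))
        sched.step(val)
        history.append({"epoch": epoch, "train_loss": float(total.data),
                        "val_sim": val, "lr": opt.lr})
        if stopper.update(val, epoch):
            break
    if history:
        stopper.restore()
        history[-1]["early_stop_epoch"] = stopper.best_epoch
    if params_hash(shared.encoder_params()) != enc_hash:
        raise RuntimeError("encoders drifted during phase 2 (freeze violated)")
    return history


def phase3(corpus: PretrainCorpus, models: dict[str, MogednModel],
           config: TrainConfig) -> list[dict]:
    """Joint adaptation under simulated missingness with the decoder frozen."""
    for c in corpus.cohorts:
        if len(np.unique(c.labels[c.train_idx])) < 2:
            raise ValueError(f"cohort {c.name} has a single class in training")
    rng = np.random.default_rng([config.seed, 3])
    shared = next(iter(models.values()))
    dec_hash = params_hash(shared.decoder_params())
    trainable = dict(shared.encoder_params())
    for name, model in models.items():
        for k, p in {**model.head_params(), **model.fusion_params()}.items():
            trainable[f"{name}:{k}"] = p
    lcfgs = {c.name: _loss_config(c.labels, c.train_idx, config)
             for c in corpus.cohorts}

    opt = Adam(trainable, lr=config.lr_phase3,
               weight_decay=config.encoder_weight_decay)
    sched = ReduceLROnPlateau(opt, mode="max", factor=config.scheduler_factor,
                              patience=config.scheduler_patience)
    stopper = _EarlyStopper(config.early_stop_patience, trainable)
    history: list[dict] = []
    for epoch in range(config.max_epochs_phase3):
        opt.zero_grad()
        total = None
        masked_this_epoch = []
        for c in corpus.cohorts:
            model = models[c.name]
            mask = None
            if rng.random() < config.mask_prob:
                mask = model.modalities[rng.integers(len(model.modalities))]
            masked_this_epoch.append(mask)
            z = {m: model.encode(c.views[m], c.graphs[m], m,
                                 training=True, rng=rng)
                 for m in model.modalities}
            loss_recon = None
            if mask is not None:
                others = {m: t for m, t in z.items() if m != mask}
                z_hat_std = model.decoder.decode_std(others, mask)
                tgt_std = model.decoder.standardize(
                    Tensor(z[mask].data), mask)
                loss_recon = recon_loss(z_hat_std[c.train_idx],
                                        tgt_std[c.train_idx])
                z = dict(z)
                z[mask] = z_hat_std * Tensor(model.decoder.latent_sigma[mask]) \
                    + Tensor(model.decoder.latent_mu[mask])
            per_head = {m: model.classify_head(z[m], m)
                        for m in model.modalities}
            fused = model.vcdn_fuse([per_head[m] for m in model.modalities])
            loss = _classification_loss(model, c, fused, per_head,
                                        lcfgs[c.name])
            if loss_recon is not None:
                loss = loss + config.lambda_recon * loss_recon
            total = loss if total is None else total + loss
        total = total / float(len(corpus.cohorts))
        if not np.isfinite(total.data):
            raise FloatingPointError(f"non-finite loss at phase-3 epoch {epoch}")
        total.backward()
        opt.step()
        val = float(np.mean([_val_f1_macro(models[c.name], c)
                             for c in corpus.cohorts]))
        sched.step(val)
        history.append({"epoch": epoch, "train_loss": float(total.data),
                        "val_f1_macro": val, "lr": opt.lr,
                        "masked": masked_this_epoch})
        if stopper.update(val, epoch):
            break
    if history:
        stopper.restore()
        history[-1]["early_stop_epoch"] = stopper.best_epoch
    if params_hash(shared.decoder_params()) != dec_hash:
        raise RuntimeError("decoder drifted during phase 3 (freeze violated)")
    return history


def run_pretraining(corpus: PretrainCorpus,
                    config: TrainConfig) -> PretrainResult:
    """Phases 1-3 in order; returns the per-cohort models (shared encoders
    and decoder) with their training histories."""
    models = build_pretrain_models(corpus, config)
    histories = {
        "phase1": phase1(corpus, models, config),
        "phase2": phase2(corpus, models, config),
        "phase3": phase3(corpus, models, config),
    }
    return PretrainResult(models=models, config=config, histories=histories)
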