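"""Objectives and evaluation metrics.

Losses accept either plain numpy arrays (returning a float) or autodiff
:class:`~mogedn.autograd.Tensor` inputs (returning a Tensor), so the same
formulas serve both the training loop and external evaluation.

The classification objective is a class- and sample-weighted focal loss

    L_cls = -(1/N) sum_i w_i sum_c alpha_c y_ic (1 - p_ic)^gamma log p_ic

with balanced class weights alpha_c = N / (C * n_c) and per-sample weights
w_i = alpha_{y_i} rescaled to mean one.  Reconstruction quality in latent
space is monitored as Sim = 1 / (1 + MSE).  Model selection during
finetuning uses the composite score

    0.2 * ACC + 0.2 * F1_weighted + 0.6 * F1_macro.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .autograd import Tensor, as_tensor

__all__ = [
    "LossConfig",
    "MetricReport",
    "focal_loss",
    "balanced_class_weights",
    "sample_weights",
    "recon_loss",
    "similarity",
    "joint_loss",
    "weighted_ce",
    "metrics",
    "composite_score",
]

_LOG_CLAMP = 1e-12


@dataclass
class LossConfig:
    """Hyperparameters of the training objectives.

    gamma : focal exponent (>= 0); 0 recovers plain cross-entropy.
    alpha : per-class weights (positive), ``None`` = unweighted.
    sample_weights : per-sample weights (positive), ``None`` = unweighted.
    lambda_recon : weight of the latent-reconstruction term in the joint loss.
    mask_prob : probability that one modality is masked in a joint-training
        epoch.
    """

    gamma: float = 2.0
    alpha: np.ndarray | None = None
    sample_weights: np.ndarray | None = None
    lambda_recon: float = 1.0
    mask_prob: float = 1.0 / 3.0

    def __post_init__(self):
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if self.lambda_recon < 0:
            raise ValueError("lambda_recon must be >= 0")
        if not 0.0 <= self.mask_prob <= 1.0:
            raise ValueError("mask_prob must lie in [0, 1]")
        for name in ("alpha", "sample_weights"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if not np.all(np.isfinite(v)) or np.any(v <= 0):
                    raise ValueError(f"{name} must be finite and positive")
                setattr(self, name, v)


@dataclass
class MetricReport:
    """Accuracy / F1 report for one evaluation."""

    acc: float
    f1_weighted: float
    f1_macro: float
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    n_c: np.ndarray
    composite: float

    def to_dict(self) -> dict:
        d = asdict(self)
        for k in ("precision", "recall", "f1", "n_c"):
            d[k] = np.asarray(d[k]).tolist()
        return d


def _check_simplex(p: np.ndarray, tol: float = 1e-6):
    if p.ndim != 2:
        raise ValueError("probabilities must be a 2-D (samples x classes) array")
    if np.any(p.min(axis=1) < -tol) or np.any(np.abs(p.sum(axis=1) - 1.0) > tol):
        raise ValueError("probability rows must lie on the simplex")


def _maybe_float(x: Tensor, tensor_mode: bool):
    return x if tensor_mode else float(x.data)


def focal_loss(probs, y_onehot, config: LossConfig):
    """Class- and sample-weighted focal loss.

    `probs` may be a numpy array (returns float) or a Tensor on the autodiff
    tape (returns Tensor).  `y_onehot` is the one-hot label matrix.
    """
    tensor_mode = isinstance(probs, Tensor)
    p = as_tensor(probs)
    y = np.asarray(y_onehot.data if isinstance(y_onehot, Tensor) else y_onehot,
                   dtype=float)
    _check_simplex(p.data)
    if y.shape != p.shape:
        raise ValueError(f"shape mismatch: probs {p.shape} vs labels {y.shape}")
    n, c = y.shape
    alpha = np.ones(c) if config.alpha is None else np.asarray(config.alpha, float)
    w = (np.ones(n) if config.sample_weights is None
         else np.asarray(config.sample_weights, float))
    if alpha.shape != (c,):
        raise ValueError("alpha must have one entry per class")
    if w.shape != (n,):
        raise ValueError("sample_weights must have one entry per sample")

    logp = p.clip_min(_LOG_CLAMP).log()
    focal = (1.0 - p) ** config.gamma if config.gamma != 0 else as_tensor(np.ones_like(y))
    per_entry = Tensor(y * alpha[None, :]) * focal * logp
    per_sample = per_entry.sum(axis=1) * Tensor(w)
    loss = -per_sample.sum() / float(n)
    return _maybe_float(loss, tensor_mode)


def balanced_class_weights(labels) -> np.ndarray:
    """alpha_c = N / (C * n_c) for integer labels 0..C-1."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("empty label vector")
    c = int(labels.max()) + 1
    n_c = np.bincount(labels, minlength=c).astype(float)
    if np.any(n_c == 0):
        missing = np.flatnonzero(n_c == 0).tolist()
        raise ValueError(f"classes {missing} have no samples in this fold")
    if c < 2:
        raise ValueError("need at least two classes")
    return labels.size / (c * n_c)


def sample_weights(labels) -> np.ndarray:
    """w_i = alpha_{y_i} rescaled to mean one."""
    labels = np.asarray(labels)
    alpha = balanced_class_weights(labels)
    w = alpha[labels]
    return w / w.mean()


def recon_loss(z_hat, z):
    """Mean squared error over all latent entries."""
    tensor_mode = isinstance(z_hat, Tensor) or isinstance(z, Tensor)
    a, b = as_tensor(z_hat), as_tensor(z)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    out = ((a - b) ** 2).mean()
    return _maybe_float(out, tensor_mode)


def similarity(mse: float) -> float:
    """Reconstruction-quality monitor Sim = 1 / (1 + MSE)."""
    return 1.0 / (1.0 + float(mse))


def joint_loss(cls, recon, lambda_recon: float):
    """L_total = L_cls + lambda * L_recon."""
    if lambda_recon < 0:
        raise ValueError("lambda_recon must be >= 0")
    return cls + lambda_recon * recon


def weighted_ce(probs, labels, w=None):
    """Weighted cross-entropy (1/N) sum_i w_i (-log p_{i, y_i})."""
    tensor_mode = isinstance(probs, Tensor)
    p = as_tensor(probs)
    _check_simplex(p.data)
    labels = np.asarray(labels)
    n, c = p.shape
    if labels.shape != (n,):
        raise ValueError("labels must have one entry per sample")
    w = np.ones(n) if w is None else np.asarray(w, float)
    onehot = np.zeros((n, c))
    onehot[np.arange(n), labels] = 1.0
    logp = p.clip_min(_LOG_CLAMP).log()
    loss = -((Tensor(onehot) * logp).sum(axis=1) * Tensor(w)).sum() / float(n)
    return _maybe_float(loss, tensor_mode)


def composite_score(acc: float, f1w: float, f1m: float) -> float:
    return 0.2 * acc + 0.2 * f1w + 0.6 * f1m


def metrics(pred_labels, true_labels, n_classes: int | None = None) -> MetricReport:
    """ACC, weighted F1, macro F1 and the composite selection score.

    Per-class F1 is 2 P_c R_c / (P_c + R_c); classes with no predicted (or no
    true) positives contribute F1 = 0.  The weighted F1 weights classes by
    their share n_c / N of the true labels; macro F1 averages over all
    modelled classes.
    """
    pred = np.asarray(pred_labels)
    true = np.asarray(true_labels)
    if pred.shape != true.shape:
        raise ValueError(f"length mismatch: {pred.shape} vs {true.shape}")
    n = true.size
    c = int(max(pred.max(initial=0), true.max(initial=0))) + 1
    if n_classes is not None:
        c = max(c, int(n_classes))
    n_c = np.bincount(true, minlength=c).astype(float)

    tp = np.zeros(c)
    fp = np.zeros(c)
    fn = np.zeros(c)
    for cls in range(c):
        tp[cls] = np.sum((pred == cls) & (true == cls))
        fp[cls] = np.sum((pred == cls) & (true != cls))
        fn[cls] = np.sum((pred != cls) & (true == cls))
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(tp + fp > 0, tp / (tp + fp), 0.0)
        recall = np.where(tp + fn > 0, tp / (tp + fn), 0.0)
        f1 = np.where(precision + recall > 0,
                      2 * precision * recall / (precision + recall), 0.0)

    acc = float(np.mean(pred == true))
    f1w = float(np.sum(n_c / n * f1))
    f1m = float(np.mean(f1))
    return MetricReport(
        acc=acc, f1_weighted=f1w, f1_macro=f1m,
        precision=precision, recall=recall, f1=f1, n_c=n_c.astype(int),
        composite=composite_score(acc, f1w, f1m),
    )
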