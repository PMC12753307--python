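"""Layers, initialisation, optimiser and LR scheduling for the numpy autodiff
engine, plus parameter-hashing utilities used by the freeze contracts."""

from __future__ import annotations

import hashlib

import numpy as np

from .autograd import Tensor

__all__ = [
    "Linear",
    "Adam",
    "ReduceLROnPlateau",
    "dropout_mask",
    "params_hash",
    "clone_state",
    "load_state",
]


class Linear:
    """Dense layer ``x @ W + b`` with Glorot-uniform initialisation."""

    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        limit = np.sqrt(6.0 / (in_dim + out_dim))
        self.W = Tensor(rng.uniform(-limit, limit, size=(in_dim, out_dim)),
                        requires_grad=True)
        self.b = Tensor(np.zeros(out_dim), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b

    def params(self, prefix: str) -> dict[str, Tensor]:
        return {f"{prefix}.W": self.W, f"{prefix}.b": self.b}


def dropout_mask(shape, p: float, rng: np.random.Generator) -> np.ndarray:
    """Inverted-dropout multiplier: zeros with prob p, else 1/(1-p)."""
    keep = rng.random(shape) >= p
    return keep / (1.0 - p)


class Adam:
    """Adam with a mutable learning rate (driven by ReduceLROnPlateau)."""

    def __init__(self, params: dict[str, Tensor], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = dict(params)
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = float(weight_decay)
        self.t = 0
        self._m = {k: np.zeros_like(p.data) for k, p in self.params.items()}
        self._v = {k: np.zeros_like(p.data) for k, p in self.params.items()}

    def zero_grad(self):
        for p in self.params.values():
            p.grad = None

    def step(self):
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self._m[k] = self.b1 * self._m[k] + (1 - self.b1) * g
            self._v[k] = self.b2 * self._v[k] + (1 - self.b2) * g * g
            mhat = self._m[k] / (1 - self.b1**self.t)
            vhat = self._v[k] / (1 - self.b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
            if self.weight_decay:  # decoupled (AdamW-style)
                p.data = p.data - self.lr * self.weight_decay * p.data


class ReduceLROnPlateau:
    """Multiply the optimiser LR by `factor` after `patience` epochs without
    improvement of the monitored statistic."""

    def __init__(self, optimizer: Adam, mode: str = "max",
                 factor: float = 0.7, patience: int = 10,
                 min_lr: float = 1e-6):
        assert 0.0 < factor < 1.0
        self.opt = optimizer
        self.mode = mode
        self.factor = factor
        self.patience = patience
        self.min_lr = min_lr
        self.best: float | None = None
        self.bad_epochs = 0

    def step(self, value: float):
        improved = (
            self.best is None
            or (self.mode == "max" and value > self.best)
            or (self.mode == "min" and value < self.best)
        )
        if improved:
            self.best = value
            self.bad_epochs = 0
        else:
            self.bad_epochs += 1
            if self.bad_epochs > self.patience:
                self.opt.lr = max(self.opt.lr * self.factor, self.min_lr)
                self.bad_epochs = 0


def params_hash(params: dict[str, Tensor]) -> str:
    """SHA-256 over parameter bytes, order-stable by name; used to verify
    that frozen components really did not move."""
    h = hashlib.sha256()
    for name in sorted(params):
        h.update(name.encode())
        h.update(np.ascontiguousarray(params[name].data).tobytes())
    return h.hexdigest()


def clone_state(params: dict[str, Tensor]) -> dict[str, np.ndarray]:
    return {k: p.data.copy() for k, p in params.items()}


def load_state(params: dict[str, Tensor], state: dict[str, np.ndarray]):
    for k, p in params.items():
        p.data = state[k].copy()
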