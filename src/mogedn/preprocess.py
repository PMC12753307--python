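"""Feature selection and normalization for multi-omics matrices.

Inputs are per-modality sample x feature matrices (mRNA expression, DNA
methylation beta-values, miRNA expression).  Pretraining cohorts use a
two-step reduction: *common* features — highly variable and measured
(non-zero-variance) in every cohort — occupy the first columns in a shared
order, followed by cohort-specific high-variance features, giving fixed
widths per modality (defaults 1000 / 1000 / 500 with common blocks
200 / 200 / 100).  Evaluation cohorts use tumor-specific features only.

Expression modalities are log2(x+1)-transformed before standardization;
methylation beta-values are z-scored as-is.  Standardization is

    x_std = (x - mu_g) / (sigma_g + eps)

per feature, with the training-fold statistics replayable on new samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "OmicsView",
    "NormalizationStats",
    "FeatureSelectionSpec",
    "normalize_view",
    "apply_normalization",
    "select_specific_features",
    "select_common_features",
    "assemble_pretraining_views",
]

MODALITIES = ("mrna", "methylation", "mirna")


@dataclass
class OmicsView:
    """One modality's sample x feature matrix."""

    modality_id: str
    matrix: np.ndarray
    feature_names: list[str]
    sample_ids: list[str]
    normalized: bool = False

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.feature_names = list(self.feature_names)
        self.sample_ids = list(self.sample_ids)
        if self.modality_id not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality_id!r}")
        if self.matrix.ndim != 2:
            raise ValueError("matrix must be 2-D (samples x features)")
        n, d = self.matrix.shape
        if n != len(self.sample_ids):
            raise ValueError(f"{n} rows but {len(self.sample_ids)} sample ids")
        if d != len(self.feature_names):
            raise ValueError(f"{d} columns but {len(self.feature_names)} feature names")
        if len(set(self.sample_ids)) != n:
            raise ValueError("sample ids must be unique")
        if len(set(self.feature_names)) != d:
            raise ValueError("feature names must be unique")
        if self.normalized and not np.all(np.isfinite(self.matrix)):
            raise ValueError("normalized view contains NaN/Inf")

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]

    def subset_features(self, idx) -> "OmicsView":
        idx = np.asarray(idx, dtype=int)
        return replace(
            self,
            matrix=self.matrix[:, idx],
            feature_names=[self.feature_names[i] for i in idx],
        )


@dataclass
class NormalizationStats:
    """Per-feature mean/SD used for standardization (replayable)."""

    mu: np.ndarray
    sigma: np.ndarray
    epsilon: float
    log_transform: bool = False

    def __post_init__(self):
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")
        if np.any(self.sigma < 0):
            raise ValueError("sigma must be non-negative")


@dataclass
class FeatureSelectionSpec:
    """Per-modality common / tumor-specific feature budgets."""

    common_dims: dict[str, int] = field(
        default_factory=lambda: {"mrna": 200, "methylation": 200, "mirna": 100})
    specific_dims: dict[str, int] = field(
        default_factory=lambda: {"mrna": 800, "methylation": 800, "mirna": 400})

    @property
    def target_dims(self) -> dict[str, int]:
        return {m: self.common_dims[m] + self.specific_dims[m]
                for m in self.common_dims}

    def __post_init__(self):
        for m in self.common_dims:
            if self.common_dims[m] < 0 or self.specific_dims.get(m, -1) < 0:
                raise ValueError("feature counts must be non-negative")
            if self.common_dims[m] + self.specific_dims[m] <= 0:
                raise ValueError(f"target width for {m} must be > 0")


def normalize_view(view: OmicsView, log_transform: bool = False,
                   epsilon: float = 1e-8) -> tuple[OmicsView, NormalizationStats]:
    """z-score each feature across samples, optionally after log2(x+1).

    Constant features map to all-zeros (the epsilon guard avoids 0/0).
    Returns the view plus the statistics needed to replay the transform.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    x = view.matrix
    if x.size == 0:
        raise ValueError("empty matrix")
    if x.shape[0] < 2:
        raise ValueError("need at least 2 samples to standardize")
    if log_transform:
        if np.any(x < 0):
            raise ValueError("negative values are incompatible with log transform")
        x = np.log2(x + 1.0)
    mu = x.mean(axis=0)
    sigma = x.std(axis=0)
    stats = NormalizationStats(mu=mu, sigma=sigma, epsilon=epsilon,
                               log_transform=log_transform)
    out = replace(view, matrix=(x - mu) / (sigma + epsilon), normalized=True)
    return out, stats


def apply_normalization(view: OmicsView, stats: NormalizationStats) -> OmicsView:
    """Replay training-fold statistics on new samples (no leakage)."""
    x = view.matrix
    if stats.log_transform:
        if np.any(x < 0):
            raise ValueError("negative values are incompatible with log transform")
        x = np.log2(x + 1.0)
    if x.shape[1] != stats.mu.size:
        raise ValueError(f"view has {x.shape[1]} features but stats describe "
                         f"{stats.mu.size}")
    return replace(view, matrix=(x - stats.mu) / (stats.sigma + stats.epsilon),
                   normalized=True)


def _variance_order(matrix: np.ndarray) -> np.ndarray:
    """Column indices sorted by descending variance, ties by column index."""
    var = matrix.var(axis=0)
    # stable sort on -var keeps the original index order within ties
    return np.argsort(-var, kind="stable")


def select_specific_features(view: OmicsView, n_keep: int) -> OmicsView:
    """Keep the n_keep highest-variance features (zero-variance removed first).

    Output columns are ordered by descending variance, ties broken by the
    original column index.
    """
    var = view.matrix.var(axis=0)
    nonzero = np.flatnonzero(var > 0)
    if n_keep > nonzero.size:
        raise ValueError(
            f"requested {n_keep} features but only {nonzero.size} have "
            "non-zero variance")
    order = _variance_order(view.matrix)
    order = order[np.isin(order, nonzero)]
    return view.subset_features(order[:n_keep])


def select_common_features(views_by_dataset: list[OmicsView],
                           n_keep: int) -> list[str]:
    """Features measured (non-zero-variance) in every dataset, ranked by the
    mean of per-dataset variance ranks; returns the top n_keep names."""
    if len(views_by_dataset) < 2:
        raise ValueError("need at least 2 datasets to define common features")
    name_sets = [set(v.feature_names) for v in views_by_dataset]
    shared = set.intersection(*name_sets)
    # restrict to non-zero variance in ALL datasets ("frequently measured")
    present = shared.copy()
    for v in views_by_dataset:
        var = dict(zip(v.feature_names, v.matrix.var(axis=0)))
        present = {f for f in present if var[f] > 0}
    if len(present) < n_keep:
        raise ValueError(
            f"only {len(present)} features are measured in all datasets; "
            f"{n_keep} requested")
    # canonical order: first dataset's column order
    ref_order = [f for f in views_by_dataset[0].feature_names if f in present]
    mean_rank = np.zeros(len(ref_order))
    for v in views_by_dataset:
        var = dict(zip(v.feature_names, v.matrix.var(axis=0)))
        vals = np.array([var[f] for f in ref_order])
        order = np.argsort(-vals, kind="stable")
        ranks = np.empty_like(order)
        ranks[order] = np.arange(len(order))
        mean_rank += ranks
    mean_rank /= len(views_by_dataset)
    top = np.argsort(mean_rank, kind="stable")[:n_keep]
    return [ref_order[i] for i in top]


def assemble_pretraining_views(common_ids: list[str],
                               view: OmicsView,
                               spec: FeatureSelectionSpec) -> OmicsView:
    """Common features first (in the shared order), then the dataset's top
    tumor-specific features, excluding any already in the common block."""
    m = view.modality_id
    n_common = spec.common_dims[m]
    n_specific = spec.specific_dims[m]
    if n_common != len(common_ids):
        raise ValueError(
            f"spec requests {n_common} common features for {m} but "
            f"{len(common_ids)} ids supplied")
    name_to_idx = {f: i for i, f in enumerate(view.feature_names)}
    missing = [f for f in common_ids if f not in name_to_idx]
    if missing:
        raise ValueError(f"common features absent from view: {missing[:5]}")
    common_idx = [name_to_idx[f] for f in common_ids]

    common_set = set(common_ids)
    var = view.matrix.var(axis=0)
    order = _variance_order(view.matrix)
    specific_idx = [i for i in order
                    if var[i] > 0 and view.feature_names[i] not in common_set]
    if len(specific_idx) < n_specific:
        raise ValueError(
            f"only {len(specific_idx)} tumor-specific candidates available "
            f"for {m}; {n_specific} requested")
    idx = list(common_idx) + specific_idx[:n_specific]
    out = view.subset_features(idx)
    assert out.n_features == spec.target_dims[m]
    return out
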