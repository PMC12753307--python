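"""Input x gradient biomarker identification.

For one modality, the trained encoder and its single-omics head are run with
an identity adjacency (so each sample's signal is attributed without graph
mixing).  Each sample receives a pseudo-label from the model's own argmax
prediction; the per-sample loss is the cross-entropy at that pseudo-label,
and the attribution of feature g for sample i is

    a_ig = | X_ig * d l_i / d X_ig |

aggregated to a per-feature score s_g = (1/N) sum_i a_ig.

Shared biomarkers average s_g over the pretraining cohorts and restrict to
the common-feature block (the first d_shared columns per modality); tumor-
specific biomarkers rank the full feature set of a finetuned cohort model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autograd import Tensor, softmax
from .model import MogednModel
from .nn import params_hash
from .preprocess import OmicsView

__all__ = ["AttributionResult", "attribute", "shared_biomarkers",
           "tumor_specific_biomarkers"]

DEFAULT_SHARED_DIMS = {"mrna": 200, "methylation": 200, "mirna": 100}
DEFAULT_SHARED_TOPK = {"mrna": 100, "methylation": 100, "mirna": 50}


@dataclass
class AttributionResult:
    """Per-feature importance scores and the ranked biomarker list."""

    modality: str
    scores: np.ndarray
    feature_names: list[str]
    ranking: np.ndarray  # feature indices, descending score
    k_top: int
    provenance: str  # shared | tumor_specific

    def __post_init__(self):
        self.scores = np.asarray(self.scores, float)
        self.ranking = np.asarray(self.ranking, int)
        if np.any(self.scores < 0):
            raise ValueError("scores are absolute values and must be >= 0")
        if sorted(self.ranking.tolist()) != list(range(self.scores.size)):
            raise ValueError("ranking must be a permutation of feature indices")

    @property
    def top_features(self) -> list[str]:
        return [self.feature_names[i] for i in self.ranking[: self.k_top]]

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({
            "rank": np.arange(self.ranking.size),
            "feature_id": [self.feature_names[i] for i in self.ranking],
            "score": self.scores[self.ranking],
        })


def _rank_desc(scores: np.ndarray) -> np.ndarray:
    """Descending by score, ties broken by ascending feature index."""
    return np.lexsort((np.arange(scores.size), -scores))


def attribute(view: OmicsView, encoder, head,
              batch_size: int | None = None) -> np.ndarray:
    """Per-feature scores s_g for one modality (identity adjacency).

    The result is invariant to the batch size: per-sample attributions are
    summed over batches and divided by the total sample count.
    """
    if view.n_samples == 0:
        raise ValueError("empty sample set")
    if not view.normalized:
        import warnings
        warnings.warn("attributing an unnormalized view; scores assume the "
                      "training normalization")
    before = params_hash({**encoder.params("e"), **head.params("h")})
    n = view.n_samples
    bs = n if batch_size is None else int(batch_size)
    acc = np.zeros(view.n_features)
    for start in range(0, n, bs):
        xb = view.matrix[start:start + bs]
        x = Tensor(xb, requires_grad=True)
        eye = Tensor(np.eye(xb.shape[0]))
        logits = head(encoder(x, eye, training=False))
        probs = softmax(logits, axis=1)
        pseudo = logits.data.argmax(axis=1)
        onehot = np.zeros_like(logits.data)
        onehot[np.arange(xb.shape[0]), pseudo] = 1.0
        losses = -(Tensor(onehot) * probs.clip_min(1e-12).log()).sum(axis=1)
        losses.sum().backward()
        acc += np.abs(xb * x.grad).sum(axis=0)
    after = params_hash({**encoder.params("e"), **head.params("h")})
    assert before == after, "attribution must not mutate model parameters"
    return acc / n


def shared_biomarkers(models: dict[str, MogednModel],
                      views_by_cohort: dict[str, dict[str, OmicsView]],
                      d_shared: dict[str, int] | None = None,
                      k_top: dict[str, int] | None = None,
                      ) -> dict[str, AttributionResult]:
    """Cross-cohort average attribution restricted to the common block.

    `views_by_cohort` maps cohort name -> modality -> pretraining view
    (common features first, per the preprocessing contract).
    """
    if set(models) != set(views_by_cohort):
        raise ValueError("models and views describe different cohorts")
    d_shared = dict(DEFAULT_SHARED_DIMS) if d_shared is None else d_shared
    k_top = dict(DEFAULT_SHARED_TOPK) if k_top is None else k_top
    modalities = next(iter(models.values())).modalities
    out: dict[str, AttributionResult] = {}
    for m in modalities:
        per_cohort = []
        names = None
        for cname, model in models.items():
            view = views_by_cohort[cname][m]
            per_cohort.append(attribute(view, model.encoders[m],
                                        model.heads[m]))
            if names is None:
                names = view.feature_names
        mean_scores = np.mean(per_cohort, axis=0)
        d = d_shared[m]
        if d > mean_scores.size:
            raise ValueError(f"d_shared[{m}]={d} exceeds feature count")
        shared_scores = mean_scores[:d]  # common block occupies first columns
        out[m] = AttributionResult(
            modality=m, scores=shared_scores,
            feature_names=names[:d],
            ranking=_rank_desc(shared_scores),
            k_top=min(k_top[m], d), provenance="shared")
    return out


def tumor_specific_biomarkers(model: MogednModel,
                              train_views: dict[str, OmicsView],
                              k_top: int = 300) -> dict[str, AttributionResult]:
    """Full-width attribution ranking for one finetuned cohort model."""
    out: dict[str, AttributionResult] = {}
    for m in model.modalities:
        view = train_views[m]
        if k_top > view.n_features:
            raise ValueError(f"k_top={k_top} exceeds the {view.n_features} "
                             f"features of {m}")
        scores = attribute(view, model.encoders[m], model.heads[m])
        out[m] = AttributionResult(
            modality=m, scores=scores, feature_names=view.feature_names,
            ranking=_rank_desc(scores), k_top=k_top,
            provenance="tumor_specific")
    return out
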