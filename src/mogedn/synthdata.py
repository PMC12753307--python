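"""Seeded generator of synthetic multi-omics cohorts.

The generator emulates the statistical structure the model assumes in real
cohorts: matched samples across modalities, subtype labels, class imbalance,
and a tunable cross-modality dependence so that one modality's signal can be
predicted from the others.

Construction.  Each class c has a latent mean m_c ~ N(0, class_sep^2 I) in a
``latent_dim``-dimensional factor space.  For sample i with label y_i a
shared factor z_s = m_{y_i} + N(0, I) is drawn, and each modality o mixes it
with an independent private factor z_o ~ N(0, I):

    u_o = rho * z_s + sqrt(1 - rho^2) * z_o

with rho = ``cross_modal_strength``.  The informative columns of modality o
are u_o @ L_o + noise with random loadings L_o; the remaining columns are
pure noise.  All class signal is routed through the shared factor, so at
rho = 0 the modalities are exactly independent of each other (and carry no
class signal), while at rho near 1 the class structure is strong and the
informative block of a masked modality is (near-)linearly predictable from
the other modalities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocess import MODALITIES, OmicsView

__all__ = ["SynthSpec", "SynthCohort", "generate"]

DEFAULT_DIMS = {"mrna": 100, "methylation": 100, "mirna": 50}


@dataclass
class SynthSpec:
    """Parameters of one synthetic cohort."""

    n_samples: int = 200
    n_classes: int = 3
    class_proportions: tuple[float, ...] = (0.5, 0.3, 0.2)
    dims: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_DIMS))
    latent_dim: int = 10
    cross_modal_strength: float = 0.9
    informative_fraction: float = 0.1
    noise_sd: float = 1.0
    class_sep: float = 2.0
    seed: int = 0
    structure_seed: int = 0

    def __post_init__(self):
        p = np.asarray(self.class_proportions, float)
        if p.size != self.n_classes or not np.isclose(p.sum(), 1.0):
            raise ValueError("class_proportions must have n_classes entries "
                             "summing to 1")
        if not 0.0 <= self.cross_modal_strength <= 1.0:
            raise ValueError("cross_modal_strength must lie in [0, 1]")
        if not 0.0 <= self.informative_fraction <= 1.0:
            raise ValueError("informative_fraction must lie in [0, 1]")
        if any(d <= 0 for d in self.dims.values()) or self.latent_dim <= 0:
            raise ValueError("dims and latent_dim must be positive")
        counts = np.round(p * self.n_samples).astype(int)
        if np.any(counts == 0):
            raise ValueError("a class has expected count 0 at this n_samples")


@dataclass
class SynthCohort:
    """Generated cohort plus the planted ground truth."""

    views: dict[str, OmicsView]
    labels: np.ndarray
    label_names: list[str]
    informative: dict[str, np.ndarray]  # planted column indices per modality
    latent: np.ndarray  # shared class-bearing factor z_s (samples x latent_dim)


def _class_counts(spec: SynthSpec) -> np.ndarray:
    p = np.asarray(spec.class_proportions, float)
    counts = np.floor(p * spec.n_samples).astype(int)
    # distribute the remainder to the largest fractional parts
    rem = spec.n_samples - counts.sum()
    frac = p * spec.n_samples - counts
    for idx in np.argsort(-frac, kind="stable")[:rem]:
        counts[idx] += 1
    return counts


def generate(spec: SynthSpec, name: str = "synth") -> SynthCohort:
    """Draw one cohort; same spec (incl. seed) gives a bit-identical cohort."""
    rng = np.random.default_rng(spec.seed)
    counts = _class_counts(spec)
    labels = rng.permutation(np.repeat(np.arange(spec.n_classes), counts))
    n, L = spec.n_samples, spec.latent_dim
    rho = spec.cross_modal_strength

    class_means = rng.normal(0.0, spec.class_sep, size=(spec.n_classes, L))
    z_shared = class_means[labels] + rng.normal(size=(n, L))

    views: dict[str, OmicsView] = {}
    informative: dict[str, np.ndarray] = {}
    n_infos = {m: int(round(spec.informative_fraction * spec.dims[m]))
               for m in spec.dims}
    # every modality carries the same aggregate signal: lower-dimensional
    # layers (miRNA) concentrate it in fewer, individually stronger features
    n_info_ref = max(n_infos.values())
    for mi, m in enumerate(MODALITIES):
        if m not in spec.dims:
            continue
        d = spec.dims[m]
        n_info = n_infos[m]
        # which columns are informative and how the latent loads onto them is
        # a property of the feature space, not of one cohort: cohorts with
        # the same structure_seed share it (same molecular covariation across
        # cancer types), which is what lets a decoder pretrained on some
        # cohorts transfer to a new one
        rng_struct = np.random.default_rng([spec.structure_seed, mi])
        info_idx = np.sort(rng_struct.choice(d, size=n_info, replace=False))
        loadings = (rng_struct.normal(size=(L, n_info)) / np.sqrt(L)
                    * np.sqrt(n_info_ref / max(n_info, 1)))
        z_own = rng.normal(size=(n, L))
        # modality-specific class means, scaled by rho*sqrt(1-rho^2): real
        # omics layers carry subtype signal unique to the layer, recoverable
        # across modalities only through the subtype itself; the scaling
        # vanishes at rho=0 (no class signal, exact independence) and rho=1
        # (modalities become exact linear functions of each other)
        m_own = rng.normal(0.0, spec.class_sep, size=(spec.n_classes, L))
        u = (rho * z_shared + np.sqrt(1.0 - rho**2) * z_own
             + rho * np.sqrt(1.0 - rho**2) * m_own[labels])
        x = rng.normal(scale=max(spec.noise_sd, 1e-12), size=(n, d))
        x[:, info_idx] += u @ loadings
        feature_names = [f"{m}_f{j:04d}" for j in range(d)]
        sample_ids = [f"{name}_s{j:04d}" for j in range(n)]
        views[m] = OmicsView(modality_id=m, matrix=x,
                             feature_names=feature_names,
                             sample_ids=sample_ids)
        informative[m] = info_idx
    label_names = [f"{name}.c{c}" for c in range(spec.n_classes)]
    return SynthCohort(views=views, labels=labels, label_names=label_names,
                       informative=informative, latent=z_shared)


# -- corpus / dataset assembly ----------------------------------------------

TOTAL_KEEP_FRACTION = 0.3  # variance-based reduction, mirroring the
COMMON_KEEP_FRACTION = 0.1  # common + tumor-specific two-step selection


def desk_feature_spec(dims: dict[str, int]):
    """Per-modality common/specific budgets scaled to synthetic widths."""
    from .preprocess import FeatureSelectionSpec
    common = {m: max(1, round(COMMON_KEEP_FRACTION * d))
              for m, d in dims.items()}
    specific = {m: max(1, round(TOTAL_KEEP_FRACTION * d)) - common[m]
                for m, d in dims.items()}
    return FeatureSelectionSpec(common_dims=common, specific_dims=specific)


def make_corpus(specs: list[SynthSpec], edge_per_node: int = 10,
                val_fraction: float = 0.25, name_prefix: str = "cohort",
                feature_spec=None):
    """Independent cohorts with distinct class sets and a shared feature
    namespace, passed through the two-step (common + tumor-specific)
    variance-based feature selection, normalized, and wrapped with graphs
    and stratified splits."""
    from sklearn.model_selection import train_test_split

    from .graphs import build_graph
    from .preprocess import (assemble_pretraining_views, normalize_view,
                             select_common_features)
    from .train_phases import Cohort, PretrainCorpus

    raws = [generate(spec, name=f"{name_prefix}{i}")
            for i, spec in enumerate(specs)]
    modalities = list(raws[0].views)
    if feature_spec is None:
        feature_spec = desk_feature_spec(
            {m: raws[0].views[m].n_features for m in modalities})
    common_ids = {}
    for m in modalities:
        n_common = feature_spec.common_dims[m]
        if len(raws) >= 2 and n_common > 0:
            common_ids[m] = select_common_features(
                [r.views[m] for r in raws], n_common)
        else:  # single cohort: no cross-dataset common block
            common_ids[m] = []

    cohorts = []
    for spec, raw in zip(specs, raws):
        views = {}
        for m in modalities:
            fs = feature_spec
            if not common_ids[m]:
                from .preprocess import FeatureSelectionSpec
                fs = FeatureSelectionSpec(
                    common_dims={m: 0},
                    specific_dims={m: feature_spec.target_dims[m]})
            selected = assemble_pretraining_views(common_ids[m], raw.views[m],
                                                  fs)
            views[m] = normalize_view(selected, log_transform=False)[0]
        graphs = {m: build_graph(v, edge_per_node) for m, v in views.items()}
        tr, val = train_test_split(
            np.arange(spec.n_samples), test_size=val_fraction,
            stratify=raw.labels, random_state=spec.seed % (2**32))
        cohorts.append(Cohort(name=raw.label_names[0].split(".")[0],
                              views=views, labels=raw.labels,
                              label_names=raw.label_names, graphs=graphs,
                              train_idx=tr, val_idx=val))
    return PretrainCorpus(cohorts=cohorts)


def make_eval_dataset(spec: SynthSpec, test_fraction: float = 0.25,
                      name: str = "eval", feature_spec=None):
    """One cohort split into train/test, reduced to tumor-specific features
    by training-fold variance (widths matching the pretraining targets);
    test rows replay the training-fold normalization (no leakage)."""
    from dataclasses import replace

    from sklearn.model_selection import train_test_split

    from .evaluate import EvalDataset
    from .preprocess import (apply_normalization, normalize_view,
                             select_specific_features)

    raw = generate(spec, name=name)
    if feature_spec is None:
        feature_spec = desk_feature_spec(
            {m: v.n_features for m, v in raw.views.items()})
    tr, te = train_test_split(
        np.arange(spec.n_samples), test_size=test_fraction,
        stratify=raw.labels, random_state=spec.seed % (2**32))
    train_views, test_views = {}, {}
    for m, v in raw.views.items():
        v_tr = replace(v, matrix=v.matrix[tr],
                       sample_ids=[v.sample_ids[i] for i in tr])
        v_tr = select_specific_features(v_tr, feature_spec.target_dims[m])
        keep = [raw.views[m].feature_names.index(f)
                for f in v_tr.feature_names]
        v_te = replace(v, matrix=v.matrix[te][:, keep],
                       feature_names=list(v_tr.feature_names),
                       sample_ids=[v.sample_ids[i] for i in te])
        v_tr_norm, stats = normalize_view(v_tr, log_transform=False)
        train_views[m] = v_tr_norm
        test_views[m] = apply_normalization(v_te, stats)
    return EvalDataset(name=name, train_views=train_views,
                       test_views=test_views,
                       y_train=raw.labels[tr], y_test=raw.labels[te],
                       label_names=raw.label_names), raw, tr, te
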