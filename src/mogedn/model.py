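"""Network components: per-omics GCN encoders, a shared multi-head decoder
for latent recovery of a missing modality, single-omics classifier heads,
and a VCDN (view correlation discovery network) fusion classifier.

Encoders realize activation(A @ H @ W) stacks with widths
input -> 200 -> 100 -> 100 (LeakyReLU slope 0.25 after every layer;
dropout 0.5 on the inputs during training).  The decoder concatenates the
available modalities' 100-d latents in fixed modality order, passes them
through a 256-wide core and a per-modality output head, reconstructing the
missing latent.  Heads are single linear layers latent -> logits.  VCDN
softmax-normalizes the per-head logits, forms the per-sample outer product
over modalities (length C^M), and maps it through a one-hidden-layer MLP to
the final subtype logits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autograd import Tensor, concat, leaky_relu, softmax
from .graphs import SampleGraph
from .nn import Linear, dropout_mask
from .preprocess import OmicsView

__all__ = ["MogednModel", "LatentSet", "GCNEncoder", "Decoder", "VCDN",
           "LATENT_DIM", "HIDDEN_DIMS"]

HIDDEN_DIMS = (200, 100)
LATENT_DIM = 100
LEAKY_SLOPE = 0.25
DROPOUT = 0.5
DECODER_CORE = 256


@dataclass
class LatentSet:
    """Per-modality latent matrices plus how each one was obtained."""

    latents: dict[str, Tensor]
    provenance: dict[str, str]  # encoded | reconstructed | zero_filled

    def __post_init__(self):
        shapes = {z.shape for z in self.latents.values()}
        if len(shapes) > 1:
            raise ValueError(f"latent shapes disagree: {shapes}")
        for m, p in self.provenance.items():
            if p not in ("encoded", "reconstructed", "zero_filled"):
                raise ValueError(f"unknown provenance {p!r} for {m}")


class GCNEncoder:
    """Graph-convolutional encoder for one modality."""

    def __init__(self, in_dim: int, rng: np.random.Generator,
                 hidden=HIDDEN_DIMS, latent=LATENT_DIM):
        widths = [in_dim, *hidden, latent]
        self.layers = [Linear(a, b, rng) for a, b in zip(widths, widths[1:])]
        self.in_dim = in_dim

    def __call__(self, x: Tensor, adjacency: Tensor,
                 training: bool = False,
                 rng: np.random.Generator | None = None) -> Tensor:
        if x.shape[1] != self.in_dim:
            raise ValueError(
                f"encoder expects {self.in_dim} features, got {x.shape[1]}")
        h = x
        if training and DROPOUT > 0:
            if rng is None:
                raise ValueError("training forward needs an RNG for dropout")
            h = h * Tensor(dropout_mask(h.shape, DROPOUT, rng))
        for layer in self.layers:
            h = leaky_relu(layer(adjacency @ h), LEAKY_SLOPE)
        return h

    def params(self, prefix: str) -> dict[str, Tensor]:
        out = {}
        for i, layer in enumerate(self.layers):
            out.update(layer.params(f"{prefix}.layer{i}"))
        return out


class Decoder:
    """Shared core + per-modality output heads reconstructing a missing
    modality's latent from the concatenation of the others'.

    The decoder operates on standardized latents: each modality's latent
    dimensions are z-scored with statistics fixed from the decoder's
    training fold (``set_latent_stats``), and the output head's prediction
    is de-standardized back to the raw latent scale.  This makes the
    reconstruction objective and the Sim monitor independent of the
    arbitrary scale the encoders happen to produce.  Until statistics are
    set, identity stats (mu 0, sigma 1) apply.
    """

    def __init__(self, modalities: list[str], rng: np.random.Generator,
                 latent=LATENT_DIM, core_width=DECODER_CORE):
        self.modalities = list(modalities)
        in_dim = (len(modalities) - 1) * latent
        self.core = Linear(in_dim, core_width, rng)
        self.heads = {m: Linear(core_width, latent, rng) for m in self.modalities}
        self.latent_mu = {m: np.zeros(latent) for m in self.modalities}
        self.latent_sigma = {m: np.ones(latent) for m in self.modalities}

    def set_latent_stats(self, modality: str, mu: np.ndarray,
                         sigma: np.ndarray) -> None:
        """Fix standardization stats from training latents: per-dimension
        centering, but one global scale per modality (the RMS of the
        per-dimension SDs).  A per-dimension scale would inflate pure-noise
        latent dimensions to the same weight as structured ones; a single
        scale keeps the reconstruction objective focused on the
        high-variance, structured dimensions while staying independent of
        the arbitrary magnitude the encoders produce."""
        sigma = np.asarray(sigma, float)
        scale = float(np.sqrt(np.mean(sigma**2)))
        self.latent_mu[modality] = np.asarray(mu, float).copy()
        self.latent_sigma[modality] = np.full(sigma.shape, max(scale, 1e-8))

    def standardize(self, z: Tensor, modality: str) -> Tensor:
        return (z - Tensor(self.latent_mu[modality])) \
            * Tensor(1.0 / self.latent_sigma[modality])

    def decode_std(self, latents: dict[str, Tensor], target: str,
                   training: bool = False,
                   rng: np.random.Generator | None = None,
                   input_dropout: float = 0.25) -> Tensor:
        """Reconstruction in the standardized latent space of `target`."""
        if target not in self.modalities:
            raise ValueError(f"unknown modality {target!r}")
        missing = [m for m in self.modalities if m not in latents]
        if [m for m in missing if m != target]:
            raise ValueError(
                f"only the target may be missing; also missing: {missing}")
        parts = [self.standardize(latents[m], m)
                 for m in self.modalities if m != target]
        x = concat(parts, axis=1)
        if training and input_dropout > 0:
            if rng is None:
                raise ValueError("training decode needs an RNG for dropout")
            x = x * Tensor(dropout_mask(x.shape, input_dropout, rng))
        h = leaky_relu(self.core(x), LEAKY_SLOPE)
        return self.heads[target](h)

    def __call__(self, latents: dict[str, Tensor], target: str) -> Tensor:
        out = self.decode_std(latents, target)
        return out * Tensor(self.latent_sigma[target]) \
            + Tensor(self.latent_mu[target])

    def params(self, prefix: str = "decoder") -> dict[str, Tensor]:
        out = self.core.params(f"{prefix}.core")
        for m, head in self.heads.items():
            out.update(head.params(f"{prefix}.head_{m}"))
        return out

    def buffers(self, prefix: str = "decoder") -> dict[str, np.ndarray]:
        out = {}
        for m in self.modalities:
            out[f"{prefix}.mu_{m}"] = self.latent_mu[m]
            out[f"{prefix}.sigma_{m}"] = self.latent_sigma[m]
        return out

    def load_buffers(self, state: dict[str, np.ndarray],
                     prefix: str = "decoder") -> None:
        for m in self.modalities:
            self.latent_mu[m] = np.asarray(state[f"{prefix}.mu_{m}"]).copy()
            self.latent_sigma[m] = np.asarray(state[f"{prefix}.sigma_{m}"]).copy()


class VCDN:
    """Cross-omics decision fusion over the outer product of per-head class
    probabilities."""

    def __init__(self, n_classes: int, n_modalities: int, rng: np.random.Generator):
        self.n_classes = n_classes
        self.n_modalities = n_modalities
        joint = n_classes**n_modalities
        self.hidden = Linear(joint, joint, rng)
        self.out = Linear(joint, n_classes, rng)

    def joint_tensor(self, per_head_logits: list[Tensor]) -> Tensor:
        """Per-sample outer product of softmaxed head outputs, flattened to
        length C^M; each row sums to 1 (product of simplices)."""
        if len(per_head_logits) != self.n_modalities:
            raise ValueError(
                f"expected {self.n_modalities} logit sets, got {len(per_head_logits)}")
        for lg in per_head_logits:
            if lg.shape[1] != self.n_classes:
                raise ValueError(
                    f"inconsistent class count: expected {self.n_classes}, "
                    f"got {lg.shape[1]}")
        n = per_head_logits[0].shape[0]
        probs = [softmax(lg, axis=1) for lg in per_head_logits]
        joint = probs[0]
        for p in probs[1:]:
            joint = joint.reshape(n, -1, 1) * p.reshape(n, 1, -1)
            joint = joint.reshape(n, -1)
        return joint

    def __call__(self, per_head_logits: list[Tensor]) -> Tensor:
        joint = self.joint_tensor(per_head_logits)
        return self.out(leaky_relu(self.hidden(joint), LEAKY_SLOPE))

    def params(self, prefix: str = "fusion") -> dict[str, Tensor]:
        out = self.hidden.params(f"{prefix}.hidden")
        out.update(self.out.params(f"{prefix}.out"))
        return out


@dataclass
class MogednModel:
    """Parameter container for encoders, shared decoder, heads and fusion.

    Modalities are processed in the fixed order given at construction
    everywhere concatenation order matters.
    """

    modalities: list[str]
    encoders: dict[str, GCNEncoder]
    decoder: Decoder
    heads: dict[str, Linear]
    fusion: VCDN
    n_classes: int

    @classmethod
    def build(cls, in_dims: dict[str, int], n_classes: int,
              rng: np.random.Generator) -> "MogednModel":
        modalities = list(in_dims)
        encoders = {m: GCNEncoder(in_dims[m], rng) for m in modalities}
        decoder = Decoder(modalities, rng)
        heads = {m: Linear(LATENT_DIM, n_classes, rng) for m in modalities}
        fusion = VCDN(n_classes, len(modalities), rng)
        return cls(modalities=modalities, encoders=encoders, decoder=decoder,
                   heads=heads, fusion=fusion, n_classes=n_classes)

    # -- parameter groups ----------------------------------------------------
    def encoder_params(self) -> dict[str, Tensor]:
        out = {}
        for m in self.modalities:
            out.update(self.encoders[m].params(f"encoder_{m}"))
        return out

    def decoder_params(self) -> dict[str, Tensor]:
        return self.decoder.params()

    def head_params(self) -> dict[str, Tensor]:
        out = {}
        for m in self.modalities:
            out.update(self.heads[m].params(f"head_{m}"))
        return out

    def fusion_params(self) -> dict[str, Tensor]:
        return self.fusion.params()

    def all_params(self) -> dict[str, Tensor]:
        return {**self.encoder_params(), **self.decoder_params(),
                **self.head_params(), **self.fusion_params()}

    # -- forward paths ---------------------------------------------------------
    def encode(self, view: OmicsView, graph: SampleGraph, modality: str,
               training: bool = False,
               rng: np.random.Generator | None = None) -> Tensor:
        if graph.n_samples != view.n_samples:
            raise ValueError(
                f"graph has {graph.n_samples} nodes but view has "
                f"{view.n_samples} samples")
        a = Tensor(graph.dense())
        return self.encoders[modality](Tensor(view.matrix), a,
                                       training=training, rng=rng)

    def decode_missing(self, latents: LatentSet, target: str) -> Tensor:
        return self.decoder(latents.latents, target)

    def classify_head(self, latent: Tensor, modality: str) -> Tensor:
        if latent.shape[1] != LATENT_DIM:
            raise ValueError(
                f"head expects latent width {LATENT_DIM}, got {latent.shape[1]}")
        return self.heads[modality](latent)

    def vcdn_fuse(self, per_head_logits: list[Tensor]) -> Tensor:
        return self.fusion(per_head_logits)

    def forward(self, views: dict[str, OmicsView], graphs: dict[str, SampleGraph],
                missing: str | None = None, use_decoder: bool = True,
                training: bool = False,
                rng: np.random.Generator | None = None,
                ) -> tuple[Tensor, dict[str, Tensor], LatentSet]:
        """Full path: encode, substitute the missing modality's latent
        (decoder reconstruction or zero fill), classify and fuse."""
        if missing is not None and missing not in self.modalities:
            raise ValueError(f"unknown modality {missing!r}")
        if missing is not None and missing in views:
            import warnings
            warnings.warn(f"view supplied for masked modality {missing!r}; "
                          "the mask wins and the view is ignored")
        latents: dict[str, Tensor] = {}
        provenance: dict[str, str] = {}
        n = next(iter(views.values())).n_samples
        for m in self.modalities:
            if m == missing:
                continue
            latents[m] = self.encode(views[m], graphs[m], m,
                                     training=training, rng=rng)
            provenance[m] = "encoded"
        if missing is not None:
            if use_decoder:
                latents[missing] = self.decoder(latents, missing)
                provenance[missing] = "reconstructed"
            else:
                latents[missing] = Tensor(np.zeros((n, LATENT_DIM)))
                provenance[missing] = "zero_filled"
        latent_set = LatentSet(latents=latents, provenance=provenance)
        per_head = {m: self.classify_head(latents[m], m) for m in self.modalities}
        fused = self.vcdn_fuse([per_head[m] for m in self.modalities])
        return fused, per_head, latent_set
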