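"""Input x gradient attribution: closed-form checks and ranking contracts."""

import numpy as np
import pytest

from mogedn.attribution import (attribute, shared_biomarkers,
                                tumor_specific_biomarkers)
from mogedn.model import GCNEncoder, MogednModel
from mogedn.nn import Linear, params_hash
from mogedn.synthdata import SynthSpec, make_corpus
from mogedn.train_phases import build_pretrain_models, TrainConfig

from conftest import make_view


def linear_toy(rng, w_enc, w_head):
    """Single linear GCN layer (slope irrelevant: weights chosen positive
    pre-activation) + linear head."""
    enc = GCNEncoder(w_enc.shape[0], rng, hidden=(), latent=w_enc.shape[1])
    enc.layers[0].W.data = w_enc.copy()
    enc.layers[0].b.data[:] = 0.0
    head = Linear(w_enc.shape[1], w_head.shape[1], rng)
    head.W.data = w_head.copy()
    head.b.data[:] = 0.0
    return enc, head


class TestAttribute:
    def test_zero_input_zero_scores(self, rng):
        view = make_view(np.zeros((5, 3)), normalized=True)
        enc, head = linear_toy(rng, np.abs(rng.normal(size=(3, 2))),
                               rng.normal(size=(2, 2)))
        np.testing.assert_allclose(attribute(view, enc, head), 0.0)

    def test_dead_feature_scores_zero(self, rng):
        w_enc = np.abs(rng.normal(size=(3, 2)))
        w_enc[1, :] = 0.0  # feature 1 disconnected from every latent unit
        enc, head = linear_toy(rng, w_enc, rng.normal(size=(2, 2)))
        view = make_view(np.abs(rng.normal(size=(6, 3))), normalized=True)
        scores = attribute(view, enc, head)
        assert scores[1] == pytest.approx(0.0, abs=1e-12)
        assert scores[0] > 0

    def test_matches_analytic_softmax_ce_gradient(self, rng):
        # one sample, positive pre-activations so the encoder is exactly
        # linear: logits = x W E; d l / d x = W E (p - y*)
        w_enc = np.array([[1.0, 0.5], [0.2, 2.0]])
        w_head = np.array([[1.0, -1.0], [0.5, 0.3]])
        enc, head = linear_toy(rng, w_enc, w_head)
        x = np.array([[2.0, 1.0]])
        logits = x @ w_enc @ w_head
        p = np.exp(logits) / np.exp(logits).sum()
        y_star = logits.argmax()
        onehot = np.zeros_like(p)
        onehot[0, y_star] = 1.0
        grad_x = (p - onehot) @ (w_enc @ w_head).T
        expected = np.abs(x * grad_x).ravel()
        scores = attribute(make_view(x, normalized=True), enc, head)
        np.testing.assert_allclose(scores, expected, atol=1e-6)

    def test_feature_scaling_scales_score_in_linear_toy(self, rng):
        # scaling a feature column by c scales x and grad consistently with
        # the closed form; verify against direct recomputation
        w_enc = np.array([[1.0, 0.5], [0.2, 2.0]])
        w_head = np.array([[1.0, -1.0], [0.5, 0.3]])
        enc, head = linear_toy(rng, w_enc, w_head)
        x = np.array([[2.0, 1.0]])
        for c in (0.5, 2.0):
            xs = x.copy()
            xs[0, 0] *= c
            logits = xs @ w_enc @ w_head
            p = np.exp(logits) / np.exp(logits).sum()
            onehot = np.zeros_like(p)
            onehot[0, logits.argmax()] = 1.0
            expected = np.abs(xs * ((p - onehot) @ (w_enc @ w_head).T)).ravel()
            got = attribute(make_view(xs, normalized=True), enc, head)
            np.testing.assert_allclose(got, expected, atol=1e-6)

    def test_sample_order_invariance(self, rng):
        enc = GCNEncoder(4, rng, hidden=(8,), latent=3)
        head = Linear(3, 2, rng)
        x = rng.normal(size=(10, 4))
        a = attribute(make_view(x, normalized=True), enc, head)
        b = attribute(make_view(x[::-1], normalized=True), enc, head)
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_batch_size_invariance(self, rng):
        enc = GCNEncoder(4, rng, hidden=(8,), latent=3)
        head = Linear(3, 2, rng)
        view = make_view(rng.normal(size=(11, 4)), normalized=True)
        full = attribute(view, enc, head)
        batched = attribute(view, enc, head, batch_size=3)
        np.testing.assert_allclose(batched, full, atol=1e-6)

    def test_parameters_not_mutated(self, rng):
        enc = GCNEncoder(4, rng)
        head = Linear(100, 3, rng)
        before = params_hash({**enc.params("e"), **head.params("h")})
        attribute(make_view(rng.normal(size=(6, 4)), normalized=True),
                  enc, head)
        assert params_hash({**enc.params("e"), **head.params("h")}) == before

    def test_unnormalized_view_warns(self, rng):
        enc = GCNEncoder(3, rng)
        head = Linear(100, 2, rng)
        with pytest.warns(UserWarning, match="unnormalized"):
            attribute(make_view(np.ones((2, 3))), enc, head)


@pytest.fixture(scope="module")
def untrained_models():
    corpus = make_corpus([SynthSpec(n_samples=60, seed=0),
                          SynthSpec(n_samples=60, seed=1)])
    models = build_pretrain_models(corpus, TrainConfig(seed=0))
    views = {c.name: c.views for c in corpus.cohorts}
    return models, views


class TestSharedBiomarkers:
    def test_ranking_restricted_to_common_block(self, untrained_models):
        models, views = untrained_models
        d_shared = {"mrna": 10, "methylation": 10, "mirna": 5}
        res = shared_biomarkers(models, views, d_shared=d_shared,
                                k_top={"mrna": 5, "methylation": 5,
                                       "mirna": 3})
        for m, r in res.items():
            assert r.ranking.max() < d_shared[m]
            assert len(r.top_features) == min(r.k_top, d_shared[m])
            assert r.provenance == "shared"

    def test_single_cohort_average_equals_own_scores(self, untrained_models):
        models, views = untrained_models
        name = next(iter(models))
        solo = shared_biomarkers({name: models[name]}, {name: views[name]},
                                 d_shared={"mrna": 10, "methylation": 10,
                                           "mirna": 5})
        direct = attribute(views[name]["mrna"], models[name].encoders["mrna"],
                           models[name].heads["mrna"])
        np.testing.assert_allclose(solo["mrna"].scores, direct[:10])


class TestTumorSpecific:
    def test_full_ranking_and_tie_break(self, rng, untrained_models):
        models, views = untrained_models
        model = next(iter(models.values()))
        train_views = views[next(iter(views))]
        res = tumor_specific_biomarkers(model, train_views,
                                        k_top=train_views["mirna"].n_features)
        r = res["mirna"]
        assert sorted(r.ranking.tolist()) == list(range(r.scores.size))
        # descending scores along the ranking, ties by ascending index
        s = r.scores[r.ranking]
        assert all(s[i] >= s[i + 1] - 1e-15 for i in range(len(s) - 1))

    def test_k_above_feature_count_rejected(self, untrained_models):
        models, views = untrained_models
        model = next(iter(models.values()))
        with pytest.raises(ValueError, match="exceeds"):
            tumor_specific_biomarkers(model, views[next(iter(views))],
                                      k_top=10_000)
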