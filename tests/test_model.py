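"""Forward contracts of encoders, decoder, heads and VCDN fusion."""

import numpy as np
import pytest
import scipy.sparse as sp

from mogedn.autograd import Tensor
from mogedn.graphs import SampleGraph
from mogedn.model import (LATENT_DIM, Decoder, GCNEncoder, MogednModel, VCDN)
from mogedn.nn import clone_state, load_state

from conftest import make_view


def identity_graph(n):
    return SampleGraph(adjacency=sp.identity(n, format="csr"),
                       edge_per_node=1, threshold=0.0)


def build_model(rng, in_dims=None, n_classes=3):
    in_dims = in_dims or {"mrna": 12, "methylation": 10, "mirna": 6}
    return MogednModel.build(in_dims, n_classes, rng)


class TestEncoder:
    def test_zero_input_zero_weights_gives_zero_latent(self, rng):
        enc = GCNEncoder(5, rng)
        for layer in enc.layers:
            layer.W.data[:] = 0.0
        out = enc(Tensor(np.zeros((4, 5))), Tensor(np.eye(4)))
        np.testing.assert_allclose(out.data, 0.0)

    def test_identical_samples_identical_latents(self, rng):
        enc = GCNEncoder(5, rng)
        x = np.tile(rng.normal(size=(1, 5)), (3, 1))
        out = enc(Tensor(x), Tensor(np.eye(3) / 1.0))
        np.testing.assert_allclose(out.data[0], out.data[1])

    def test_one_layer_toy_matches_hand_product(self, rng):
        enc = GCNEncoder(2, rng, hidden=(), latent=2)
        w = np.array([[1.0, -2.0], [0.5, 3.0]])
        enc.layers[0].W.data = w.copy()
        enc.layers[0].b.data = np.array([0.1, -0.1])
        a = np.array([[0.5, 0.5], [0.25, 0.75]])
        x = np.array([[1.0, 2.0], [-1.0, 0.5]])
        pre = a @ x @ w + np.array([0.1, -0.1])
        expected = np.where(pre > 0, pre, 0.25 * pre)  # LeakyReLU(0.25)
        out = enc(Tensor(x), Tensor(a))
        np.testing.assert_allclose(out.data, expected, atol=1e-12)

    def test_width_mismatch_rejected(self, rng):
        enc = GCNEncoder(5, rng)
        with pytest.raises(ValueError, match="expects 5"):
            enc(Tensor(np.zeros((3, 4))), Tensor(np.eye(3)))


class TestDecoder:
    def test_core_input_width_is_sum_of_other_latents(self, rng):
        dec = Decoder(["mrna", "methylation", "mirna"], rng)
        assert dec.core.W.shape[0] == 2 * LATENT_DIM

    def test_zero_weights_zero_reconstruction(self, rng):
        dec = Decoder(["mrna", "methylation", "mirna"], rng)
        for p in dec.params().values():
            p.data[:] = 0.0
        z = {m: Tensor(rng.normal(size=(4, LATENT_DIM)))
             for m in ("mrna", "methylation")}
        np.testing.assert_allclose(dec(z, "mirna").data, 0.0)

    def test_single_sample_matches_hand_forward(self, rng):
        dec = Decoder(["mrna", "methylation"], rng, latent=2, core_width=3)
        z = {"mrna": Tensor(np.array([[1.0, -1.0]]))}
        h = np.array([[1.0, -1.0]]) @ dec.core.W.data + dec.core.b.data
        h = np.where(h > 0, h, 0.25 * h)
        expected = h @ dec.heads["methylation"].W.data \
            + dec.heads["methylation"].b.data
        np.testing.assert_allclose(dec(z, "methylation").data, expected,
                                   atol=1e-12)

    def test_two_missing_modalities_rejected(self, rng):
        dec = Decoder(["mrna", "methylation", "mirna"], rng)
        z = {"mrna": Tensor(np.zeros((2, LATENT_DIM)))}
        with pytest.raises(ValueError, match="missing"):
            dec(z, "mirna")

    def test_standardization_roundtrip(self, rng):
        dec = Decoder(["mrna", "methylation"], rng)
        dec.set_latent_stats("mrna", rng.normal(size=LATENT_DIM),
                             rng.uniform(0.5, 2, LATENT_DIM))
        z = {"methylation": Tensor(rng.normal(size=(3, LATENT_DIM)))}
        std = dec.decode_std(z, "mrna").data
        raw = dec(z, "mrna").data
        np.testing.assert_allclose(
            raw, std * dec.latent_sigma["mrna"] + dec.latent_mu["mrna"])


class TestVCDN:
    def test_joint_length_is_classes_to_the_modalities(self, rng):
        v = VCDN(2, 3, rng)
        logits = [Tensor(rng.normal(size=(5, 2))) for _ in range(3)]
        assert v.joint_tensor(logits).shape == (5, 8)

    def test_confident_heads_give_one_hot_joint(self, rng):
        v = VCDN(3, 3, rng)
        big = np.full((1, 3), -50.0)
        big[0, 1] = 50.0
        joint = v.joint_tensor([Tensor(big)] * 3).data
        idx = np.ravel_multi_index((1, 1, 1), (3, 3, 3))
        assert joint[0, idx] == pytest.approx(1.0, abs=1e-9)

    def test_hand_outer_product(self, rng):
        v = VCDN(2, 2, rng)
        a = np.log(np.array([[0.5, 0.5]]))
        b = np.array([[50.0, -50.0]])
        joint = v.joint_tensor([Tensor(a), Tensor(b)]).data
        np.testing.assert_allclose(joint, [[0.5, 0.0, 0.5, 0.0]], atol=1e-9)

    def test_joint_rows_sum_to_one(self, rng):
        v = VCDN(4, 3, rng)
        logits = [Tensor(rng.normal(size=(7, 4))) for _ in range(3)]
        np.testing.assert_allclose(v.joint_tensor(logits).data.sum(axis=1),
                                   1.0, atol=1e-10)

    def test_inconsistent_class_counts_rejected(self, rng):
        v = VCDN(3, 2, rng)
        with pytest.raises(ValueError, match="class count"):
            v([Tensor(np.zeros((2, 3))), Tensor(np.zeros((2, 4)))])


class TestForward:
    def _views_graphs(self, rng, model, n=6):
        views, graphs = {}, {}
        for m in model.modalities:
            d = model.encoders[m].in_dim
            views[m] = make_view(rng.normal(size=(n, d)), modality=m,
                                 normalized=True)
            graphs[m] = identity_graph(n)
        return views, graphs

    def test_no_missing_equals_plain_path(self, rng):
        model = build_model(rng)
        views, graphs = self._views_graphs(rng, model)
        fused, per_head, latents = model.forward(views, graphs)
        for m in model.modalities:
            assert latents.provenance[m] == "encoded"
            direct = model.classify_head(
                model.encode(views[m], graphs[m], m), m)
            np.testing.assert_allclose(per_head[m].data, direct.data)

    def test_zero_fill_is_exact_zero_matrix(self, rng):
        model = build_model(rng)
        views, graphs = self._views_graphs(rng, model)
        _, _, latents = model.forward(views, graphs, missing="mirna",
                                      use_decoder=False)
        np.testing.assert_array_equal(latents.latents["mirna"].data, 0.0)
        assert latents.provenance["mirna"] == "zero_filled"

    def test_decoder_on_and_off_differ(self, rng):
        model = build_model(rng)
        views, graphs = self._views_graphs(rng, model)
        on, _, lat_on = model.forward(views, graphs, missing="mirna",
                                      use_decoder=True)
        off, _, _ = model.forward(views, graphs, missing="mirna",
                                  use_decoder=False)
        assert lat_on.provenance["mirna"] == "reconstructed"
        assert not np.allclose(on.data, off.data)

    def test_mask_wins_warning_when_view_supplied(self, rng):
        model = build_model(rng)
        views, graphs = self._views_graphs(rng, model)
        with pytest.warns(UserWarning, match="mask wins"):
            model.forward(views, graphs, missing="mrna", use_decoder=False)

    def test_permutation_equivariance(self, rng):
        model = build_model(rng)
        views, graphs = self._views_graphs(rng, model, n=5)
        fused, _, _ = model.forward(views, graphs)
        perm = rng.permutation(5)
        pviews = {m: make_view(v.matrix[perm], modality=m, normalized=True)
                  for m, v in views.items()}
        pfused, _, _ = model.forward(pviews, graphs)
        np.testing.assert_allclose(pfused.data, fused.data[perm], atol=1e-10)

    def test_state_roundtrip_reproduces_forward(self, rng):
        model = build_model(rng)
        views, graphs = self._views_graphs(rng, model)
        fused, _, _ = model.forward(views, graphs)
        state = clone_state(model.all_params())
        model2 = build_model(np.random.default_rng(999))
        load_state(model2.all_params(), state)
        fused2, _, _ = model2.forward(views, graphs)
        np.testing.assert_array_equal(fused.data, fused2.data)
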