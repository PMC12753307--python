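"""Three-phase curriculum: freeze contracts, determinism, learnability."""

import numpy as np
import pytest

from mogedn.autograd import Tensor
from mogedn.losses_metrics import similarity
from mogedn.model import Decoder, LATENT_DIM
from mogedn.nn import Adam, params_hash
from mogedn.synthdata import SynthSpec, make_corpus
from mogedn.train_phases import (TrainConfig, build_pretrain_models,
                                 mean_baseline_sim, phase1, phase2, phase3,
                                 run_pretraining, _frozen_latents)


@pytest.fixture(scope="module")
def small_corpus():
    return make_corpus([SynthSpec(n_samples=80, seed=0),
                        SynthSpec(n_samples=80, seed=1)])


def small_config(**kw):
    base = dict(max_epochs_phase1=60, max_epochs_phase2=60,
                max_epochs_phase3=30, early_stop_patience=20, seed=0)
    base.update(kw)
    return TrainConfig(**base)


class TestPhase1:
    def test_zero_epochs_returns_initial_model(self, small_corpus):
        cfg = small_config(max_epochs_phase1=0)
        models = build_pretrain_models(small_corpus, cfg)
        before = params_hash(next(iter(models.values())).all_params())
        history = phase1(small_corpus, models, cfg)
        assert history == []
        assert params_hash(next(iter(models.values())).all_params()) == before

    def test_history_contract_and_decoder_untouched(self, small_corpus):
        cfg = small_config()
        models = build_pretrain_models(small_corpus, cfg)
        dec_before = params_hash(next(iter(models.values())).decoder_params())
        history = phase1(small_corpus, models, cfg)
        assert 0 < len(history) <= cfg.max_epochs_phase1
        assert "early_stop_epoch" in history[-1]
        assert all(np.isfinite(h["train_loss"]) for h in history)
        assert params_hash(next(iter(models.values())).decoder_params()) \
            == dec_before

    def test_separable_corpus_reaches_high_f1(self):
        # single well-separated cohort: supervised pretraining must learn it
        corpus = make_corpus([SynthSpec(n_samples=150, seed=3),
                              SynthSpec(n_samples=150, seed=4)])
        cfg = small_config(max_epochs_phase1=200, early_stop_patience=40)
        models = build_pretrain_models(corpus, cfg)
        history = phase1(corpus, models, cfg)
        assert max(h["val_f1_macro"] for h in history) > 0.8

    def test_single_class_cohort_rejected(self, small_corpus):
        cfg = small_config()
        models = build_pretrain_models(small_corpus, cfg)
        bad = small_corpus.cohorts[0]
        saved = bad.labels.copy()
        bad.labels[:] = 0
        try:
            with pytest.raises(ValueError, match="single class"):
                phase1(small_corpus, models, cfg)
        finally:
            bad.labels[:] = saved


class TestPhase2:
    def test_encoders_frozen_by_hash(self, small_corpus):
        cfg = small_config()
        models = build_pretrain_models(small_corpus, cfg)
        phase1(small_corpus, models, cfg)
        shared = next(iter(models.values()))
        enc_before = params_hash(shared.encoder_params())
        head_before = params_hash(shared.head_params())
        phase2(small_corpus, models, cfg)
        assert params_hash(shared.encoder_params()) == enc_before
        assert params_hash(shared.head_params()) == head_before

    def test_linearly_dependent_latents_reach_sim_near_one(self, rng):
        # constructed fixture: target latent is an exact linear map of the
        # other modalities' latents; decoder training drives Sim toward 1
        mods = ["mrna", "methylation", "mirna"]
        width = 10  # small latent instance: the mechanism, not the size
        dec = Decoder(mods, rng, latent=width, core_width=64)
        n_train, n = 500, 600
        za = rng.normal(size=(n, width))
        zb = rng.normal(size=(n, width))
        mix = rng.normal(size=(2 * width, width)) / 4
        zc = np.hstack([za, zb]) @ mix
        for m, z in zip(mods, (za, zb, zc)):
            dec.set_latent_stats(m, z[:n_train].mean(0), z[:n_train].std(0))
        opt = Adam(dec.params(), lr=5e-3)
        for _ in range(1200):
            opt.zero_grad()
            pred = dec.decode_std({"mrna": Tensor(za[:n_train]),
                                   "methylation": Tensor(zb[:n_train])},
                                  "mirna")
            tgt = dec.standardize(Tensor(zc[:n_train]), "mirna")
            ((pred - tgt) ** 2).mean().backward()
            opt.step()
        pred = dec.decode_std({"mrna": Tensor(za[n_train:]),
                               "methylation": Tensor(zb[n_train:])},
                              "mirna").data
        tgt = dec.standardize(Tensor(zc[n_train:]), "mirna").data
        assert similarity(((pred - tgt) ** 2).mean()) > 0.95

    def test_independent_latents_plateau_at_mean_baseline(self, rng):
        mods = ["mrna", "methylation"]
        width = 10
        dec = Decoder(mods, rng, latent=width, core_width=64)
        za = rng.normal(size=(500, width))
        zb = rng.normal(size=(500, width))  # independent of za
        for m, z in zip(mods, (za, zb)):
            dec.set_latent_stats(m, z[:400].mean(0), z[:400].std(0))
        opt = Adam(dec.params(), lr=5e-3)
        for _ in range(200):
            opt.zero_grad()
            pred = dec.decode_std({"mrna": Tensor(za[:400])}, "methylation")
            tgt = dec.standardize(Tensor(zb[:400]), "methylation")
            ((pred - tgt) ** 2).mean().backward()
            opt.step()
        pred = dec.decode_std({"mrna": Tensor(za[400:])}, "methylation").data
        tgt = dec.standardize(Tensor(zb[400:]), "methylation").data
        sim = similarity(((pred - tgt) ** 2).mean())
        baseline = similarity((tgt**2).mean())
        assert sim <= baseline + 0.02  # no structure to exploit
        assert sim > baseline - 0.15   # and no catastrophic drift


class TestPhase3:
    def test_decoder_frozen_and_mask_prob_zero_never_masks(self, small_corpus):
        cfg = small_config(mask_prob=0.0)
        models = build_pretrain_models(small_corpus, cfg)
        phase1(small_corpus, models, cfg)
        phase2(small_corpus, models, cfg)
        shared = next(iter(models.values()))
        dec_before = params_hash(shared.decoder_params())
        history = phase3(small_corpus, models, cfg)
        assert params_hash(shared.decoder_params()) == dec_before
        assert all(m is None for h in history for m in h["masked"])

    def test_masking_fires_with_prob_one(self, small_corpus):
        cfg = small_config(mask_prob=1.0, max_epochs_phase3=5)
        models = build_pretrain_models(small_corpus, cfg)
        phase1(small_corpus, models, cfg)
        phase2(small_corpus, models, cfg)
        history = phase3(small_corpus, models, cfg)
        assert all(m is not None for h in history for m in h["masked"])


class TestDeterminism:
    def test_full_curriculum_bit_reproducible(self):
        corpus = make_corpus([SynthSpec(n_samples=60, seed=0),
                              SynthSpec(n_samples=60, seed=1)])
        cfg = small_config(max_epochs_phase1=20, max_epochs_phase2=15,
                           max_epochs_phase3=10)
        r1 = run_pretraining(corpus, cfg)
        r2 = run_pretraining(corpus, cfg)
        assert r1.histories == r2.histories
        assert params_hash(r1.shared_model.all_params()) \
            == params_hash(r2.shared_model.all_params())

    def test_phase_rerun_from_boundary_reproduces_history(self, small_corpus):
        cfg = small_config(max_epochs_phase2=15)
        models = build_pretrain_models(small_corpus, cfg)
        phase1(small_corpus, models, cfg)
        shared = next(iter(models.values()))
        from mogedn.nn import clone_state, load_state
        snapshot = clone_state(shared.all_params())
        h_a = phase2(small_corpus, models, cfg)
        load_state(shared.all_params(), snapshot)
        h_b = phase2(small_corpus, models, cfg)
        assert h_a == h_b


class TestBaseline:
    def test_mean_baseline_sim_standardized_near_half(self, small_corpus):
        cfg = small_config(max_epochs_phase1=20)
        models = build_pretrain_models(small_corpus, cfg)
        phase1(small_corpus, models, cfg)
        shared = next(iter(models.values()))
        latents = _frozen_latents(models, small_corpus)
        for m in shared.modalities:
            pooled = np.vstack([latents[c.name][m][c.train_idx]
                                for c in small_corpus.cohorts])
            shared.decoder.set_latent_stats(m, pooled.mean(0), pooled.std(0))
        base = mean_baseline_sim(latents[small_corpus.cohorts[0].name],
                                 small_corpus.cohorts[0].val_idx,
                                 shared.decoder)
        assert 0.3 < base < 0.7
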