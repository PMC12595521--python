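"""VAE loss components, training behavior, and latent embedding."""

import numpy as np
import pytest

from thermorca.encoding import encode, encode_sequences, decode_argmax
from thermorca.synthetic import make_planted_dataset
from thermorca.vae import (
    VaeConfig,
    VaeModel,
    decoder_probabilities,
    elbo,
    embed,
    gaussian_kl,
    latent_table,
    predict_property,
    train_semisupervised,
    train_unsupervised,
)

SMALL = dict(encoder_widths=(64, 32), decoder_widths=(32, 64))


class TestGaussianKl:
    def test_posterior_equal_to_prior_is_zero(self):
        assert gaussian_kl(np.zeros(4), np.zeros(4)) == pytest.approx(0.0)

    def test_unit_shift_is_half(self):
        # ½ Σ (μ² + σ² − 1 − log σ²) with μ=(1,0,0,0), σ=1 → ½
        assert gaussian_kl(np.array([1.0, 0, 0, 0]), np.zeros(4)) == pytest.approx(0.5)

    def test_matches_monte_carlo_estimate(self):
        rng = np.random.default_rng(0)
        mu = rng.normal(size=4)
        lv = rng.normal(scale=0.5, size=4)
        sd = np.exp(0.5 * lv)
        n = 100_000
        z = mu + sd * rng.standard_normal((n, 4))
        log_q = -0.5 * np.sum((z - mu) ** 2 / sd**2 + lv + np.log(2 * np.pi), axis=1)
        log_p = -0.5 * np.sum(z**2 + np.log(2 * np.pi), axis=1)
        samples = log_q - log_p
        se = samples.std(ddof=1) / np.sqrt(n)
        assert abs(samples.mean() - gaussian_kl(mu, lv)[0]) < 3 * se

    def test_nonnegative_for_random_inputs(self):
        rng = np.random.default_rng(1)
        kl = gaussian_kl(rng.normal(size=(200, 4)), rng.normal(size=(200, 4)))
        assert np.all(kl >= 0)


class TestDecoderOutputs:
    def test_distributions_normalized_for_random_latents(self, small_unsup_model):
        rng = np.random.default_rng(2)
        probs = decoder_probabilities(small_unsup_model, rng.normal(size=(50, 4)))
        assert np.allclose(probs.sum(axis=-1), 1.0, atol=1e-6)
        assert np.all(probs >= 0)


class TestTraining:
    def test_same_seed_identical_parameters(self, planted_small):
        msa, _ = planted_small
        oh = encode(msa)
        cfg = VaeConfig(epochs=10, seed=3, **SMALL)
        a = train_unsupervised(oh, cfg)
        b = train_unsupervised(oh, cfg)
        assert all(np.array_equal(a.params[k], b.params[k]) for k in a.params)

    def test_training_improves_elbo(self, small_unsup_model):
        hist = small_unsup_model.history
        assert hist[-1]["loss"] < hist[0]["loss"]
        assert all(h["kl"] >= 0 for h in hist)

    def test_wildtype_reconstructed_after_training(self, planted_small, small_unsup_model):
        msa, _ = planted_small
        wt_onehot = encode_sequences([msa.wildtype_row], ["wt"])
        mu = embed(small_unsup_model, wt_onehot)[0].mean
        decoded = decode_argmax(decoder_probabilities(small_unsup_model, mu))[0]
        assert decoded == msa.wildtype_row

    def test_fullbatch_row_shuffle_same_final_loss(self, planted_small):
        msa, _ = planted_small
        cfg = VaeConfig(epochs=40, seed=4, batch_size=0, **SMALL)
        a = train_unsupervised(encode(msa), cfg)
        order = np.random.default_rng(5).permutation(msa.n_seqs)
        shuffled = encode_sequences([msa.rows[i] for i in order], [msa.ids[i] for i in order])
        b = train_unsupervised(shuffled, cfg)
        assert b.history[-1]["loss"] == pytest.approx(a.history[-1]["loss"], rel=0.1)

    def test_empty_msa_rejected(self):
        from thermorca.encoding import OneHotMSA

        empty = OneHotMSA(tensor=np.zeros((0, 5, 21)), ids=[])
        with pytest.raises(ValueError):
            train_unsupervised(empty, VaeConfig(epochs=1))


class TestSemisupervised:
    def labels(self, msa, truth):
        from thermorca.synthetic import is_functional, true_tmax

        t = np.full(msa.n_seqs, np.nan)
        a = np.zeros(msa.n_seqs)
        for i, row in enumerate(msa.rows):
            if is_functional(row, truth):
                a[i] = 1.0
                t[i] = true_tmax(row, truth)
        return t, a

    def test_zero_property_weight_reduces_to_unsupervised(self, planted_small):
        msa, truth = planted_small
        oh = encode(msa)
        t, a = self.labels(msa, truth)
        cfg = VaeConfig(epochs=15, seed=6, **SMALL)
        unsup = train_unsupervised(oh, cfg)
        semi = train_semisupervised(oh, t, a, VaeConfig(epochs=15, seed=6, property_weight=0.0, **SMALL))
        shared = [k for k in unsup.params if not k.startswith("prop_")]
        assert all(np.array_equal(unsup.params[k], semi.params[k]) for k in shared)

    def test_all_unlabeled_rejected(self, planted_small):
        msa, _ = planted_small
        oh = encode(msa)
        nan = np.full(msa.n_seqs, np.nan)
        with pytest.raises(ValueError, match="no supervision"):
            train_semisupervised(oh, nan, nan, VaeConfig(epochs=1, **SMALL))

    def test_predictions_finite_and_probabilistic(self, planted_small):
        msa, truth = planted_small
        t, a = self.labels(msa, truth)
        m = train_semisupervised(encode(msa), t, a, VaeConfig(epochs=30, seed=7, property_weight=10, **SMALL))
        tmax_hat, p_act = predict_property(m, encode(msa))
        assert np.all(np.isfinite(tmax_hat))
        assert np.all((p_act >= 0) & (p_act <= 1))

    def test_supervised_latent_separates_classes_better(self, planted_small):
        # analogue of the published before/after embeddings: coloring by
        # thermal tolerance shows more structure once the property head
        # shapes the latent space
        from sklearn.metrics import silhouette_score
        from thermorca.synthetic import true_tmax

        msa, truth = planted_small
        oh = encode(msa)
        t, a = self.labels(msa, truth)
        cfg_u = VaeConfig(epochs=60, seed=8, **SMALL)
        cfg_s = VaeConfig(epochs=60, seed=8, property_weight=10, **SMALL)
        unsup = train_unsupervised(oh, cfg_u)
        semi = train_semisupervised(oh, t, a, cfg_s)
        classes = np.array([true_tmax(r, truth) > truth.base_tmax for r in msa.rows])
        z_u = np.stack([p.mean for p in embed(unsup, oh)])
        z_s = np.stack([p.mean for p in embed(semi, oh)])
        assert silhouette_score(z_s, classes) > silhouette_score(z_u, classes)


class TestEmbed:
    def test_identical_sequences_identical_embeddings(self, planted_small, small_unsup_model):
        msa, _ = planted_small
        twice = encode_sequences([msa.wildtype_row, msa.wildtype_row], ["a", "b"])
        pts = embed(small_unsup_model, twice)
        assert np.array_equal(pts[0].mean, pts[1].mean)
        assert np.array_equal(pts[0].log_variance, pts[1].log_variance)

    def test_coordinates_table_shape(self, planted_small, small_unsup_model):
        msa, _ = planted_small
        df = latent_table(small_unsup_model, encode(msa))
        assert len(df) == msa.n_seqs
        assert {"id", "z1", "z2", "z3", "z4", "label"} <= set(df.columns)

    def test_untrained_model_rejected(self, planted_small):
        msa, _ = planted_small
        model = VaeModel(config=VaeConfig(), n_columns=msa.column_count, params={})
        with pytest.raises(ValueError, match="untrained"):
            embed(model, encode(msa))


class TestElbo:
    def test_components_consistent(self, planted_small, small_unsup_model):
        msa, _ = planted_small
        total, recon, kl = elbo(encode(msa), small_unsup_model)
        assert kl >= 0
        assert total == pytest.approx(recon - small_unsup_model.config.kl_weight * kl)


class TestPersistence:
    def test_save_load_round_trip(self, small_unsup_model, tmp_path):
        path = tmp_path / "model.npz"
        small_unsup_model.save(path)
        loaded = VaeModel.load(path)
        assert loaded.config == small_unsup_model.config
        assert all(np.array_equal(loaded.params[k], small_unsup_model.params[k])
                   for k in small_unsup_model.params)
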