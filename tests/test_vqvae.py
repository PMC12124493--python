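"""Vector quantization, EMA codebook updates, and the autoencoder contract."""

import itertools

import numpy as np
import pytest

from kaizen import SceneParams, VQVAE, VQVAEConfig, generate_scene
from kaizen.pipeline import training_pair_stream
from kaizen.vqvae import VectorQuantizerEMA


def tiny_config(**kw):
    defaults = dict(
        patch_size=32, codebook_size=8, enc_channels=(4, 4, 8, 8, 8),
        dec_t_channels=(4, 4, 4), res_hidden=4, seed=0,
    )
    defaults.update(kw)
    return VQVAEConfig(**defaults)


class TestQuantizer:
    def test_exact_embedding_maps_to_its_index(self, rng):
        q = VectorQuantizerEMA(tiny_config(codebook_size=5, embedding_dim=2), rng)
        idx, quant = q.quantize(q.embeddings[3][None])
        assert idx[0] == 3
        np.testing.assert_array_equal(quant[0], q.embeddings[3])

    def test_single_code_always_selected(self, rng):
        q = VectorQuantizerEMA(tiny_config(codebook_size=1, embedding_dim=2), rng)
        idx, _ = q.quantize(rng.normal(size=(40, 2)))
        assert set(idx) == {0}

    def test_matches_exhaustive_nearest_neighbor(self, rng):
        """Brute-force oracle: per-vector argmin over all pairwise distances."""
        q = VectorQuantizerEMA(tiny_config(codebook_size=32, embedding_dim=2), rng)
        latents = rng.normal(size=(1000, 2))
        idx, quant = q.quantize(latents)
        for v, i in zip(latents, idx):
            dists = [np.sum((v - e) ** 2) for e in q.embeddings]
            assert i == int(np.argmin(dists))
        np.testing.assert_array_equal(quant, q.embeddings[idx])

    def test_ema_update_moves_only_assigned_code(self, rng):
        q = VectorQuantizerEMA(tiny_config(codebook_size=4, embedding_dim=2), rng)
        q.embeddings = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0], [10.0, 10.0]])
        # warm every code so none is at zero usage
        q.ema_cluster_size[:] = 1.0
        q.ema_embed_sum[:] = q.embeddings * 1.0
        before = q.embeddings.copy()
        sums_before = q.ema_embed_sum.copy()
        batch = np.tile(q.embeddings[2] + np.array([0.5, -0.5]), (16, 1))
        idx, _ = q.quantize(batch)
        assert set(idx) == {2}
        q.ema_update(batch, idx)
        moved = q.embeddings[2] - before[2]
        target_dir = batch.mean(axis=0) - before[2]
        assert moved @ target_dir > 0  # moved toward the batch mean
        # unassigned codes: sums and counts decay by the same factor, so
        # their embedding vectors stay put (up to Laplace smoothing)
        others = [k for k in range(4) if k != 2]
        np.testing.assert_allclose(q.embeddings[others], before[others], atol=1e-3)
        np.testing.assert_allclose(
            q.ema_embed_sum[others], q.decay * sums_before[others]
        )


class TestAutoencoderShapes:
    @pytest.mark.parametrize("patch_size,latent_side", [(32, 4), (40, 5), (120, 15)])
    def test_encode_decode_preserve_patch_size(self, patch_size, latent_side):
        model = VQVAE(tiny_config(patch_size=patch_size))
        z = model.encode(np.zeros((2, patch_size, patch_size)))
        assert z.shape == (2, latent_side, latent_side, 2)
        assert model.decode(z).shape == (2, patch_size, patch_size, 1)

    def test_identical_patches_give_identical_latents(self, rng):
        model = VQVAE(tiny_config())
        patch = rng.random((32, 32))
        np.testing.assert_array_equal(model.encode(patch), model.encode(patch.copy()))

    def test_wrong_patch_side_rejected(self):
        model = VQVAE(tiny_config())
        with pytest.raises(ValueError):
            model.encode(np.zeros((2, 40, 40)))


@pytest.fixture(scope="module")
def trained():
    scenes = [
        generate_scene(SceneParams(n_cells=6, seed=s)) for s in range(4)
    ]
    stream = training_pair_stream(
        scenes, 32, rng=np.random.default_rng(1)
    )
    cfg = VQVAEConfig.toy(
        codebook_size=16, enc_channels=(8, 8, 16, 16, 16),
        dec_t_channels=(8, 8, 8), res_hidden=8, warmup_steps=60,
        train_steps=220, seed=0,
    )
    model = VQVAE(cfg).fit(stream)
    return model, scenes


class TestTrainingAndPredict:

    def test_loss_beats_zero_predictor_baseline(self, trained):
        model, scenes = trained
        stream = training_pair_stream(scenes, 32, rng=np.random.default_rng(9))
        pairs = list(itertools.islice(stream, 128))
        l1, zero_baseline = model.holdout_l1(pairs)
        assert l1 < zero_baseline

    def test_predict_shape_anchor_and_nonnegativity(self, trained):
        model, scenes = trained
        from kaizen.patches import pad_for_inference
        padded = pad_for_inference(scenes[0].image, 32)
        out = model.predict((40, 50), padded)
        assert out.shape == (32, 32)
        assert out.min() >= 0.0
        np.testing.assert_array_equal(out, model.predict((40, 50), padded))

    def test_save_load_round_trip(self, trained, tmp_path):
        model, scenes = trained
        path = tmp_path / "model.npz"
        model.save(path)
        clone = VQVAE.load(path)
        from kaizen.patches import pad_for_inference
        padded = pad_for_inference(scenes[0].image, 32)
        np.testing.assert_array_equal(
            model.predict((40, 50), padded), clone.predict((40, 50), padded)
        )
        assert clone.config == model.config

    def test_seeded_training_is_deterministic(self):
        def short_run():
            scenes = [generate_scene(SceneParams(n_cells=5, seed=2))]
            stream = training_pair_stream(scenes, 32, rng=np.random.default_rng(3))
            cfg = tiny_config(train_steps=5, warmup_steps=2)
            return VQVAE(cfg).fit(stream).loss_history_

        assert short_run() == short_run()

    def test_empty_center_only_stream_trends_toward_zero_output(self):
        scene = generate_scene(SceneParams(n_cells=3, seed=4))
        stream = training_pair_stream(
            scene and [scene], 32, p_center=0.0, rng=np.random.default_rng(5)
        )
        cfg = VQVAEConfig.toy(
            codebook_size=8, enc_channels=(4, 4, 8, 8, 8),
            dec_t_channels=(4, 4, 4), res_hidden=4, warmup_steps=30,
            train_steps=120, seed=0,
        )
        model = VQVAE(cfg).fit(stream)
        first = np.mean(model.loss_history_[:20])
        last = np.mean(model.loss_history_[-20:])
        assert last < first  # loss vs the empty target shrinks in trend
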