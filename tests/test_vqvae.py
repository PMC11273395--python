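"""VQ-VAE: quantization against brute force, loss arithmetic, ALM, training."""

import dataclasses

import numpy as np
import pytest

from octa_anomaly import vqvae
from octa_anomaly.synthetic import DatasetManifest, ManifestRecord
from octa_anomaly.vqvae import (VqVae, VqVaeConfig, alignment_loss_map_upscaled,
                                decode, encode, quantize, vqvae_loss)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


class TestQuantize:
    def test_exact_match_gives_zero_alm(self, rng):
        cb = rng.normal(size=(8, 4))
        idx, q, alm = quantize(cb[3][None, None], cb)
        assert idx[0, 0] == 3 and alm[0, 0] == 0.0

    def test_two_code_hand_case(self):
        cb = np.array([[0.0, 0.0], [1.0, 1.0]])
        idx, q, alm = quantize(np.array([[[0.1, 0.1]]]), cb)
        assert idx[0, 0] == 0
        assert alm[0, 0] == pytest.approx(0.02)
        assert np.allclose(q[0, 0], [0.0, 0.0])

    def test_matches_exhaustive_search(self, rng):
        cb = rng.normal(size=(8, 4))
        feats = rng.normal(size=(10, 10, 4))
        idx, q, alm = quantize(feats, cb)
        for r in range(10):
            for c in range(10):
                d = [np.sum((feats[r, c] - e) ** 2) for e in cb]
                assert idx[r, c] == int(np.argmin(d))
                assert alm[r, c] == pytest.approx(min(d), abs=1e-12)

    def test_tie_broken_by_lowest_index(self):
        cb = np.array([[1.0, 0.0], [-1.0, 0.0]])
        idx, _, _ = quantize(np.array([[[0.0, 0.0]]]), cb)
        assert idx[0, 0] == 0

    def test_idempotent_on_quantized_grid(self, rng):
        cb = rng.normal(size=(6, 3))
        feats = rng.normal(size=(5, 5, 3))
        idx, q, _ = quantize(feats, cb)
        idx2, q2, alm2 = quantize(q, cb)
        assert np.array_equal(idx, idx2)
        assert np.all(alm2 == 0.0)

    def test_alm_zero_iff_feature_equals_code(self, rng):
        cb = rng.normal(size=(4, 3))
        feats = cb[[0, 2]][None]            # exact codes
        _, _, alm = quantize(feats, cb)
        assert np.all(alm == 0.0)
        _, _, alm = quantize(feats + 1e-3, cb)
        assert np.all(alm > 0.0)

    def test_dimension_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="dim"):
            quantize(rng.normal(size=(2, 2, 3)), rng.normal(size=(4, 5)))


class TestLossArithmetic:
    def test_perfect_reconstruction_zero_components(self, rng):
        x = rng.random((8, 8))
        f = rng.normal(size=(2, 2, 4))
        loss = vqvae_loss(x, x, f, f)
        assert loss.reconstruction == 0.0
        assert loss.alignment == 0.0 and loss.commitment == 0.0
        assert loss.total == 0.0

    def test_alignment_equals_commitment(self, rng):
        loss = vqvae_loss(rng.random((4, 4)), rng.random((4, 4)),
                          rng.normal(size=(2, 2, 3)), rng.normal(size=(2, 2, 3)))
        assert loss.alignment == loss.commitment

    def test_matches_hand_computation(self, rng):
        x, xp = rng.random((6, 6)), rng.random((6, 6))
        f, q = rng.normal(size=(3, 3, 4)), rng.normal(size=(3, 3, 4))
        loss = vqvae_loss(x, xp, f, q, commitment_weight=0.25)
        rec = np.abs(x - xp).mean()
        align = ((f - q) ** 2).sum(-1).mean()
        assert loss.reconstruction == pytest.approx(rec, abs=1e-6)
        assert loss.alignment == pytest.approx(align, abs=1e-6)
        assert loss.total == pytest.approx(rec + 1.25 * align, abs=1e-6)

    def test_l2_option(self, rng):
        x, xp = rng.random((4, 4)), rng.random((4, 4))
        f = rng.normal(size=(2, 2, 2))
        loss = vqvae_loss(x, xp, f, f, recon="l2")
        assert loss.reconstruction == pytest.approx(((x - xp) ** 2).mean())


class TestEncodeDecode:
    def test_latent_grid_size_follows_downsampling(self, tiny_vqvae):
        img = np.zeros((32, 32))
        feats = encode(img, tiny_vqvae)
        assert feats.shape == (8, 8, 16)     # one stride stage -> factor 4

    def test_clinical_ratio_arithmetic(self):
        cfg = VqVaeConfig(image_size=480, channels=(16, 32))
        assert cfg.downsample_factor == 8
        assert cfg.latent_size == 60

    def test_indivisible_size_rejected(self, tiny_vqvae):
        with pytest.raises(ValueError, match="divisible"):
            encode(np.zeros((30, 30)), tiny_vqvae)

    def test_encode_deterministic_in_eval_mode(self, tiny_vqvae, rng):
        img = rng.random((32, 32))
        assert np.array_equal(encode(img, tiny_vqvae), encode(img, tiny_vqvae))

    def test_decode_restores_spatial_size(self, tiny_vqvae, rng):
        img = rng.random((32, 32))
        feats = encode(img, tiny_vqvae)
        _, q, _ = quantize(feats, tiny_vqvae.codebook.data)
        out = decode(q, tiny_vqvae)
        assert out.shape == (32, 32) and np.isfinite(out).all()

    def test_decode_shape_mismatch_rejected(self, tiny_vqvae, rng):
        with pytest.raises(ValueError, match="grid"):
            decode(rng.normal(size=(4, 4, 16)), tiny_vqvae)

    def test_roundtrip_tracks_mean_after_training(self, tiny_vqvae, tiny_dataset):
        from octa_anomaly.imgio import read_image
        rec = tiny_dataset.subset("train")[0]
        img = read_image(tiny_dataset.resolve(rec.image))
        feats = encode(img, tiny_vqvae)
        _, q, _ = quantize(feats, tiny_vqvae.codebook.data)
        out = decode(q, tiny_vqvae)
        assert abs(out.mean() - img.mean()) < 0.15


class TestAlmUpscale:
    def test_constant_map_stays_constant(self):
        up = alignment_loss_map_upscaled(np.full((4, 4), 0.3), 32)
        assert up.shape == (32, 32) and np.all(up == 0.3)

    def test_nearest_neighbour_block_replication(self):
        alm = np.array([[1.0, 2.0], [3.0, 4.0]])
        up = alignment_loss_map_upscaled(alm, 4)
        assert np.array_equal(up, np.kron(alm, np.ones((2, 2))))

    def test_max_never_grows(self, rng):
        for _ in range(10):
            alm = rng.random((5, 5))
            up = alignment_loss_map_upscaled(alm, 37)
            assert up.max() <= alm.max()

    def test_target_smaller_than_latent_rejected(self):
        with pytest.raises(ValueError):
            alignment_loss_map_upscaled(np.zeros((8, 8)), 4)


class TestTraining:
    def test_smoke_run_finite_loss(self, tiny_dataset, tiny_vqvae_cfg):
        cfg = dataclasses.replace(tiny_vqvae_cfg, epochs=1)
        model = vqvae.train_vqvae(tiny_dataset, cfg)
        assert np.isfinite(model.train_log[-1]["total"])

    def test_loss_decreases_over_training(self, tiny_vqvae):
        log = tiny_vqvae.train_log
        assert log[-1]["reconstruction"] < log[0]["reconstruction"]

    def test_refuses_diseased_train_record(self, tiny_dataset):
        bad = DatasetManifest(records=list(tiny_dataset.records),
                              root=tiny_dataset.root)
        sick = bad.subset(label="diseased")[0]
        bad.records.append(ManifestRecord(sick.image, sick.vessel_mask,
                                          sick.anomaly_mask, "diseased", "train"))
        with pytest.raises(ValueError, match="healthy"):
            vqvae.train_vqvae(bad, VqVaeConfig(image_size=32))

    def test_checkpoint_roundtrip(self, tiny_vqvae, tmp_path, rng):
        path = tmp_path / "model.npz"
        vqvae.save_vqvae(tiny_vqvae, path)
        loaded = vqvae.load_vqvae(path)
        img = rng.random((32, 32))
        assert np.array_equal(encode(img, tiny_vqvae), encode(img, loaded))
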