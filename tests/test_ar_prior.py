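"""Autoregressive latent prior: causality, normalization, scoring."""

import itertools

import numpy as np
import pytest

from octa_anomaly.ar_prior import (ArConfig, ArPrior, calibrate_t_ar, nll_map,
                                   scan_score, train_ar, load_ar, save_ar)


def _zeroed(cfg: ArConfig) -> ArPrior:
    model = ArPrior(cfg)
    for p in model.parameters():
        p.data = np.zeros_like(p.data)
    return model


class TestNllMap:
    def test_uniform_model_gives_log_k(self):
        model = _zeroed(ArConfig(codebook_size=32, channels=8, n_blocks=1))
        z = np.random.default_rng(0).integers(0, 32, (4, 4))
        assert np.allclose(nll_map(z, model), np.log(32), atol=1e-6)

    def test_cells_sum_to_full_grid_nll(self):
        # probabilities over all 81 possible 2x2 grids with K=3 sum to 1
        model = ArPrior(ArConfig(codebook_size=3, channels=8, n_blocks=2,
                                 rng_seed=1))
        total = sum(np.exp(-nll_map(np.array(v).reshape(2, 2), model).sum())
                    for v in itertools.product(range(3), repeat=4))
        assert total == pytest.approx(1.0, abs=1e-4)

    def test_out_of_range_index_rejected(self):
        model = _zeroed(ArConfig(codebook_size=4, channels=8, n_blocks=1))
        with pytest.raises(ValueError, match="range"):
            nll_map(np.array([[0, 7]]), model)

    @pytest.mark.parametrize("use_attention", [False, True])
    def test_future_flip_leaves_past_nll_bit_identical(self, use_attention):
        rng = np.random.default_rng(3)
        model = ArPrior(ArConfig(codebook_size=8, channels=16, n_blocks=2,
                                 use_attention=use_attention, rng_seed=3))
        for _ in range(10):
            z = rng.integers(0, 8, (6, 6))
            r, c = int(rng.integers(0, 6)), int(rng.integers(0, 6))
            z2 = z.copy()
            z2[r, c] = (z2[r, c] + 1 + int(rng.integers(0, 7))) % 8
            flat = r * 6 + c
            n1, n2 = nll_map(z, model), nll_map(z2, model)
            assert np.array_equal(n1.ravel()[:flat], n2.ravel()[:flat])

    def test_nll_nonnegative(self):
        model = ArPrior(ArConfig(codebook_size=5, channels=8, n_blocks=1,
                                 rng_seed=9))
        z = np.random.default_rng(1).integers(0, 5, (8, 8))
        assert np.all(nll_map(z, model) >= 0.0)


class TestScanScore:
    def test_hand_case(self):
        assert scan_score(np.array([1.0, 8.0, 9.0]), 7.0) == 17.0

    def test_no_cell_above_threshold(self):
        assert scan_score(np.array([1.0, 2.0, 3.0]), 7.0) == 0.0

    def test_zero_threshold_sums_positive_map(self):
        m = np.array([0.5, 1.5, 2.0])
        assert scan_score(m, 0.0) == pytest.approx(4.0)

    def test_monotone_in_cell_values(self):
        rng = np.random.default_rng(0)
        m = rng.random((6, 6)) * 3
        base = scan_score(m, 1.0)
        for _ in range(20):
            m2 = m.copy()
            m2[rng.integers(0, 6), rng.integers(0, 6)] += rng.random()
            assert scan_score(m2, 1.0) >= base

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            scan_score(np.array([1.0]), -1.0)


class TestCalibration:
    def test_linear_interpolation_percentile(self):
        assert calibrate_t_ar(np.arange(1, 101), 95) == pytest.approx(95.05)

    def test_constant_values(self):
        assert calibrate_t_ar([3.3] * 50, 95) == 3.3

    def test_percentile_100_is_max(self):
        assert calibrate_t_ar([1.0, 9.0, 4.0], 100) == 9.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            calibrate_t_ar([])


class TestTraining:
    def test_smoke_epoch_finite(self):
        grids = [np.random.default_rng(i).integers(0, 4, (4, 4))
                 for i in range(6)]
        model = train_ar(grids, ArConfig(codebook_size=4, channels=8,
                                         n_blocks=1, epochs=1, rng_seed=0))
        assert np.isfinite(model.train_log[-1]["cross_entropy"])

    def test_degenerate_dataset_memorized(self):
        grids = [np.full((4, 4), 2)] * 16
        model = train_ar(grids, ArConfig(codebook_size=4, channels=16,
                                         n_blocks=1, epochs=250, rng_seed=0))
        assert nll_map(grids[0], model).mean() < 0.05

    def test_heldout_healthy_beats_shuffled(self):
        # structured grids: vertical stripes with jitter; shuffled copies
        # destroy the structure and should look less likely
        rng = np.random.default_rng(5)
        def grid():
            base = np.tile(np.arange(6) % 3, (6, 1))
            flip = rng.random((6, 6)) < 0.1
            return np.where(flip, rng.integers(0, 3, (6, 6)), base)
        train = [grid() for _ in range(40)]
        model = train_ar(train, ArConfig(codebook_size=3, channels=16,
                                         n_blocks=2, epochs=60, rng_seed=0))
        held = [grid() for _ in range(10)]
        held_nll = np.mean([nll_map(z, model).mean() for z in held])
        shuf_nll = np.mean([nll_map(rng.permutation(z.ravel()).reshape(6, 6),
                                    model).mean() for z in held])
        assert held_nll < shuf_nll

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            train_ar([], ArConfig(codebook_size=4))

    def test_checkpoint_roundtrip(self, tmp_path):
        grids = [np.random.default_rng(i).integers(0, 4, (4, 4))
                 for i in range(4)]
        model = train_ar(grids, ArConfig(codebook_size=4, channels=8,
                                         n_blocks=1, epochs=2, rng_seed=0))
        save_ar(model, tmp_path / "ar.npz")
        loaded = load_ar(tmp_path / "ar.npz")
        z = grids[0]
        assert np.array_equal(nll_map(z, model), nll_map(z, loaded))
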