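import numpy as np
import pytest

from nanoquant.segmentation import (
    ModelEnsemble,
    ThresholdModel,
    TrainConfig,
    UNetConfig,
    build_model,
    normalize_patch,
    predict_patch,
    predict_volume,
    train,
)
from nanoquant.unet import dice_ce_loss_and_grad, softmax_fg
from nanoquant.volume_io import plan_tiles


class TestNormalizePatch:
    def test_direct_formula(self):
        np.testing.assert_allclose(
            normalize_patch(np.array([[[2.0, 4.0, 6.0]]])), [[[0.0, 0.5, 1.0]]]
        )

    def test_constant_patch_maps_to_zero(self):
        out = normalize_patch(np.full((2, 2, 2), 7.0))
        assert (out == 0).all()

    def test_unit_range_is_fixed_point(self):
        rng = np.random.default_rng(0)
        patch = rng.random((3, 3, 3))
        patch.flat[0] = 0.0
        patch.flat[-1] = 1.0
        np.testing.assert_allclose(normalize_patch(patch), patch, rtol=1e-6)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            normalize_patch(np.empty((0, 2, 2)))


class TestUNetConfig:
    def test_decoder_is_one_less_than_encoder(self):
        cfg = UNetConfig()
        assert cfg.encoder_levels == 6 and cfg.decoder_levels == 5

    def test_patch_shape_divisibility_enforced(self):
        with pytest.raises(ValueError):
            UNetConfig(encoder_levels=3, patch_shape=(30, 32, 32))

    def test_tiny_preset(self):
        cfg = UNetConfig.tiny()
        assert cfg.encoder_levels == 3 and cfg.base_channels == 8


class TestBuildModel:
    def test_output_shape_contract_tiny(self):
        model = build_model(UNetConfig.tiny(), seed=0)
        x = np.zeros((1, 1, 16, 16, 16), dtype=np.float32)
        assert model.forward(x, keep=False).shape == (1, 2, 16, 16, 16)

    def test_output_shape_contract_full_depth(self):
        # 6 encoder levels need divisibility by 32; 2 base channels keep it light
        cfg = UNetConfig(encoder_levels=6, base_channels=2, patch_shape=(32, 32, 32))
        model = build_model(cfg, seed=0)
        x = np.zeros((1, 1, 32, 32, 32), dtype=np.float32)
        assert model.forward(x, keep=False).shape == (1, 2, 32, 32, 32)

    def test_indivisible_input_rejected(self):
        model = build_model(UNetConfig.tiny(), seed=0)
        with pytest.raises(ValueError, match="divisible"):
            model.forward(np.zeros((1, 1, 15, 16, 16), dtype=np.float32), keep=False)

    def test_deterministic_initialization(self):
        a = build_model(UNetConfig.tiny(), seed=7)
        b = build_model(UNetConfig.tiny(), seed=7)
        for (pa, _), (pb, _) in zip(a.parameters(), b.parameters()):
            np.testing.assert_array_equal(pa, pb)
        c = build_model(UNetConfig.tiny(), seed=8)
        assert any(
            not np.array_equal(pa, pc)
            for (pa, _), (pc, _) in zip(a.parameters(), c.parameters())
        )


class TestLoss:
    def test_perfect_prediction_drives_loss_to_zero(self):
        target = (np.random.default_rng(0).random((1, 4, 4, 4)) < 0.3).astype(np.float32)
        logits = np.zeros((1, 2, 4, 4, 4), dtype=np.float32)
        logits[:, 1] = np.where(target > 0, 50.0, -50.0)
        logits[:, 0] = -logits[:, 1]
        total, dice_loss, ce, _ = dice_ce_loss_and_grad(logits, target)
        assert ce == pytest.approx(0.0, abs=1e-8)
        assert dice_loss == pytest.approx(0.0, abs=1e-5)
        assert total == pytest.approx(0.0, abs=1e-5)

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(1)
        logits = rng.standard_normal((1, 2, 2, 2, 2)).astype(np.float64)
        target = (rng.random((1, 2, 2, 2)) < 0.5).astype(np.float32)
        _, _, _, grad = dice_ce_loss_and_grad(logits, target)
        eps = 1e-5
        for idx in [(0, 1, 0, 0, 0), (0, 0, 1, 1, 1), (0, 1, 1, 0, 1)]:
            lo = logits.copy(); lo[idx] -= eps
            hi = logits.copy(); hi[idx] += eps
            f_lo, _, _, _ = dice_ce_loss_and_grad(lo, target)
            f_hi, _, _, _ = dice_ce_loss_and_grad(hi, target)
            assert grad[idx] == pytest.approx((f_hi - f_lo) / (2 * eps), rel=1e-3, abs=1e-8)


class TestTrain:
    def _pairs(self, n, shape=(16, 16, 16), seed=0):
        rng = np.random.default_rng(seed)
        pairs = []
        for _ in range(n):
            x = rng.uniform(50, 100, size=shape).astype(np.float32)
            y = np.zeros(shape, dtype=np.uint8)
            z, yy, xx = rng.integers(3, 13, size=3)
            x[z - 2:z + 2, yy - 2:yy + 2, xx - 2:xx + 2] += 400
            y[z - 2:z + 2, yy - 2:yy + 2, xx - 2:xx + 2] = 1
            pairs.append((x, y))
        return pairs

    CFG = UNetConfig(encoder_levels=2, base_channels=4, patch_shape=(16, 16, 16))

    def test_fewer_pairs_than_folds_rejected(self):
        with pytest.raises(ValueError, match="folds"):
            train(self._pairs(2), self.CFG, TrainConfig(folds=5, epochs=1,
                                                        crop_shape=(16, 16, 16)))

    def test_non_binary_gt_rejected(self):
        pairs = self._pairs(2)
        pairs[0] = (pairs[0][0], pairs[0][1] * 3)
        with pytest.raises(ValueError, match="binary"):
            train(pairs, self.CFG, TrainConfig(folds=2, epochs=1, crop_shape=(16, 16, 16)))

    def test_each_pair_validates_exactly_once(self):
        from nanoquant.segmentation import _fold_split

        rng = np.random.default_rng(0)
        folds = _fold_split(5, 5, rng)
        seen = sorted(int(i) for part in folds for i in part)
        assert seen == [0, 1, 2, 3, 4]
        assert all(len(p) == 1 for p in folds)

    def test_training_is_deterministic(self):
        pairs = self._pairs(4)
        tcfg = TrainConfig(folds=2, epochs=2, learning_rate=0.01, momentum=0.9,
                           crop_shape=(16, 16, 16), seed=5)
        a, loga = train(pairs, self.CFG, tcfg)
        b, logb = train(pairs, self.CFG, tcfg)
        assert loga == logb
        for ma, mb in zip(a.members, b.members):
            for (pa, _), (pb, _) in zip(ma.parameters(), mb.parameters()):
                np.testing.assert_array_equal(pa, pb)

    def test_overfit_single_pair(self):
        # a replicated bright-cube pair must be learnable almost perfectly
        from nanoquant.evaluation import voxel_dice

        pairs = self._pairs(1, seed=3) * 2
        tcfg = TrainConfig(folds=2, epochs=120, learning_rate=0.03, momentum=0.9,
                           crop_shape=(16, 16, 16), augment=False, seed=1)
        ens, _ = train(pairs, self.CFG, tcfg)
        pred = predict_patch(ens, pairs[0][0])
        assert voxel_dice(pred, pairs[0][1] > 0) >= 0.95


class TestPredict:
    def test_ensemble_of_identical_members_equals_single(self):
        cfg = UNetConfig.tiny((16, 16, 16))
        m = build_model(cfg, seed=0)
        single = ModelEnsemble(members=[m], config=cfg)
        triple = ModelEnsemble(members=[m, m, m], config=cfg)
        x = np.random.default_rng(0).uniform(0, 255, (16, 16, 16)).astype(np.float32)
        np.testing.assert_array_equal(single.predict(x), triple.predict(x))

    def test_constant_patch_deterministic(self):
        cfg = UNetConfig.tiny((16, 16, 16))
        ens = ModelEnsemble(members=[build_model(cfg, seed=0)], config=cfg)
        x = np.full((16, 16, 16), 42.0, dtype=np.float32)
        a = ens.predict(x)
        b = ens.predict(x)
        np.testing.assert_array_equal(a, b)

    def test_tie_probability_counts_as_foreground(self):
        class Half:
            config = UNetConfig.tiny()

            def predict(self, patch):
                return np.full(patch.shape, 0.5) >= 0.5

        assert predict_patch(Half(), np.zeros((4, 4, 4))).all()

    def test_affine_intensity_invariance(self):
        cfg = UNetConfig.tiny((16, 16, 16))
        ens = ModelEnsemble(members=[build_model(cfg, seed=0)], config=cfg)
        rng = np.random.default_rng(4)
        x = rng.uniform(10, 200, (16, 16, 16)).astype(np.float64)
        base = ens.predict(x)
        np.testing.assert_array_equal(ens.predict(3.0 * x + 17.0), base)

    def test_nondivisible_patch_padded_and_cropped(self):
        cfg = UNetConfig.tiny((16, 16, 16))
        ens = ModelEnsemble(members=[build_model(cfg, seed=0)], config=cfg)
        x = np.random.default_rng(0).uniform(0, 1, (10, 13, 9)).astype(np.float32)
        assert ens.predict(x).shape == (10, 13, 9)

    def test_empty_patch_rejected(self):
        with pytest.raises(ValueError):
            predict_patch(ThresholdModel(1.0), np.empty((0, 2, 2)))


class TestPredictVolume:
    def test_stub_tiled_equals_full_threshold(self):
        rng = np.random.default_rng(0)
        vol = rng.uniform(0, 255, (20, 17, 13)).astype(np.float32)
        stub = ThresholdModel(128.0)
        for maxp in [(7, 5, 13), (20, 17, 13), (4, 4, 4)]:
            grid = plan_tiles(vol.shape, maxp, halo=(0, 0, 0))
            np.testing.assert_array_equal(predict_volume(stub, vol, grid), vol >= 128.0)

    def test_halo_does_not_change_local_operator(self):
        rng = np.random.default_rng(1)
        vol = rng.uniform(0, 255, (12, 12, 12)).astype(np.float32)
        stub = ThresholdModel(100.0)
        grid = plan_tiles(vol.shape, (5, 5, 5), halo=(3, 3, 3))
        np.testing.assert_array_equal(predict_volume(stub, vol, grid), vol >= 100.0)

    def test_tile_order_independence(self):
        rng = np.random.default_rng(2)
        vol = rng.uniform(0, 255, (12, 12, 12)).astype(np.float32)
        grid = plan_tiles(vol.shape, (6, 6, 6))
        a = predict_volume(ThresholdModel(128), vol, grid)
        grid.patches = grid.patches[::-1]
        b = predict_volume(ThresholdModel(128), vol, grid)
        np.testing.assert_array_equal(a, b)

    def test_grid_shape_mismatch_rejected(self):
        grid = plan_tiles((4, 4, 4), (4, 4, 4))
        with pytest.raises(ValueError):
            predict_volume(ThresholdModel(1), np.zeros((5, 4, 4)), grid)

    def test_all_background_phantom_stub_negative_control(self):
        from nanoquant.phantom import PhantomConfig, generate_phantom

        cfg = PhantomConfig(shape=(24, 48, 48), particles_per_organ=0, noise_sigma=3.0)
        sample = generate_phantom(cfg, seed=0)
        # threshold far above every background level
        stub = ThresholdModel(400.0)
        grid = plan_tiles(sample.volume.shape, (16, 32, 32))
        mask = predict_volume(stub, sample.volume, grid)
        assert mask.mean() < 0.01
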