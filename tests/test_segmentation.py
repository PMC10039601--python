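"""Segmentation: dice coefficient, U-net contract, training behavior."""

import numpy as np
import pytest

import sellamorph as sm
from sellamorph.segmentation import dice_coefficient


def shift(mask, dy, dx):
    return np.roll(mask, (dy, dx), axis=(0, 1))


class TestDiceCoefficient:
    def test_identical_nonempty(self):
        m = np.zeros((20, 20), dtype=bool)
        m[5:10, 5:10] = True
        assert dice_coefficient(m, m) == pytest.approx(1.0)

    def test_disjoint_masks(self):
        a = np.zeros((20, 20), dtype=bool)
        b = np.zeros((20, 20), dtype=bool)
        a[2:5, 2:5] = True
        b[10:13, 10:13] = True
        assert dice_coefficient(a, b) == pytest.approx(0.0, abs=1e-6)

    def test_half_overlap_case(self):
        # |A| = |B| = 4, |A n B| = 2 -> 2*2 / (4+4) = 0.5
        a = np.zeros((10, 10), dtype=bool)
        b = np.zeros((10, 10), dtype=bool)
        a[0, 0:4] = True
        b[0, 2:6] = True
        assert dice_coefficient(a, b) == pytest.approx(0.5, abs=1e-6)

    def test_symmetry_and_translation_invariance(self):
        rng = np.random.default_rng(12)
        for _ in range(10):
            a = rng.random((32, 32)) > 0.6
            b = rng.random((32, 32)) > 0.6
            assert dice_coefficient(a, b) == dice_coefficient(b, a)
            # wrap-around translation preserves overlap structure
            assert dice_coefficient(shift(a, 3, 5), shift(b, 3, 5)) == pytest.approx(
                dice_coefficient(a, b)
            )

    def test_both_empty_is_perfect_agreement(self):
        empty = np.zeros((8, 8), dtype=bool)
        assert dice_coefficient(empty, empty) == pytest.approx(1.0)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            dice_coefficient(np.zeros((4, 4), bool), np.zeros((5, 5), bool))

    def test_bounds_on_random_masks(self):
        rng = np.random.default_rng(13)
        for _ in range(20):
            a = rng.random((16, 16)) > rng.random()
            b = rng.random((16, 16)) > rng.random()
            assert 0.0 <= dice_coefficient(a, b) <= 1.0


class TestUNetContract:
    def test_reduced_model_io_shapes(self):
        model = sm.build_unet(sm.REDUCED_UNET, seed=0)
        x = np.zeros((1, 128, 128, 1), np.float32)
        assert model.forward(x).shape == (1, 128, 128, 1)

    def test_full_profile_constructs(self):
        model = sm.build_unet(sm.UNetConfig(depth=4, base_channels=64, in_size=400))
        # 400 = 2^4 * 25, so four pooling levels fit exactly
        assert model.config.in_size == 400

    def test_forward_deterministic(self):
        model = sm.build_unet(sm.UNetConfig(depth=2, base_channels=4, in_size=32))
        x = np.random.default_rng(0).random((2, 32, 32, 1)).astype(np.float32)
        np.testing.assert_array_equal(model.forward(x), model.forward(x))

    def test_same_seed_same_weights(self):
        cfg = sm.UNetConfig(depth=2, base_channels=4, in_size=32)
        m1, m2 = sm.build_unet(cfg, seed=5), sm.build_unet(cfg, seed=5)
        for p1, p2 in zip(m1.state_arrays(), m2.state_arrays()):
            np.testing.assert_array_equal(p1, p2)

    def test_incompatible_in_size_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            sm.UNetConfig(depth=4, base_channels=8, in_size=100)

    def test_wrong_input_size_rejected(self):
        model = sm.build_unet(sm.UNetConfig(depth=2, base_channels=4, in_size=32))
        with pytest.raises(ValueError, match="in_size"):
            model.forward(np.zeros((1, 64, 64, 1), np.float32))

    def test_checkpoint_roundtrip(self, tmp_path):
        cfg = sm.UNetConfig(depth=2, base_channels=4, in_size=32)
        model = sm.build_unet(cfg, seed=3)
        path = tmp_path / "ckpt.npz"
        model.save(path)
        loaded = sm.UNet.load(path)
        x = np.random.default_rng(1).random((1, 32, 32, 1)).astype(np.float32)
        np.testing.assert_array_equal(model.forward(x), loaded.forward(x))


@pytest.fixture(scope="module")
def tiny_pair():
    samp = sm.make_sample(5, canvas_size=32)
    return samp.image, samp.mask


class TestTraining:

    def test_single_epoch_single_record(self, tiny_pair):
        img, mask = tiny_pair
        ucfg = sm.UNetConfig(depth=2, base_channels=4, in_size=32)
        tcfg = sm.TrainConfig(learning_rate=1e-4, batch_size=2, epochs=1, seed=0)
        _, hist = sm.train([img] * 4, [mask] * 4, ucfg, tcfg,
                           val_images=[img], val_masks=[mask])
        assert hist.epoch == [1]
        assert len(hist.val_dice) == 1
        assert 0.0 <= hist.val_dice[0] <= 1.0

    def test_mismatched_pairs_rejected(self, tiny_pair):
        img, mask = tiny_pair
        ucfg = sm.UNetConfig(depth=2, base_channels=4, in_size=32)
        tcfg = sm.TrainConfig(epochs=1)
        with pytest.raises(ValueError):
            sm.train([img, img], [mask], ucfg, tcfg)
        with pytest.raises(ValueError):
            sm.train([img], [mask[:16, :16]], ucfg, tcfg)

    def test_training_reproducible_under_seed(self, tiny_pair):
        img, mask = tiny_pair
        ucfg = sm.UNetConfig(depth=2, base_channels=4, in_size=32)
        tcfg = sm.TrainConfig(learning_rate=1e-4, batch_size=2, epochs=2, seed=7)
        _, h1 = sm.train([img] * 6, [mask] * 6, ucfg, tcfg)
        _, h2 = sm.train([img] * 6, [mask] * 6, ucfg, tcfg)
        assert h1.val_loss == h2.val_loss
        assert h1.val_dice == h2.val_dice
        assert h1.train_loss == h2.train_loss

    def test_overfit_reaches_near_perfect_dice(self, overfit_run):
        model, samp, hist = overfit_run
        assert hist.best_val_dice >= 0.99

    def test_predict_on_memorized_pair(self, overfit_run, tiny_pipeline_config):
        from sellamorph.pipeline import network_input

        model, samp, _ = overfit_run
        pred = sm.predict_mask(model, network_input(samp.image, tiny_pipeline_config))
        assert dice_coefficient(pred, samp.mask) >= 0.99

    def test_inference_deterministic(self, overfit_run, tiny_pipeline_config):
        from sellamorph.pipeline import network_input

        model, samp, _ = overfit_run
        x = network_input(samp.image, tiny_pipeline_config)
        np.testing.assert_array_equal(sm.predict_mask(model, x),
                                      sm.predict_mask(model, x))

    def test_threshold_one_gives_empty_mask(self, overfit_run, tiny_pipeline_config):
        from sellamorph.pipeline import network_input

        model, samp, _ = overfit_run
        x = network_input(samp.image, tiny_pipeline_config)
        assert not sm.predict_mask(model, x, threshold=1.0).any()
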