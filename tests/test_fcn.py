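"""Network construction, training behaviour, inference and metrics."""

import numpy as np
import pytest

from somaquant.fcn import (FCNConfig, TrainedModel, build_fcn, evaluate,
                           predict, split_dataset, train)
from somaquant.imaging import LabelMask, MultiChannelImage

SMALL = dict(layer_widths=(4, 8, 4, 4), reduction_factor=4)


def small_config(**kw):
    base = dict(n_classes=2, patch_size=15, kernel_sizes=(5, 5, 1, 5, 3),
                max_epochs=5, patience=3, seed=0, **SMALL)
    base.update(kw)
    return FCNConfig(**base)


class TestConfig:
    def test_even_patch_size_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            small_config(patch_size=16)

    def test_receptive_field_must_equal_patch_size(self):
        with pytest.raises(ValueError, match="receptive field"):
            small_config(kernel_sizes=(3, 3, 1, 3, 3))

    def test_reduction_factor_must_divide_width(self):
        with pytest.raises(ValueError, match="reduction_factor"):
            small_config(layer_widths=(4, 6, 4, 4))

    def test_default_receptive_field_is_63(self):
        cfg = FCNConfig()
        assert sum(k - 1 for k in cfg.kernel_sizes) + 1 == 63
        assert cfg.patch_size == 63


class TestForward:
    def test_output_resolution_equals_input(self, rng):
        net = build_fcn(small_config(), in_channels=2)
        probs = net.predict_proba(rng.random((128, 96, 2)))
        assert probs.shape == (128, 96, 2)

    def test_probabilities_sum_to_one(self, rng):
        net = build_fcn(small_config(n_classes=3), in_channels=1)
        probs = net.predict_proba(rng.random((20, 25, 1)))
        np.testing.assert_allclose(probs.sum(axis=2), 1.0, atol=1e-6)

    def test_receptive_field_radius_31_with_default_kernels(self, rng):
        # default kernel stack: perturbing a pixel farther than 31 px from
        # the centre cannot change the centre's output
        cfg = FCNConfig(layer_widths=(2, 4, 4, 4), reduction_factor=4, seed=1)
        net = build_fcn(cfg, in_channels=1)
        x = rng.random((65, 65, 1))
        base = net.predict_proba(x)[32, 32]
        far = x.copy()
        far[0, 0, 0] += 10.0  # distance 32 > 31
        np.testing.assert_allclose(net.predict_proba(far)[32, 32], base,
                                   atol=1e-10)
        near = x.copy()
        near[32, 2, 0] += 10.0  # distance 30 <= 31
        assert not np.allclose(net.predict_proba(near)[32, 32], base)

    def test_tiled_prediction_matches_whole_image_in_interior(self, rng):
        # convolutional equivariance: predicting a tile with enough context
        # reproduces the whole-image prediction in the tile interior
        cfg = small_config(seed=2)
        net = build_fcn(cfg, in_channels=1)
        x = rng.random((64, 64, 1))
        whole = net.predict_proba(x)
        r = cfg.receptive_radius  # 7
        tile = x[16 - r:48 + r, 16 - r:48 + r]
        tiled = net.predict_proba(tile)
        np.testing.assert_allclose(tiled[2 * r:-2 * r, 2 * r:-2 * r],
                                   whole[16 + r:48 - r, 16 + r:48 - r],
                                   atol=1e-10)


class TestSplitDataset:
    def make_items(self, n):
        return [(np.zeros((20, 20, 1)), np.zeros((20, 20), int))
                for _ in range(n)]

    def test_eighty_twenty_split_of_ten_images(self):
        train_set, test_set = split_dataset(self.make_items(10), 0.8, seed=0)
        assert len(train_set) == 8 and len(test_set) == 2

    def test_same_seed_gives_identical_partition(self):
        items = [(np.full((4, 4, 1), i), np.zeros((4, 4), int))
                 for i in range(9)]
        a_train, a_test = split_dataset(items, 0.8, seed=5)
        b_train, b_test = split_dataset(items, 0.8, seed=5)
        for (xa, _), (xb, _) in zip(a_train + a_test, b_train + b_test):
            np.testing.assert_array_equal(xa, xb)

    def test_fraction_one_warns_about_empty_test_set(self):
        with pytest.warns(UserWarning, match="empty test"):
            train_set, test_set = split_dataset(self.make_items(4), 1.0, 0)
        assert len(train_set) == 4 and len(test_set) == 0

    def test_fewer_than_two_images_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            split_dataset(self.make_items(1))


class TestTrain:
    def test_all_background_collapses_to_background(self, rng):
        images = [(rng.random((24, 24, 1)) * 0.05, np.zeros((24, 24), int))
                  for _ in range(4)]
        cfg = small_config(max_epochs=8)
        net = build_fcn(cfg, in_channels=1)
        trained = train(net, images[:3], images[3:], cfg)
        assert trained.log[-1]["test_pixel_error"] == 0.0
        mask, _ = predict(trained, images[0][0])
        assert np.all(mask.labels == 0)

    def test_overfits_tiny_easy_dot_set(self):
        # capacity check: bright blobs on dark background learn to sub-1%
        # training pixel error
        rng = np.random.default_rng(7)
        images = []
        for _ in range(5):
            y = np.zeros((32, 32), int)
            x = rng.normal(0.05, 0.01, (32, 32, 1))
            for _ in range(6):
                r, c = rng.integers(3, 29, 2)
                y[r - 1:r + 2, c - 1:c + 2] = 1
                x[r - 1:r + 2, c - 1:c + 2, 0] = 0.8
            images.append((np.clip(x, 0, 1), y))
        cfg = small_config(max_epochs=60, patience=60, class_weighting=True,
                           layer_widths=(8, 16, 8, 8))
        net = build_fcn(cfg, in_channels=1)
        trained = train(net, images, [], cfg)
        assert min(l["train_pixel_error"] for l in trained.log) < 0.01

    def test_stop_epoch_attains_minimum_heldout_error(self, cell_model):
        errs = [l["test_pixel_error"] for l in cell_model.log]
        assert cell_model.stop_epoch == int(np.argmin(errs)) + 1

    def test_empty_train_set_rejected(self):
        cfg = small_config()
        with pytest.raises(ValueError, match="empty train"):
            train(build_fcn(cfg, 1), [], [], cfg)


class TestPredict:
    def test_prediction_is_argmax_of_probability_map(self, cell_model, rng):
        img = rng.random((40, 40, 3))
        mask, probs = predict(cell_model, img)
        np.testing.assert_array_equal(mask.labels, probs.argmax(axis=2))

    def test_channel_mismatch_rejected(self, cell_model, rng):
        with pytest.raises(ValueError, match="channels"):
            predict(cell_model, rng.random((20, 20, 2)))

    def test_excluded_channel_blinds_the_network(self, cell_model, rng):
        base = MultiChannelImage(rng.random((30, 30, 3)) * 0.2,
                                 ["marker", "nuclear", "target"])
        altered = base.copy()
        altered.pixels[:, :, 2] = 0.9  # arbitrary target-channel content
        m1, _ = predict(cell_model, base, excluded_channel="target")
        m2, _ = predict(cell_model, altered, excluded_channel="target")
        np.testing.assert_array_equal(m1.labels, m2.labels)


class TestEvaluate:
    def test_perfect_prediction(self, rng):
        y = rng.integers(0, 3, (30, 30))
        m = evaluate(LabelMask(y, class_names=["a", "b", "c"]),
                     LabelMask(y.copy(), class_names=["a", "b", "c"]))
        assert m.pixel_error == 0.0
        np.testing.assert_allclose(m.specificity[~np.isnan(m.specificity)],
                                   100.0)
        np.testing.assert_allclose(m.sensitivity[~np.isnan(m.sensitivity)],
                                   100.0)

    def test_hand_computed_confusion_rates(self):
        # 10x10, class 1: TP = 10, TN = 85, FP = 5, FN = 0 pixels
        truth = np.zeros((10, 10), int)
        truth.ravel()[:10] = 1
        pred = truth.copy()
        pred.ravel()[10:15] = 1  # 5 false positives
        m = evaluate(pred, truth, n_classes=2)
        assert m.tp[1] == pytest.approx(10.0)
        assert m.fp[1] == pytest.approx(5.0)
        assert m.fn[1] == pytest.approx(0.0)
        assert m.tn[1] == pytest.approx(85.0)
        assert m.specificity[1] == pytest.approx(100 * 85 / 90)
        assert m.sensitivity[1] == pytest.approx(100.0)
        assert m.pixel_error == pytest.approx(5.0)

    def test_rates_sum_to_hundred_per_class(self, rng):
        pred = rng.integers(0, 4, (25, 25))
        truth = rng.integers(0, 4, (25, 25))
        m = evaluate(pred, truth, n_classes=4)
        np.testing.assert_allclose(m.tp + m.tn + m.fp + m.fn, 100.0)

    def test_absent_class_metrics_are_nan_not_zero(self):
        pred = np.zeros((5, 5), int)
        truth = np.zeros((5, 5), int)
        m = evaluate(pred, truth, n_classes=2)
        assert np.isnan(m.sensitivity[1])  # class 1 never occurs

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            evaluate(np.zeros((4, 4), int), np.zeros((5, 5), int))


class TestSerialization:
    def test_checkpoint_roundtrip_preserves_predictions(self, cell_model,
                                                        tmp_path, rng):
        path = tmp_path / "model.npz"
        cell_model.save(path)
        again = TrainedModel.load(path)
        x = rng.random((30, 30, 3))
        np.testing.assert_array_equal(
            predict(cell_model, x)[1], predict(again, x)[1])
        assert again.class_names == cell_model.class_names
        assert again.stop_epoch == cell_model.stop_epoch


class TestDotTaskQuality:
    def test_dot_sensitivity_above_85_percent(self, cell_model):
        """At convergence the rare dot class is detected with high
        sensitivity on held-out synthetic fields."""
        from conftest import CELL_CLASSES, cell_field_pairs
        triples = cell_field_pairs(2, seed=77)
        preds = [predict(cell_model, img)[0] for img, _, _ in triples]
        m = evaluate(preds, [sem for _, sem, _ in triples])
        assert m.sensitivity[CELL_CLASSES.index("dot")] > 85.0
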