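"""Weight maps, augmentation, network mechanics and the Dice metric."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from podometry.segmentation import (AugmentConfig, EncoderDecoder,
                                    SegmentationModel, TrainConfig,
                                    WeightMapParams, augment, dice,
                                    load_model, make_weight_map, predict,
                                    save_model, split_scenes, train,
                                    weighted_bce_with_logits)
from podometry.segmentation.augment import flip_horizontal
from podometry.synthetic import SceneGroundTruth


def _blob_mask(shape, centers, radius):
    mask = np.zeros(shape, dtype=np.int32)
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    for label, (r, c) in enumerate(centers, start=1):
        mask[(yy - r) ** 2 + (xx - c) ** 2 <= radius**2] = label
    return mask


class TestWeightMap:
    def test_single_object_has_no_border_term(self):
        mask = _blob_mask((64, 64), [(32, 32)], 6)
        w = make_weight_map(mask, WeightMapParams(class_balance=False))
        assert np.allclose(w, 1.0)

    def test_border_term_matches_formula(self):
        # two single-pixel objects; at a pixel with d1=1, d2=2 the border
        # term is w0*exp(-(1+2)^2/(2*sigma^2)) = 10*exp(-9/50) ~ 8.353
        mask = np.zeros((32, 32), dtype=np.int32)
        mask[16, 10] = 1
        mask[16, 13] = 2
        w = make_weight_map(mask, WeightMapParams(w0=10.0, sigma=5.0,
                                                  class_balance=False))
        p = w[16, 11]  # d1 = 1 (to label 1), d2 = 2 (to label 2)
        assert p == pytest.approx(1.0 + 10.0 * math.exp(-9.0 / 50.0), rel=1e-9)
        assert 10.0 * math.exp(-9.0 / 50.0) == pytest.approx(8.353, abs=5e-4)

    def test_zero_separation_gives_full_w0(self):
        mask = np.zeros((16, 16), dtype=np.int32)
        mask[8, 4] = 1
        mask[8, 5] = 2
        w = make_weight_map(mask, WeightMapParams(w0=10.0, class_balance=False))
        # on an object pixel d1=0, d2=1 -> term 10*exp(-1/50); the
        # theoretical d1=d2=0 limit is exp(0) -> exactly w0
        assert w.max() <= 1.0 + 10.0
        assert w[8, 4] == pytest.approx(1.0 + 10.0 * math.exp(-1.0 / 50.0))

    def test_weight_at_least_class_balance_floor(self):
        mask = _blob_mask((64, 64), [(20, 20), (40, 44)], 5)
        params = WeightMapParams()
        w = make_weight_map(mask, params)
        fg = mask > 0
        floor = np.where(fg, 0.5 / fg.mean(), 0.5 / (1 - fg.mean()))
        assert np.all(w >= floor - 1e-12)

    def test_border_term_monotone_in_distance_sum(self):
        mask = np.zeros((40, 40), dtype=np.int32)
        mask[20, 5] = 1
        mask[20, 34] = 2
        w = make_weight_map(mask, WeightMapParams(class_balance=False))
        # moving along the row away from the midpoint increases d1+d2
        row = w[20, 6:34]
        mid = len(row) // 2
        assert row[mid] == row.max() == pytest.approx(row[mid])
        assert np.all(np.diff(row[mid:]) <= 1e-12)


class TestAugment:
    def test_disabled_is_identity(self, rng):
        img = rng.random((32, 32))
        mask = (img > 0.5).astype(np.int32)
        out_img, out_mask = augment(img, mask, AugmentConfig(enabled=False), 1)
        assert np.array_equal(out_img, img)
        assert np.array_equal(out_mask, mask)

    def test_seed_determinism(self, rng):
        img = rng.random((32, 32))
        mask = (img > 0.6).astype(np.int32)
        a = augment(img, mask, AugmentConfig(), 42)
        b = augment(img, mask, AugmentConfig(), 42)
        assert np.array_equal(a[0], b[0])
        assert np.array_equal(a[1], b[1])

    def test_horizontal_flip_is_involution(self, rng):
        img = rng.random((16, 24))
        mask = (img > 0.5).astype(np.int32)
        i2, m2 = flip_horizontal(*flip_horizontal(img, mask))
        assert np.array_equal(i2, img)
        assert np.array_equal(m2, mask)

    def test_label_set_preserved(self, rng):
        img = rng.random((64, 64))
        mask = _blob_mask((64, 64), [(20, 20), (44, 40)], 7)
        cfg = AugmentConfig(elastic_alpha=4.0)
        for seed in range(6):
            _, out = augment(img, mask, cfg, seed)
            assert set(np.unique(out)) <= set(np.unique(mask))


class TestNetwork:
    def test_gradients_match_finite_differences(self, rng):
        net = EncoderDecoder(base_channels=2, seed=1)
        x = rng.normal(size=(1, 1, 8, 8))
        y = (rng.random((1, 1, 8, 8)) > 0.5).astype(float)
        w = rng.random((1, 1, 8, 8)) + 0.5

        def loss():
            return weighted_bce_with_logits(net.forward(x), y, w)

        _, d = loss()
        net.backward(d)
        params = net.params()
        for pi in (0, 5, len(params) - 1):
            p, gname, owner = params[pi]
            g = getattr(owner, gname)
            idx = tuple(rng.integers(0, s) for s in p.shape)
            eps = 1e-6
            orig = p[idx]
            p[idx] = orig + eps
            lp, _ = loss()
            p[idx] = orig - eps
            lm, _ = loss()
            p[idx] = orig
            assert g[idx] == pytest.approx((lp - lm) / (2 * eps), rel=1e-4,
                                           abs=1e-10)

    def test_probabilities_in_unit_interval_and_shape(self, rng):
        net = EncoderDecoder(base_channels=2, seed=0)
        img = rng.random((50, 61))  # not multiples of 4: reflect-padded
        proba = net.predict_proba(img)
        assert proba.shape == img.shape
        assert proba.min() >= 0.0 and proba.max() <= 1.0

    def test_threshold_is_idempotent_on_binary_grid(self):
        proba = np.array([[0.0, 1.0], [1.0, 0.0]])
        assert np.array_equal(proba >= 0.5, (proba >= 0.5) >= 0.5)

    def test_checkpoint_roundtrip(self, tmp_path, rng):
        net = EncoderDecoder(base_channels=2, seed=3)
        model = SegmentationModel(net=net, task="tuft", prob_threshold=0.5,
                                  config=TrainConfig())
        save_model(model, tmp_path / "ckpt")
        loaded = load_model(tmp_path / "ckpt")
        img = rng.random((32, 32))
        assert np.array_equal(net.predict_proba(img),
                              loaded.net.predict_proba(img))
        assert loaded.task == "tuft"


class TestTraining:
    @staticmethod
    def _constant_scenes(n, value=0):
        rng = np.random.default_rng(0)
        scenes = []
        for _ in range(n):
            img = rng.random((128, 128)) * 0.1
            empty = np.zeros((128, 128), dtype=np.int32)
            scenes.append(SceneGroundTruth(
                image_wt1=img, image_nephrin=img, tuft_mask=empty,
                nuclei_mask=empty, per_glomerulus=[]))
        return scenes

    def test_training_on_empty_masks_predicts_background(self):
        scenes = self._constant_scenes(4)
        cfg = TrainConfig(epochs=3, crops_per_scene=4, base_channels=4, seed=0)
        model = train(scenes, "nuclei", cfg)
        _, mask = predict(model, scenes[0].image_wt1)
        assert mask.mean() < 0.01

    def test_training_is_reproducible(self, tiny_scene):
        scenes = [tiny_scene] * 3
        cfg = TrainConfig(epochs=1, crops_per_scene=2, crop_size=128,
                          base_channels=4, seed=5)
        a = train(scenes, "tuft", cfg)
        b = train(scenes, "tuft", cfg)
        assert np.array_equal(a.net.head.w, b.net.head.w)
        assert a.training_log.equals(b.training_log)

    def test_split_is_disjoint_and_covers(self):
        for n in (2, 5, 20):
            tr, va = split_scenes(n, 0.2, seed=3)
            assert set(tr) | set(va) == set(range(n))
            assert set(tr) & set(va) == set()
            assert len(va) >= 1
        assert split_scenes(10, 0.2, seed=3) == split_scenes(10, 0.2, seed=3)

    def test_needs_two_scenes(self, tiny_scene):
        with pytest.raises(ValueError):
            train([tiny_scene], "tuft", TrainConfig())


class TestDice:
    def test_identical_and_disjoint(self):
        a = np.zeros((8, 8), bool)
        a[2:5, 2:5] = True
        assert dice(a, a) == 1.0
        b = np.zeros((8, 8), bool)
        b[6:8, 6:8] = True
        assert dice(a, b) == 0.0
        assert dice(np.zeros((4, 4), bool), np.zeros((4, 4), bool)) == 1.0

    def test_half_overlap(self):
        a = np.zeros((4, 4), bool)
        b = np.zeros((4, 4), bool)
        a[0, 0:4] = True
        b[0, 2:4] = True
        b[1, 0:2] = True
        assert dice(a, b) == 0.5

    @settings(derandomize=True, max_examples=50)
    @given(st.integers(0, 2**32 - 1))
    def test_matches_set_overlap_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.random((12, 12)) > 0.6
        b = rng.random((12, 12)) > 0.6
        set_a = {(i, j) for i, j in zip(*np.nonzero(a))}
        set_b = {(i, j) for i, j in zip(*np.nonzero(b))}
        if not set_a and not set_b:
            expected = 1.0
        else:
            expected = 2 * len(set_a & set_b) / (len(set_a) + len(set_b))
        assert dice(a, b) == pytest.approx(expected)
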