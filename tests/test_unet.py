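"""Network shape contracts, patching, augmentation and inference assembly."""

import numpy as np
import pytest

from papillae import build_model, reduced_config, sliding_window_predict, train
from papillae.patches import (
    AugmentParams,
    apply_augment,
    augment,
    downscale_training_image,
    extract_patches,
)
from papillae.unet import UNetConfig, load_model, save_model

from conftest import flood_fill_count


def tiny_config(**overrides):
    params = dict(
        encoder_widths=(4, 8),
        patch_height=32,
        patch_width=48,
        epochs=2,
        batch_size=4,
        learning_rate=1e-3,
        dropout_fraction=0.2,
    )
    params.update(overrides)
    return UNetConfig(**params)


def random_dataset(rng, n=6, shape=(32, 48)):
    data = []
    for _ in range(n):
        mask = np.zeros(shape, bool)
        mask[8:14, 10:18] = True
        img = np.repeat(mask[..., None], 3, axis=-1).astype(np.float32)
        img += rng.normal(0, 0.05, img.shape).astype(np.float32)
        data.append((img, mask.astype(np.float32), np.ones(shape, np.float32)))
    return data


class TestBuildModel:
    def test_output_shape_matches_input(self):
        model = build_model(tiny_config())
        x = np.random.default_rng(0).random((1, 32, 48, 3), dtype=np.float32)
        out = model.net.forward(x)
        assert out.shape == (1, 32, 48)
        assert np.all((out >= 0) & (out <= 1))

    def test_reduced_preset_shape_contract(self):
        model = build_model(reduced_config())
        x = np.zeros((1, 128, 192, 3), np.float32)
        assert model.net.forward(x).shape == (1, 128, 192)

    def test_incompatible_patch_size_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            UNetConfig(encoder_widths=(8, 16, 32), patch_height=98, patch_width=96)

    def test_same_seed_identical_initial_predictions(self):
        x = np.random.default_rng(1).random((1, 32, 48, 3), dtype=np.float32)
        a = build_model(tiny_config(seed=9)).net.forward(x)
        b = build_model(tiny_config(seed=9)).net.forward(x)
        np.testing.assert_array_equal(a, b)

    def test_predict_pads_odd_sizes(self):
        model = build_model(tiny_config())
        out = model.predict(np.zeros((33, 49, 3), np.float32))
        assert out.shape == (33, 49)


class TestExtractPatches:
    def test_exact_tiling_arithmetic(self):
        img = np.zeros((768, 1152, 3), np.float32)
        mask = np.zeros((768, 1152), bool)
        patches = extract_patches(img, mask, patch_size=(384, 576))
        assert len(patches) == 4
        assert patches[0][0].shape == (384, 576, 3)

    def test_tongue_free_patches_excluded(self):
        img = np.zeros((64, 96, 3), np.float32)
        mask = np.zeros((64, 96), bool)
        tongue = np.zeros((64, 96), bool)
        tongue[:32, :] = True  # tongue only in the upper half
        patches = extract_patches(img, mask, tongue_mask=tongue, patch_size=(32, 48))
        assert len(patches) == 2

    def test_all_tongue_keeps_everything(self):
        img = np.zeros((64, 96, 3), np.float32)
        patches = extract_patches(
            img, np.zeros((64, 96), bool), tongue_mask=np.ones((64, 96), bool),
            patch_size=(32, 48),
        )
        assert len(patches) == 4

    def test_too_small_image_raises(self):
        with pytest.raises(ValueError, match="resize"):
            extract_patches(
                np.zeros((16, 16, 3)), np.zeros((16, 16), bool), patch_size=(32, 48)
            )


class TestDownscale:
    def test_factor_four_shapes_and_values(self, rng):
        img = rng.random((256, 384, 3)).astype(np.float32)
        mask = np.zeros((256, 384), bool)
        mask[:128] = True
        weights = np.where(mask, 5.0, 1.0).astype(np.float32)
        im2, m2, w2 = downscale_training_image(img, mask, weights, factor=4)
        assert im2.shape == (64, 96, 3)
        assert m2.shape == (64, 96) and m2.dtype == bool
        assert m2[:32].all() and not m2[32:].any()
        assert set(np.unique(w2)) <= {1.0, 5.0}
        # block mean of the first block
        assert im2[0, 0, 0] == pytest.approx(img[:4, :4, 0].mean(), rel=1e-5)


class TestAugment:
    def test_identity_draw_unchanged(self, rng):
        img = rng.random((20, 30, 3)).astype(np.float32)
        mask = rng.random((20, 30)) < 0.3
        out_img, (out_mask,) = apply_augment(img, [mask], AugmentParams())
        np.testing.assert_array_equal(out_img, img)
        np.testing.assert_array_equal(out_mask, mask)

    def test_mirror_preserves_component_count(self, rng):
        mask = rng.random((40, 40)) < 0.05
        n = flood_fill_count(mask)
        _, (mirrored,) = apply_augment(
            np.zeros((40, 40, 3), np.float32), [mask], AugmentParams(mirror_h=True)
        )
        assert flood_fill_count(mirrored) == n
        assert mirrored.dtype == bool

    def test_quarter_turn_preserves_seven_components(self):
        mask = np.zeros((64, 64), bool)
        rng = np.random.default_rng(4)
        placed = 0
        while placed < 7:
            r, c = rng.integers(12, 52, size=2)
            region = mask[r - 3: r + 4, c - 3: c + 4]
            if not region.any():
                mask[r - 1: r + 2, c - 1: c + 2] = True
                placed += 1
        assert flood_fill_count(mask) == 7
        _, (rotated,) = apply_augment(
            np.zeros((64, 64, 3), np.float32), [mask], AugmentParams(rotation_deg=90.0)
        )
        assert flood_fill_count(rotated) == 7

    def test_intensity_touches_image_only(self, rng):
        img = np.full((10, 10, 3), 0.5, np.float32)
        mask = np.ones((10, 10), bool)
        out_img, (out_mask,) = apply_augment(
            img, [mask], AugmentParams(intensity_gain=1.2, intensity_bias=0.05)
        )
        assert out_img[0, 0, 0] == pytest.approx(0.65)
        np.testing.assert_array_equal(out_mask, mask)

    def test_random_draw_keeps_masks_binary(self, rng):
        img = rng.random((30, 30, 3)).astype(np.float32)
        mask = rng.random((30, 30)) < 0.3
        weights = np.where(mask, 10.0, 1.0).astype(np.float32)
        _, (m2, w2) = augment(img, [mask, weights], seed=5)
        assert m2.dtype == bool
        assert set(np.unique(w2)) <= {1.0, 10.0}


class TestTraining:
    def test_one_epoch_finite_bounded_loss(self, rng):
        model = build_model(tiny_config(epochs=1))
        model = train(model, random_dataset(rng))
        assert len(model.history["train"]) == 1
        assert 0.0 <= model.history["val"][0] <= 1.0

    def test_loss_decreases_on_easy_data(self, rng):
        model = build_model(tiny_config(epochs=8, learning_rate=3e-3))
        model = train(model, random_dataset(rng, n=8))
        assert model.history["val"][-1] < model.history["val"][0]

    def test_training_deterministic(self, rng):
        data = random_dataset(rng)
        h1 = train(build_model(tiny_config(seed=3)), data).history
        h2 = train(build_model(tiny_config(seed=3)), data).history
        np.testing.assert_allclose(h1["train"], h2["train"], rtol=1e-6)

    def test_empty_dataset_raises(self):
        with pytest.raises(ValueError):
            train(build_model(tiny_config()), [])

    def test_checkpoint_roundtrip(self, rng, tmp_path):
        model = train(build_model(tiny_config(epochs=1)), random_dataset(rng))
        x = rng.random((1, 32, 48, 3), dtype=np.float32)
        before = model.net.forward(x)
        save_model(model, tmp_path / "model")
        loaded = load_model(tmp_path / "model")
        np.testing.assert_allclose(loaded.net.forward(x), before, rtol=1e-6)


class TestSlidingWindow:
    def test_non_overlapping_equals_per_patch(self, rng):
        model = build_model(tiny_config())
        img = rng.random((64, 96, 3)).astype(np.float32)
        ens = sliding_window_predict(model, img, stride=(32, 48))
        direct = np.zeros((64, 96), np.float32)
        for r in range(0, 64, 32):
            for c in range(0, 96, 48):
                direct[r: r + 32, c: c + 48] = model.net.forward(
                    img[None, r: r + 32, c: c + 48]
                )[0]
        np.testing.assert_allclose(ens, direct, atol=1e-6)

    def test_half_overlap_matches_accumulation_oracle(self, rng):
        model = build_model(tiny_config())
        img = rng.random((64, 96, 3)).astype(np.float32)
        ens = sliding_window_predict(model, img, stride=(16, 24))
        acc = np.zeros((64, 96)); cnt = np.zeros((64, 96))
        for r in range(0, 33, 16):
            for c in range(0, 49, 24):
                acc[r: r + 32, c: c + 48] += model.net.forward(img[None, r: r + 32, c: c + 48])[0]
                cnt[r: r + 32, c: c + 48] += 1
        np.testing.assert_allclose(ens, acc / cnt, atol=1e-6)

    def test_output_shape_equals_input(self, rng):
        model = build_model(tiny_config())
        img = rng.random((70, 101, 3)).astype(np.float32)
        assert sliding_window_predict(model, img).shape == (70, 101)
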