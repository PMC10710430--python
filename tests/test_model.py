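"""FlyNet architecture contracts, the Log-Cosh Dice loss, training
mechanics and prediction."""

import numpy as np
import pytest

from flyheart import (
    ModelConfig,
    PhantomConfig,
    TrainConfig,
    build_flynet,
    log_cosh_dice_loss,
    predict_masks,
    render_fullsize_phantom,
    render_phantom,
)
from flyheart.model import (
    SamplePair,
    _augmented_crop,
    _log_cosh_dice_grad,
    evaluate_model,
    split_samples,
    train_model,
)
from flyheart import nn
from flyheart.preprocess import bbox_from_mask, crop_resize, normalize_video

TINY = ModelConfig(seq_len=4, in_size=32, n_levels=3, n_spatiotemporal=1, base_filters=4)


class TestArchitecture:
    def test_output_matches_input_shape_with_unit_range(self):
        model = build_flynet(ModelConfig(seq_len=4, in_size=128), seed=0)
        x = np.random.default_rng(0).normal(size=(1, 4, 1, 128, 128)).astype(np.float32)
        probs, _ = model.forward(x, training=False)
        assert probs.shape == x.shape
        assert probs.min() > 0.0 and probs.max() < 1.0

    def test_smaller_geometry(self):
        model = build_flynet(ModelConfig(seq_len=2, in_size=64, n_levels=3), seed=0)
        x = np.zeros((2, 2, 1, 64, 64), dtype=np.float32)
        probs, _ = model.forward(x, training=False)
        assert probs.shape == (2, 2, 1, 64, 64)

    def test_indivisible_input_size_rejected(self):
        with pytest.raises(ValueError):
            build_flynet(ModelConfig(in_size=100, n_levels=4))

    def test_spatiotemporal_count_bounds(self):
        with pytest.raises(ValueError):
            build_flynet(ModelConfig(n_levels=3, n_spatiotemporal=4))

    def test_temporal_sensitivity_of_convlstm_path(self):
        """Frame order changes the output — a purely per-frame network
        would be invariant to it."""
        model = build_flynet(TINY, seed=3)
        video, _, _ = render_phantom(
            PhantomConfig(n_frames=4, height=32, width=32, fps=10.0, base_hr=2.0,
                          semi_axes=(6.0, 8.0), wall_thickness=2.0, seed=0)
        )
        x = normalize_video(video.frames)[None, :, None].astype(np.float32)
        perm = [3, 1, 0, 2]
        probs, _ = model.forward(x, training=False)
        probs_shuf, _ = model.forward(x[:, perm], training=False)
        # compare frame-aligned predictions
        diff = np.abs(probs[:, perm] - probs_shuf).mean()
        assert diff > 1e-4

    def test_spatial_only_model_is_frame_permutation_equivariant(self):
        cfg = ModelConfig(seq_len=4, in_size=32, n_levels=3, n_spatiotemporal=0,
                          base_filters=4)
        model = build_flynet(cfg, seed=3)
        x = np.random.default_rng(1).normal(size=(1, 4, 1, 32, 32)).astype(np.float32)
        perm = [2, 0, 3, 1]
        probs, _ = model.forward(x, training=False)
        probs_shuf, _ = model.forward(x[:, perm], training=False)
        np.testing.assert_allclose(probs[:, perm], probs_shuf, atol=1e-6)

    def test_gradients_reach_convlstm_kernels(self):
        model = build_flynet(TINY, seed=0)
        rng = np.random.default_rng(0)
        x = rng.normal(size=(1, 4, 1, 32, 32)).astype(np.float32)
        y = (rng.random((1, 4, 1, 32, 32)) > 0.7).astype(np.float32)
        probs, state = model.forward(x, training=True)
        nn.zero_grads(model.params())
        model.backward(_log_cosh_dice_grad(probs, y), state)
        lstm_conv = model.enc[0]["temporal"].conv
        assert np.abs(lstm_conv.w.grad).max() > 0

    def test_save_load_round_trip(self, tmp_path):
        model = build_flynet(TINY, seed=5)
        x = np.random.default_rng(2).normal(size=(1, 4, 1, 32, 32)).astype(np.float32)
        probs, _ = model.forward(x, training=False)
        model.save(tmp_path / "net")
        reloaded = type(model).load(tmp_path / "net")
        probs2, _ = reloaded.forward(x, training=False)
        np.testing.assert_array_equal(probs, probs2)


class TestLoss:
    def test_perfect_prediction_is_zero(self):
        y = (np.random.default_rng(0).random((2, 3, 5, 5)) > 0.5).astype(float)
        assert log_cosh_dice_loss(y, y, eps=0.0) == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_prediction_closed_form(self):
        p = np.zeros((1, 4, 4))
        t = np.zeros((1, 4, 4))
        p[0, 0, 0] = 1.0
        t[0, 3, 3] = 1.0
        assert log_cosh_dice_loss(p, t, eps=0.0) == pytest.approx(
            np.log(np.cosh(1.0)), abs=1e-9
        )

    def test_half_dice_closed_form(self):
        # |p ∩ t| = 2, |p| = |t| = 4 -> Dice 0.5
        p = np.zeros((1, 4, 4))
        t = np.zeros((1, 4, 4))
        p[0, 0, :4] = 1.0
        t[0, 0, 2:] = t[0, 1, :2] = 1.0
        assert log_cosh_dice_loss(p, t, eps=0.0) == pytest.approx(
            np.log(np.cosh(0.5)), abs=1e-9
        )

    def test_monotone_decreasing_in_dice(self):
        t = np.ones((1, 10))
        losses = []
        for frac in np.linspace(0.1, 1.0, 10):
            p = np.full((1, 10), frac)
            losses.append(log_cosh_dice_loss(p, t, eps=0.0))
        assert all(a > b for a, b in zip(losses, losses[1:]))

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            log_cosh_dice_loss(np.zeros((1, 3)), np.zeros((1, 4)))

    def test_gradient_matches_numeric(self):
        rng = np.random.default_rng(3)
        p = rng.random((2, 6))
        t = (rng.random((2, 6)) > 0.5).astype(float)
        g = _log_cosh_dice_grad(p, t, eps=1.0)
        eps = 1e-7
        for idx in [(0, 0), (1, 3), (0, 5)]:
            orig = p[idx]
            p[idx] = orig + eps
            lp = log_cosh_dice_loss(p, t)
            p[idx] = orig - eps
            lm = log_cosh_dice_loss(p, t)
            p[idx] = orig
            assert g[idx] == pytest.approx((lp - lm) / (2 * eps), rel=1e-4)


def _tiny_sample(seed=0, n_frames=8):
    cfg = PhantomConfig(n_frames=n_frames, height=48, width=48, fps=10.0, base_hr=2.0,
                        semi_axes=(8.0, 11.0), wall_thickness=2.0, speckle_scale=0.0,
                        blur_sigma=0.5, seed=seed)
    fv, fm, _, _, _, _ = render_fullsize_phantom(cfg, full_height=72, full_width=48)
    return SamplePair(fv.frames, fm.frames)


class TestTraining:
    def test_one_epoch_descends(self):
        sample = _tiny_sample()
        model = build_flynet(TINY, seed=0)
        tc = TrainConfig(epochs=1, seed=0, split=(1.0, 0.0, 0.0), jitter=0)
        before, _ = evaluate_model(model, [sample], margin=tc.margin)
        history = train_model(model, tc, [sample], val_samples=[])
        after, _ = evaluate_model(model, [sample], margin=tc.margin)
        assert after < before
        assert len(history["train_loss"]) == 1

    def test_empty_training_set_raises(self):
        model = build_flynet(TINY, seed=0)
        with pytest.raises(ValueError):
            train_model(model, TrainConfig(), [])

    def test_split_fractions_partition_samples(self):
        samples = [_tiny_sample(s, n_frames=2) for s in range(10)]
        rng = np.random.default_rng(0)
        train, val, test = split_samples(samples, (0.8, 0.1, 0.1), rng)
        assert (len(train), len(val), len(test)) == (8, 1, 1)
        assert {id(s) for s in train + val + test} == {id(s) for s in samples}

    def test_bad_split_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(split=(0.5, 0.2, 0.2)).validate()

    def test_zero_jitter_augmentation_equals_deterministic_crop(self):
        sample = _tiny_sample()
        rng = np.random.default_rng(0)
        x, y = _augmented_crop(sample.full_img, sample.full_mask, 32, 4, 0, rng)
        box = bbox_from_mask(sample.full_mask, margin=4, square=True)
        np.testing.assert_array_equal(
            x, normalize_video(crop_resize(sample.full_img, box, 32))
        )
        np.testing.assert_array_equal(
            y, crop_resize(sample.full_mask, box, 32, mask=True)
        )

    def test_jittered_crop_always_contains_heart(self):
        sample = _tiny_sample()
        rng = np.random.default_rng(1)
        for _ in range(20):
            _, y = _augmented_crop(sample.full_img, sample.full_mask, 32, 4, 4, rng)
            assert y.sum() == pytest.approx(
                crop_resize(
                    sample.full_mask,
                    bbox_from_mask(sample.full_mask, margin=4, square=True),
                    32,
                    mask=True,
                ).sum(),
                rel=0.15,
            )


class TestPrediction:
    def test_frame_count_preserved_with_padded_tail(self):
        model = build_flynet(TINY, seed=0)
        video = np.random.default_rng(0).normal(size=(10, 32, 32)).astype(np.float32)
        mask = predict_masks(model, video)
        assert mask.shape == (10, 32, 32)
        assert set(np.unique(mask).tolist()) <= {0, 1}

    def test_prediction_is_pure(self):
        model = build_flynet(TINY, seed=1)
        video = np.random.default_rng(1).normal(size=(6, 32, 32)).astype(np.float32)
        np.testing.assert_array_equal(
            model.predict_probs(video), model.predict_probs(video)
        )

    def test_wrong_spatial_size_rejected(self):
        model = build_flynet(TINY, seed=0)
        with pytest.raises(ValueError):
            predict_masks(model, np.zeros((4, 64, 64), dtype=np.float32))
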