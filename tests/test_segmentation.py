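import numpy as np
import pytest

from echolvef import nn
from echolvef.segmentation import (
    SegConfig,
    build_acnn,
    dice,
    load_model,
    predict_mask,
    predict_proba,
    save_model,
    train,
)


class TestDice:
    def test_identical_disjoint_and_half_overlap(self):
        a = np.zeros((4, 4), bool)
        a[:2] = True
        b = np.zeros((4, 4), bool)
        b[1:3] = True  # |a|=8, |b|=8, overlap 4
        assert dice(a, a) == 1.0
        assert dice(a, ~a) == 0.0
        assert dice(a, b) == 0.5

    def test_symmetry_and_bounds(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            a = rng.random((8, 8)) > 0.5
            b = rng.random((8, 8)) > 0.5
            assert dice(a, b) == dice(b, a)
            assert 0.0 <= dice(a, b) <= 1.0

    def test_empty_vs_empty_is_one(self):
        z = np.zeros((3, 3), bool)
        assert dice(z, z) == 1.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dice(np.zeros((2, 2), bool), np.zeros((3, 3), bool))


class TestConvOracle:
    def test_matches_scipy_correlate2d(self):
        from scipy.signal import correlate2d

        rng = np.random.default_rng(3)
        conv = nn.Conv2d(1, 1, 3, pad=1, rng=rng)
        x = rng.normal(size=(1, 1, 9, 9))
        out = conv.forward(x)[0, 0]
        expected = correlate2d(x[0, 0], conv.W[0, 0], mode="same") + conv.b[0]
        assert np.allclose(out, expected)

    def test_dilated_kernel_matches_inflated_dense_kernel(self):
        from scipy.signal import correlate2d

        rng = np.random.default_rng(4)
        conv = nn.Conv2d(1, 1, 3, dilation=2, rng=rng)
        x = rng.normal(size=(1, 1, 12, 12))
        out = conv.forward(x)[0, 0]
        inflated = np.zeros((5, 5))
        inflated[::2, ::2] = conv.W[0, 0]
        expected = correlate2d(x[0, 0], inflated, mode="same") + conv.b[0]
        assert np.allclose(out, expected)

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(5)
        conv = nn.Conv2d(2, 3, 3, stride=2, dilation=1, rng=rng)
        x = rng.normal(size=(2, 2, 8, 8))
        out = conv.forward(x)
        g = rng.normal(size=out.shape)
        gx = conv.backward(g)
        eps = 1e-6
        flat_idx = [(0, 1, 3, 4), (1, 0, 0, 0), (1, 1, 7, 7)]
        for idx in flat_idx:
            xp = x.copy()
            xp[idx] += eps
            xm = x.copy()
            xm[idx] -= eps
            num = (np.sum(conv.forward(xp) * g) - np.sum(conv.forward(xm) * g)) / (2 * eps)
            assert num == pytest.approx(gx[idx], rel=1e-4, abs=1e-7)


class TestBuildACNN:
    def test_forward_on_zero_frame_is_finite_probability_grid(self):
        model = build_acnn(SegConfig(input_size=(32, 32)))
        proba = predict_proba(model, np.zeros((32, 32)))
        assert proba.shape == (1, 32, 32)
        assert np.all(np.isfinite(proba)) and proba.min() >= 0 and proba.max() <= 1

    def test_same_seed_identical_initialisation(self):
        m1 = build_acnn(SegConfig(seed=11))
        m2 = build_acnn(SegConfig(seed=11))
        for a, b in zip(m1.state_arrays(), m2.state_arrays()):
            assert np.array_equal(a, b)

    def test_width_scaling_reduces_parameter_count(self):
        small = build_acnn(SegConfig(width_scale=0.125))
        full = build_acnn(SegConfig(width_scale=1.0))
        n_small = sum(p.size for p in small.state_arrays())
        n_full = sum(p.size for p in full.state_arrays())
        assert n_small < n_full

    def test_indivisible_input_size_rejected(self):
        with pytest.raises(ValueError):
            SegConfig(input_size=(30, 30))

    def test_duplicate_atrous_rates_rejected(self):
        with pytest.raises(ValueError):
            SegConfig(atrous_rates=(2, 2, 4))


class TestTrain:
    @pytest.fixture(scope="class")
    def tiny_pair(self):
        rng = np.random.default_rng(1)
        mask = np.zeros((32, 32), bool)
        mask[8:24, 10:22] = True
        frame = np.clip(0.3 + 0.5 * mask + rng.normal(0, 0.05, (32, 32)), 0, 1)
        return frame, mask

    def test_zero_epochs_leaves_parameters_unchanged(self, tiny_pair):
        frame, mask = tiny_pair
        cfg = SegConfig(input_size=(32, 32), epochs=0)
        model = build_acnn(cfg)
        before = [p.copy() for p in model.state_arrays()]
        train(model, frame[None], mask[None])
        for a, b in zip(before, model.state_arrays()):
            assert np.array_equal(a, b)

    def test_duplicated_pair_gives_identical_first_gradient(self, tiny_pair):
        # mean loss: duplicating one pair ten-fold leaves the gradient unchanged
        frame, mask = tiny_pair
        cfg = SegConfig(input_size=(32, 32), seed=2)

        def first_grads(n_copies):
            model = build_acnn(cfg)
            x = np.repeat(frame[None, None], n_copies, axis=0)
            y = np.repeat(mask[None, None].astype(float), n_copies, axis=0)
            logits = model.net.forward(x)
            _, grad = nn.bce_with_logits(logits, y)
            model.net.backward(grad)
            return [g.copy() for _, g in model.net.parameters()]

        for g1, g10 in zip(first_grads(1), first_grads(10)):
            assert np.allclose(g1, g10, atol=1e-12)

    def test_smoothed_loss_non_increasing_on_overfit_fixture(self, tiny_pair):
        frame, mask = tiny_pair
        cfg = SegConfig(input_size=(32, 32), epochs=60, learning_rate=1e-2)
        model = train(build_acnn(cfg), frame[None], mask[None])
        hist = np.asarray(model.training_history)
        smoothed = np.convolve(hist, np.ones(5) / 5, mode="valid")
        assert np.all(np.diff(smoothed) <= 1e-3)
        assert hist[-1] < hist[0]

    def test_shape_mismatch_rejected(self, tiny_pair):
        frame, mask = tiny_pair
        model = build_acnn(SegConfig(input_size=(32, 32)))
        with pytest.raises(ValueError):
            train(model, frame[None], mask[None, :16, :16])

    def test_non_binary_masks_rejected(self, tiny_pair):
        frame, _ = tiny_pair
        model = build_acnn(SegConfig(input_size=(32, 32)))
        with pytest.raises(ValueError):
            train(model, frame[None], np.full((1, 32, 32), 0.5))


class TestPredictMask:
    @pytest.mark.parametrize("p,expect_full", [(0.4, False), (0.6, True)])
    def test_threshold_semantics(self, p, expect_full):
        from echolvef.segmentation import SegModel

        cfg = SegConfig(input_size=(32, 32))

        class _ConstLogit:
            def forward(self, x):
                return np.full((x.shape[0], 1, 32, 32), np.log(p / (1 - p)))

        model = SegModel(config=cfg, net=_ConstLogit())
        mask = predict_mask(model, np.zeros((32, 32)))
        assert mask.all() if expect_full else not mask.any()

    def test_idempotent_for_fixed_model(self, overfit_fixture):
        frames, _ = overfit_fixture
        model = build_acnn(SegConfig())
        m1 = predict_mask(model, frames[0])
        m2 = predict_mask(model, frames[0])
        assert np.array_equal(m1, m2)

    def test_wrong_shape_rejected(self):
        model = build_acnn(SegConfig(input_size=(32, 32)))
        with pytest.raises(ValueError):
            predict_mask(model, np.zeros((16, 16)))


def test_save_load_roundtrip_preserves_predictions(tmp_path, overfit_fixture):
    frames, masks = overfit_fixture
    cfg = SegConfig(epochs=5)
    model = train(build_acnn(cfg), frames[:2], masks[:2])
    proba = predict_proba(model, frames[0])
    path = tmp_path / "model.npz"
    save_model(model, path)
    back = load_model(path)
    assert np.allclose(predict_proba(back, frames[0]), proba)
    assert back.config == model.config
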