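import numpy as np
import pytest
from sklearn.base import clone

from amypetseg.model import (
    UNet,
    UNetConfig,
    UNetSegmenter,
    build_unet,
    forward,
    load_checkpoint,
    save_checkpoint,
)


def _expected_param_count(depth: int, base: int, in_ch: int = 1, n_classes: int = 2) -> int:
    """Independent closed-form parameter count: sum of kernel*in*out + out."""
    total = 0
    cin = in_ch
    for i in range(depth):  # encoder: two 3x3 convs per stage
        ch = base * 2**i
        total += 9 * cin * ch + ch
        total += 9 * ch * ch + ch
        cin = ch
    bch = base * 2**depth  # bottleneck
    total += 9 * cin * bch + bch
    total += 9 * bch * bch + bch
    for i in reversed(range(depth)):  # decoder: 2x2 up-conv + two 3x3 convs
        ch = base * 2**i
        total += 4 * (2 * ch) * ch + ch
        total += 9 * (2 * ch) * ch + ch
        total += 9 * ch * ch + ch
    total += 1 * base * n_classes + n_classes  # final 1x1
    return total


@pytest.fixture(scope="session")
def trained_segmenter(training_slices):
    X, y = training_slices
    seg = UNetSegmenter(
        depth=2,
        base_channels=8,
        learning_rate=1e-3,
        batch_size=4,
        max_epochs=80,
        augment_data=False,
        random_state=0,
    )
    return seg.fit(X, y)


class TestBuildUnet:
    def test_output_shape_contract(self):
        net = build_unet(UNetConfig(depth=1, base_channels=4, seed=0))
        out = net.forward(np.zeros((3, 16, 16)))
        assert out.shape == (3, 2, 16, 16)

    @pytest.mark.parametrize("depth,base", [(1, 4), (2, 8), (3, 4)])
    def test_parameter_count_matches_closed_form_oracle(self, depth, base):
        net = build_unet(UNetConfig(depth=depth, base_channels=base, seed=0))
        assert net.parameter_count() == _expected_param_count(depth, base)

    def test_depth_two_has_eleven_conv_layers(self):
        net = build_unet(UNetConfig(depth=2, base_channels=8, seed=0))
        assert net.conv_layer_count() == 11

    def test_same_seed_identical_initial_weights(self):
        cfg = UNetConfig(depth=2, base_channels=4, seed=7)
        a, b = build_unet(cfg), build_unet(cfg)
        for pa, pb in zip(a.parameters(), b.parameters()):
            np.testing.assert_array_equal(pa.value, pb.value)

    def test_indivisible_input_size_rejected(self):
        net = build_unet(UNetConfig(depth=2, base_channels=4, seed=0))
        with pytest.raises(ValueError, match="divisible"):
            net.forward(np.zeros((1, 30, 30)))

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            UNetConfig(depth=0)
        with pytest.raises(ValueError):
            UNetConfig(n_classes=3)


class TestForward:
    def test_probabilities_sum_to_one_per_pixel(self, rng):
        net = build_unet(UNetConfig(depth=2, base_channels=4, seed=1))
        prob = forward(net, rng.normal(size=(2, 32, 32)))
        np.testing.assert_allclose(prob.sum(axis=1), 1.0, atol=1e-6)
        assert prob.min() >= 0 and prob.max() <= 1

    def test_zeroed_final_layer_gives_uniform_half(self, rng):
        net = build_unet(UNetConfig(depth=1, base_channels=4, seed=2))
        net.final.weight.value[...] = 0.0
        net.final.bias.value[...] = 0.0
        prob = forward(net, rng.normal(size=(1, 16, 16)))
        np.testing.assert_allclose(prob, 0.5)

    def test_wrong_channel_count_rejected(self):
        net = build_unet(UNetConfig(depth=1, base_channels=4, seed=0))
        with pytest.raises(ValueError, match="expected"):
            net.forward(np.zeros((1, 3, 16, 16)))

    def test_gradient_reaches_every_parameter(self, training_slices):
        X, y = training_slices
        net = build_unet(UNetConfig(depth=2, base_channels=8, seed=0))
        from amypetseg.losses import iou_loss_grad, softmax

        x = (X[:2] - X.mean()) / X.std()
        logits = net.forward(x)
        p = softmax(logits, axis=1)
        dp = np.zeros_like(p)
        for i in range(2):
            dp[i, 1] = iou_loss_grad(p[i, 1], y[i])
        dz = p * (dp - (dp * p).sum(axis=1, keepdims=True))
        for par in net.parameters():
            par.zero_grad()
        net.backward(dz)
        for par in net.parameters():
            assert np.any(par.grad != 0.0), par.name

    def test_translation_covariance_by_full_pooling_stride(self, trained_segmenter, training_slices):
        # shifting the input by the total downsampling factor (2^depth = 4)
        # shifts the prediction by the same amount, up to border effects
        X, _ = training_slices
        shift = 4
        base = trained_segmenter.predict(X[4:5])[0]
        shifted = trained_segmenter.predict(np.roll(X[4:5], shift, axis=1))[0]
        realigned = np.roll(base, shift, axis=0)
        inter = np.count_nonzero(realigned & shifted)
        union = np.count_nonzero(realigned | shifted)
        assert union > 0
        assert inter / union > 0.9


class TestUNetSegmenter:
    def test_overfit_single_slice_drives_iou_above_point_nine(self, training_slices):
        X, y = training_slices
        seg = UNetSegmenter(
            learning_rate=1e-3,
            batch_size=1,
            max_epochs=50,
            augment_data=False,
            random_state=0,
        )
        seg.fit(X[4:5], y[4:5])
        assert seg.history_["train_iou"].iloc[-1] > 0.9

    def test_zero_epochs_returns_initial_network_and_empty_history(self, training_slices):
        X, y = training_slices
        seg = UNetSegmenter(max_epochs=0, random_state=0).fit(X[:2], y[:2])
        assert len(seg.history_) == 0
        ref = build_unet(UNetConfig(depth=2, base_channels=8, seed=0))
        for pa, pb in zip(seg.network_.parameters(), ref.parameters()):
            np.testing.assert_array_equal(pa.value, pb.value)

    def test_fit_is_deterministic_for_fixed_random_state(self, training_slices):
        X, y = training_slices
        kw = dict(learning_rate=1e-3, max_epochs=3, augment_data=True, random_state=5)
        a = UNetSegmenter(**kw).fit(X, y)
        b = UNetSegmenter(**kw).fit(X, y)
        assert a.history_.equals(b.history_)
        np.testing.assert_array_equal(a.predict(X), b.predict(X))

    def test_history_records_validation_curves(self, training_slices):
        X, y = training_slices
        seg = UNetSegmenter(learning_rate=1e-3, max_epochs=3, random_state=0)
        seg.fit(X[:6], y[:6], X_val=X[6:], y_val=y[6:])
        assert {"epoch", "train_loss", "train_iou", "val_loss", "val_iou"} <= set(
            seg.history_.columns
        )
        assert len(seg.history_) == 3
        assert 0 <= seg.best_epoch_ < 3

    def test_score_is_mean_validation_iou(self, trained_segmenter, training_slices):
        X, y = training_slices
        score = trained_segmenter.score(X, y)
        assert 0.0 <= score <= 1.0
        assert score > 0.8  # trained on these slices; must fit them well

    def test_sklearn_clone_and_get_params_roundtrip(self):
        seg = UNetSegmenter(depth=3, base_channels=4, learning_rate=2e-4)
        cloned = clone(seg)
        assert cloned.get_params() == seg.get_params()
        seg.set_params(depth=1)
        assert seg.depth == 1

    def test_predict_before_fit_raises(self):
        with pytest.raises(RuntimeError, match="not fitted"):
            UNetSegmenter().predict(np.zeros((1, 16, 16)))

    def test_binary_mask_validation(self, training_slices):
        X, _ = training_slices
        with pytest.raises(ValueError, match="binary"):
            UNetSegmenter(max_epochs=1).fit(X[:2], X[:2])

    def test_checkpoint_roundtrip_preserves_predictions(self, trained_segmenter, training_slices, tmp_path):
        X, _ = training_slices
        path = tmp_path / "ckpt.npz"
        save_checkpoint(trained_segmenter.network_, path)
        net2 = load_checkpoint(path)
        Xs = (X[:3] - trained_segmenter.mean_) / trained_segmenter.std_
        np.testing.assert_array_equal(
            trained_segmenter.network_.predict_proba(Xs), net2.predict_proba(Xs)
        )
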