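"""Loss, schedule, class weights, network contracts and gradient checks."""

import hashlib

import numpy as np
import pytest

from cxrseg import (
    PhantomSpec,
    TrainConfig,
    UNetSegmenter,
    UNetSpec,
    build_unet,
    compute_class_weights,
    focal_loss,
    generate_dataset,
    poly_decay_lr,
    predict_masks,
    train_model,
)
from cxrseg.edges import EnhanceOptions
from cxrseg.model import _focal_loss_and_grad, load_checkpoint, save_checkpoint


class TestClassWeights:
    def test_equal_frequencies_give_unit_weights(self):
        masks = np.zeros((1, 4, 4, 4), dtype=np.uint8)
        masks[:, :, :2] = 1  # every class gets the same 8 pixels
        w = compute_class_weights(masks)
        assert np.allclose(w.weights, 1.0)

    def test_nine_to_one_frequencies(self):
        # frequencies (0.9, 0.1) -> raw (1/0.9, 1/0.1), mean-1 -> (0.2, 1.8)
        masks = np.zeros((1, 2, 10, 10), dtype=np.uint8)
        masks[0, 0, :9] = 1  # 90 pixels
        masks[0, 1, 9, :] = 1  # 10 pixels
        w = compute_class_weights(masks)
        assert np.allclose(w.weights, [0.2, 1.8])

    def test_invariant_to_uniform_pixel_scaling(self):
        base = np.zeros((1, 2, 10, 10), dtype=np.uint8)
        base[0, 0, :6] = 1
        base[0, 1, 6] = 1
        scaled = np.repeat(base, 10, axis=0)
        assert np.allclose(
            compute_class_weights(base).weights,
            compute_class_weights(scaled).weights,
        )

    def test_ordering_inverse_to_frequency_and_mean_one(self, tiny_dataset):
        w = compute_class_weights(tiny_dataset)
        counts = np.array(
            [sum(s.masks[c].sum() for s in tiny_dataset) for c in w.class_names]
        )
        # rarer class => weight at least as large
        order_by_count = np.argsort(counts)
        weights_sorted = w.weights[order_by_count]
        assert np.all(np.diff(weights_sorted) <= 1e-12)
        assert np.isclose(w.weights.mean(), 1.0)

    def test_zero_pixel_class_raises_with_name(self):
        masks = np.zeros((1, 4, 4, 4), dtype=np.uint8)
        masks[:, [0, 1, 3]] = 1
        with pytest.raises(ValueError, match="clavicles"):
            compute_class_weights(masks)


class TestFocalLoss:
    def test_perfect_prediction_is_zero(self):
        assert focal_loss(np.array([1.0]), np.array([1]), alpha=2.0, gamma=3.0) == pytest.approx(
            0.0, abs=1e-5
        )

    def test_gamma_zero_alpha_one_is_cross_entropy(self, rng):
        p = rng.uniform(0.05, 0.95, size=50)
        t = rng.integers(0, 2, size=50)
        p_t = np.where(t == 1, p, 1 - p)
        assert focal_loss(p, t, alpha=1.0, gamma=0.0) == pytest.approx(
            float(np.mean(-np.log(p_t)))
        )

    def test_closed_form_half_probability(self):
        # (1-0.5)^2 * (-ln 0.5) = 0.25 ln 2
        assert focal_loss(np.array([0.5]), np.array([1]), 1.0, 2.0) == pytest.approx(
            0.25 * np.log(2), rel=1e-6
        )

    def test_monotone_decreasing_in_p_t(self):
        ps = np.linspace(0.05, 0.95, 30)
        losses = [focal_loss(np.array([p]), np.array([1]), 1.0, 2.0) for p in ps]
        assert np.all(np.diff(losses) < 0)

    def test_bounded_by_weighted_cross_entropy(self, rng):
        p = rng.uniform(0.05, 0.95, size=100)
        t = rng.integers(0, 2, size=100)
        p_t = np.where(t == 1, p, 1 - p)
        ce = float(np.mean(-2.0 * np.log(p_t)))
        assert focal_loss(p, t, alpha=2.0, gamma=1.5) <= ce

    def test_rejects_bad_parameters(self):
        with pytest.raises(ValueError):
            focal_loss(np.array([0.5]), np.array([1]), alpha=1.0, gamma=-1.0)
        with pytest.raises(ValueError):
            focal_loss(np.array([0.5]), np.array([1]), alpha=0.0)


class TestPolyDecay:
    def test_endpoints_and_midpoint(self):
        cfg = TrainConfig(epochs=10, lr_initial=1e-3, lr_end=1e-5, power=1.0)
        assert poly_decay_lr(0, cfg) == pytest.approx(1e-3)
        assert poly_decay_lr(10, cfg) == pytest.approx(1e-5)
        assert poly_decay_lr(5, cfg) == pytest.approx((1e-3 + 1e-5) / 2)

    @pytest.mark.parametrize("power", [1.0, 2.0, 3.5])
    def test_monotone_nonincreasing(self, power):
        cfg = TrainConfig(epochs=20, power=power)
        lrs = [poly_decay_lr(s, cfg) for s in range(25)]
        assert np.all(np.diff(lrs) <= 1e-18)

    def test_clamps_beyond_decay_steps(self):
        cfg = TrainConfig(epochs=5)
        assert poly_decay_lr(100, cfg) == pytest.approx(cfg.lr_end)

    def test_zero_decay_steps_rejected(self):
        cfg = TrainConfig(epochs=5, decay_steps=0)
        with pytest.raises(ValueError):
            poly_decay_lr(1, cfg)


class TestUNet:
    def test_shape_contract_and_open_interval_outputs(self, rng):
        net = build_unet(UNetSpec(depth=2, base_filters=4, out_channels=4), seed=0)
        x = rng.uniform(size=(2, 1, 64, 64))
        out = net.forward(x)
        assert out.shape == (2, 4, 64, 64)
        assert (out > 0).all() and (out < 1).all()

    def test_zero_final_projection_gives_half_probability(self, rng):
        net = build_unet(UNetSpec(depth=1, base_filters=2, out_channels=3), seed=0)
        net.head.W[:] = 0.0
        net.head.b[:] = 0.0
        out = net.forward(rng.uniform(size=(1, 1, 16, 16)))
        assert np.allclose(out, 0.5)

    def test_rejects_indivisible_spatial_size(self, rng):
        net = build_unet(UNetSpec(depth=3, base_filters=2), seed=0)
        with pytest.raises(ValueError):
            net.forward(rng.uniform(size=(1, 1, 20, 20)))

    def test_backprop_matches_finite_differences(self, rng):
        """Analytic gradients agree with central differences on a tiny net.

        Biases are perturbed away from zero first: an exactly-zero
        pre-activation sits on the ReLU kink where the loss is not
        differentiable and finite differences are meaningless.
        """
        from cxrseg._nn import UNet

        net = UNet(depth=2, base_filters=2, in_channels=1, out_channels=3, seed=1)
        for layer in net._layers():
            layer.b[:] = rng.normal(0, 0.1, size=layer.b.shape)
        x = rng.uniform(0, 1, (2, 1, 8, 8))
        y = (rng.uniform(0, 1, (2, 3, 8, 8)) > 0.5).astype(int)
        alpha = np.array([0.7, 1.3, 1.0])

        def loss():
            return _focal_loss_and_grad(net.forward(x), y, alpha, 2.0)[0]

        _, d = _focal_loss_and_grad(net.forward(x), y, alpha, 2.0)
        net.zero_grad()
        net.backward(d)
        eps = 1e-6
        for layer in net._layers():
            for W, dW in layer.params():
                flat = W.reshape(-1)
                dflat = dW.reshape(-1)
                for k in rng.choice(flat.size, size=min(6, flat.size), replace=False):
                    old = flat[k]
                    flat[k] = old + eps
                    lp = loss()
                    flat[k] = old - eps
                    lm = loss()
                    flat[k] = old
                    num = (lp - lm) / (2 * eps)
                    assert num == pytest.approx(dflat[k], rel=5e-3, abs=1e-9)


@pytest.fixture(scope="module")
def trained():
    ds = generate_dataset(6, PhantomSpec(seed=21))
    cfg = TrainConfig(epochs=4, batch_size=2, seed=0,
                      enhance=EnhanceOptions(method="sobel"))
    model, history = train_model(ds, UNetSpec(depth=2, base_filters=4), cfg)
    return ds, cfg, model, history


class TestTraining:

    def test_history_bookkeeping(self, trained):
        _, cfg, _, history = trained
        assert len(history) == cfg.epochs
        assert history["lr"].iloc[0] == pytest.approx(cfg.lr_initial)
        assert history["lr"].iloc[-1] == pytest.approx(
            poly_decay_lr(cfg.epochs - 1, cfg)
        )

    def test_reproducible_under_seed(self, trained):
        ds, cfg, _, history = trained
        _, history2 = train_model(ds, UNetSpec(depth=2, base_filters=4), cfg)
        assert np.allclose(history["train_loss"], history2["train_loss"])

    def test_enhancement_never_touches_labels(self, trained):
        """Sobel enhancement changes the input tensor, not the mask tensor."""
        ds, _, _, _ = trained
        raw = ds.mask_tensor()
        digest_before = hashlib.sha256(raw.tobytes()).hexdigest()
        cfg = TrainConfig(epochs=1, seed=0, enhance=EnhanceOptions(method="sobel"))
        train_model(ds, UNetSpec(depth=2, base_filters=4), cfg)
        assert hashlib.sha256(ds.mask_tensor().tobytes()).hexdigest() == digest_before

    def test_empty_dataset_rejected(self):
        from cxrseg.datatypes import Dataset

        with pytest.raises(ValueError):
            train_model(Dataset([]), UNetSpec(), TrainConfig(epochs=1))

    def test_predict_masks_thresholds(self, trained):
        ds, _, model, _ = trained
        probs, masks = predict_masks(model, ds[0].image)
        assert probs.shape == (4, 64, 64)
        assert ((probs > 0) & (probs < 1)).all()
        _, ones = predict_masks(model, ds[0].image, threshold=0.0)
        assert ones.channels.all()
        # strict-inequality convention at exactly the threshold
        at_half = (np.full((4, 4), 0.5) > 0.5).astype(np.uint8)
        assert not at_half.any()
        # idempotence of binarization
        binary = masks.channels
        assert np.array_equal((binary > 0.5).astype(np.uint8), binary)

    def test_probabilities_exactly_at_threshold_map_to_zero(self, trained):
        """A zeroed final projection yields p = 0.5 everywhere, which the
        strict > 0.5 binarization maps to all-empty masks."""
        ds, _, model, _ = trained
        import copy

        frozen = copy.deepcopy(model)
        frozen.net_.head.W[:] = 0.0
        frozen.net_.head.b[:] = 0.0
        assert np.allclose(frozen.predict_proba(ds[0].image), 0.5)
        assert not frozen.predict(ds[0].image[None]).any()

    def test_checkpoint_round_trip(self, trained, tmp_path):
        ds, _, model, _ = trained
        path = tmp_path / "ckpt.npz"
        save_checkpoint(model, path)
        back = load_checkpoint(path)
        assert np.allclose(
            back.predict_proba(ds[0].image), model.predict_proba(ds[0].image)
        )

    def test_sklearn_param_round_trip(self):
        est = UNetSegmenter(depth=3, gamma=1.0)
        clone = UNetSegmenter(**est.get_params())
        assert clone.get_params() == est.get_params()
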