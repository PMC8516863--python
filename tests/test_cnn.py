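import numpy as np
import pytest

from ecgtfmap import nn
from ecgtfmap.cnn import (CnnConfig, ConvGroupSpec, build_model,
                          expected_param_count, fit_plain, predict,
                          predict_proba, train)


def _small_config(**kw):
    """Reduced-width architecture for fast training mechanics tests."""
    groups = [
        ConvGroupSpec(8, (3, 3), (1, 1), (2, 2), 0.0),
        ConvGroupSpec(8, (3, 3), (1, 1), (2, 2), 0.0),
        ConvGroupSpec(8, (2, 2), (1, 1), (2, 2), 0.0),
        ConvGroupSpec(8, (2, 2), (2, 2), None, 0.0),
    ]
    kw.setdefault("conv_groups", groups)
    kw.setdefault("input_size", 40)
    return CnnConfig(**kw)


def _rand_maps(rng, n, size=120, shift=0.0):
    return rng.random((n, size, size)) * 0.3 + shift


class TestArchitecture:
    def test_default_param_count_matches_layer_arithmetic(self):
        cfg = CnnConfig()
        model = build_model(cfg)
        # hand bookkeeping: conv (k*k*cin+1)*cout, BN 2*c, dense (din+1)*9
        conv = (3 * 3 * 1 + 1) * 128 + (3 * 3 * 128 + 1) * 64 \
            + (2 * 2 * 64 + 1) * 32 + (2 * 2 * 32 + 1) * 16
        bn = 2 * (128 + 64 + 32 + 16)
        # 120 -> pool 60 -> pool 30 -> pool 15 -> stride-2 "same" 8
        dense = (8 * 8 * 16 + 1) * 9
        assert model.n_params() == conv + bn + dense
        assert expected_param_count(cfg) == model.n_params()

    def test_param_count_oracle_for_other_configs(self):
        cfg = _small_config(n_classes=4)
        assert build_model(cfg).n_params() == expected_param_count(cfg)

    def test_two_class_head_width(self):
        cfg = CnnConfig(n_classes=2)
        model = build_model(cfg)
        p = predict(model, np.random.rand(120, 120))
        assert p.shape == (2,)

    def test_wrong_input_shape_rejected(self):
        model = build_model(CnnConfig())
        with pytest.raises(ValueError, match="120"):
            predict(model, np.random.rand(64, 64))


class TestPredict:
    def test_untrained_softmax_probabilities(self):
        model = build_model(CnnConfig(seed=1))
        p = predict(model, np.random.rand(120, 120))
        assert p.shape == (9,)
        assert np.all(p >= 0) and abs(p.sum() - 1.0) < 1e-5

    def test_all_zero_map_is_finite(self):
        model = build_model(CnnConfig(seed=1))
        p = predict(model, np.zeros((120, 120)))
        assert np.all(np.isfinite(p)) and abs(p.sum() - 1.0) < 1e-5

    def test_inference_is_deterministic(self):
        model = build_model(CnnConfig(seed=1))
        x = np.random.rand(120, 120)
        np.testing.assert_array_equal(predict(model, x), predict(model, x))


class TestGradients:
    """Finite-difference checks of each layer's backward pass."""

    @pytest.mark.parametrize("layer_fn,xshape", [
        (lambda rng: nn.Conv2D(2, 3, (3, 3), 1, l2=0.0, rng=rng), (2, 6, 6, 2)),
        (lambda rng: nn.Conv2D(2, 3, (2, 2), 2, l2=0.0, rng=rng), (2, 7, 7, 2)),
        (lambda rng: nn.BatchNorm(3), (2, 4, 4, 3)),
        (lambda rng: nn.Dense(5, 4, rng), (3, 5)),
        (lambda rng: nn.MaxPool2x2(), (2, 4, 4, 3)),
    ])
    def test_backward_matches_finite_differences(self, layer_fn, xshape):
        rng = np.random.default_rng(0)
        layer = layer_fn(rng)
        x = rng.standard_normal(xshape).astype(np.float32)
        out = layer.forward(x, True)
        gout = rng.standard_normal(out.shape).astype(np.float32)
        dx = layer.backward(gout)

        def scalar(xv):
            return float((layer.forward(xv, True) * gout).sum())

        flat = x.ravel()
        for k in rng.choice(flat.size, size=6, replace=False):
            eps, old = 1e-3, flat[k]
            flat[k] = old + eps
            lp = scalar(x)
            flat[k] = old - eps
            lm = scalar(x)
            flat[k] = old
            num = (lp - lm) / (2 * eps)
            got = dx.ravel()[k]
            assert abs(num - got) <= 1e-2 + 0.02 * (abs(num) + abs(got))


class TestTraining:
    def test_folds_must_be_at_least_two(self):
        model = build_model(_small_config())
        maps = np.random.rand(20, 40, 40)
        with pytest.raises(ValueError, match="folds"):
            train(model, maps, [0, 1] * 10, folds=1)

    def test_missing_class_raises_stratification_error(self):
        model = build_model(_small_config(n_classes=3))
        maps = np.random.rand(10, 40, 40)
        with pytest.raises(ValueError, match="stratification"):
            train(model, maps, [0] * 10, folds=2, epochs=1)

    def test_fold_sizes_partition_training_portion(self):
        rng = np.random.default_rng(0)
        cfg = _small_config(n_classes=2, seed=0, batch_size=16)
        model = build_model(cfg)
        maps = np.concatenate([_rand_maps(rng, 20, 40),
                               _rand_maps(rng, 20, 40, 0.5)])
        labels = [0] * 20 + [1] * 20
        model = train(model, maps, labels, split_seed=1, folds=4, epochs=1)
        folds = model.history["folds"]
        assert len(folds) == 4
        n_train_portion = 40 - len(model.test_indices)
        assert n_train_portion == 32
        assert sum(f["n_val"] for f in folds) == n_train_portion
        assert all(f["n_train"] + f["n_val"] == n_train_portion for f in folds)

    def test_separable_classes_learned_and_loss_decreases(self):
        rng = np.random.default_rng(3)
        cfg = _small_config(n_classes=2, seed=0, batch_size=8,
                            learning_rate=0.01)
        model = build_model(cfg)
        maps = np.concatenate([_rand_maps(rng, 8, 40),
                               _rand_maps(rng, 8, 40, 0.5)])
        labels = np.array([0] * 8 + [1] * 8)
        losses = fit_plain(model, maps, labels, epochs=15, seed=5)
        proba = predict_proba(model, maps)
        assert (proba.argmax(1) == labels).mean() >= 0.95
        # smoothed loss decreases from start to end
        assert np.mean(losses[-3:]) < np.mean(losses[:3])

    def test_overfit_toy_memorises_training_labels(self):
        rng = np.random.default_rng(4)
        cfg = _small_config(n_classes=3, seed=1, batch_size=6)
        model = build_model(cfg)
        maps = rng.random((6, 40, 40))
        labels = np.array([0, 1, 2, 0, 1, 2])
        fit_plain(model, maps, labels, epochs=60, seed=2)
        proba = predict_proba(model, maps)
        assert (proba.argmax(1) == labels).mean() == 1.0
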