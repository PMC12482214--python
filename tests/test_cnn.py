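"""The numpy CNN: architecture arithmetic, gradients, training regime."""

import numpy as np
import pytest

from mcsv.cnn import (
    CNNConfig,
    EarlyStopping,
    InputTensorSpec,
    ModelSizingError,
    SubbandEnsemble,
    ablation_variant,
    build_model,
    predict_proba,
    shallow_config,
    train,
)


def _chain_shapes(h, w, config):
    """Independent shape oracle: same-padding ceil arithmetic + floor pooling."""
    shapes = [(h, w, 1)]
    cin = 1
    for idx, (kh, kw, f, sh, sw) in enumerate(config.conv_specs):
        h, w = -(-h // sh), -(-w // sw)
        cin = f
        shapes.append((h, w, cin))
        if idx in config.pool_after:
            h, w = h // 2, w // 2
            shapes.append((h, w, cin))
    return shapes


def _param_count_oracle(h, w, config):
    total = 0
    cin = 1
    for idx, (kh, kw, f, sh, sw) in enumerate(config.conv_specs):
        total += kh * kw * cin * f + f
        h, w = -(-h // sh), -(-w // sw)
        cin = f
        if idx in config.pool_after:
            h, w = h // 2, w // 2
    n_in = h * w * cin
    for units in config.dense_units:
        total += n_in * units + units
        n_in = units
    total += n_in * config.n_classes + config.n_classes
    return total


class TestArchitecture:
    def test_layer_shapes_follow_stride_arithmetic(self):
        config = CNNConfig()
        model = build_model(InputTensorSpec(126, 64), config)
        assert model.layer_shapes == _chain_shapes(126, 64, config)
        # documented chain for the 126x64 input
        assert model.layer_shapes == [
            (126, 64, 1), (126, 64, 8), (63, 32, 8),
            (63, 11, 16), (31, 5, 16), (31, 2, 32),
        ]

    @pytest.mark.parametrize("h, w", [(126, 64), (48, 8), (21, 16)])
    def test_parameter_count_matches_closed_form(self, h, w):
        config = CNNConfig()
        model = build_model(InputTensorSpec(h, w), config)
        assert model.count_parameters() == _param_count_oracle(h, w, config)

    def test_same_seed_gives_identical_initial_weights(self):
        a = build_model(InputTensorSpec(24, 8), CNNConfig(seed=7))
        b = build_model(InputTensorSpec(24, 8), CNNConfig(seed=7))
        for wa, wb in zip(a.get_weights(), b.get_weights()):
            assert np.array_equal(wa, wb)

    def test_window_too_narrow_raises_sizing_error(self):
        with pytest.raises(ModelSizingError):
            build_model(InputTensorSpec(24, 4), CNNConfig())

    def test_input_spec_rejects_tiny_windows(self):
        with pytest.raises(ValueError):
            InputTensorSpec(24, 3)


class TestGradients:
    def test_backprop_matches_numerical_gradient(self, rng):
        config = CNNConfig(
            conv_specs=[(3, 3, 2, 1, 1), (3, 3, 3, 1, 2)],
            pool_after=(0,),
            dense_units=(8,),
            dropout=0.0,
            seed=0,
        )
        model = build_model(InputTensorSpec(8, 8), config)
        x = rng.normal(size=(4, 8, 8))
        y = np.array([0, 1, 0, 1])

        def loss():
            p = model.predict_proba(x)
            return -np.mean(np.log(p[np.arange(4), y] + 1e-12))

        logits = model.forward(model._as_nhwc(x), training=True)
        z = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(z)
        probs = e / e.sum(axis=1, keepdims=True)
        grad = probs
        grad[np.arange(4), y] -= 1
        grad /= 4
        for layer in reversed(model.layers):
            grad = layer.backward(grad)

        eps = 1e-5
        for name, owner in model._param_tensors():
            W, G = getattr(owner, name), getattr(owner, "d" + name)
            idx = tuple(rng.integers(0, s) for s in W.shape)
            W[idx] += eps
            hi = loss()
            W[idx] -= 2 * eps
            lo = loss()
            W[idx] += eps
            numeric = (hi - lo) / (2 * eps)
            assert numeric == pytest.approx(G[idx], rel=1e-4, abs=1e-8)


class TestEarlyStopping:
    def test_strictly_rising_error_stops_at_epoch_11(self):
        model = build_model(InputTensorSpec(8, 8), _tiny_config())
        X, y = _tiny_data()
        result = train(
            model, (X, y), (X, y), model.config,
            validation_metric=lambda m, epoch: 0.01 * epoch,
        )
        assert result.stopped_epoch == 11
        assert len(result.history["val_error"]) == 11

    def test_max_epochs_cap_honored(self):
        model = build_model(InputTensorSpec(8, 8), _tiny_config(max_epochs=1))
        X, y = _tiny_data()
        result = train(model, (X, y), (X, y), model.config)
        assert result.stopped_epoch == 1
        assert len(result.history["train_loss"]) == 1

    def test_plateau_does_not_stop(self):
        stopper = EarlyStopping(patience=3)
        assert not any(stopper.update(0.5) for _ in range(20))

    def test_counter_resets_on_improvement(self):
        stopper = EarlyStopping(patience=2)
        seq = [0.5, 0.6, 0.4, 0.5, 0.6]
        decisions = [stopper.update(e) for e in seq]
        assert decisions == [False, False, False, False, True]

    def test_single_class_training_set_rejected(self):
        model = build_model(InputTensorSpec(8, 8), _tiny_config())
        X, _ = _tiny_data()
        with pytest.raises(ValueError, match="both classes"):
            train(model, (X, np.zeros(len(X), dtype=int)), (X, np.zeros(len(X), dtype=int)))


def _tiny_config(**kw):
    return CNNConfig(
        conv_specs=[(3, 3, 2, 1, 1)], pool_after=(0,), dense_units=(8,), seed=0, **kw
    )


def _tiny_data():
    rng = np.random.default_rng(0)
    X = rng.normal(size=(40, 8, 8))
    y = np.tile([0, 1], 20)
    X[y == 1, :2, :] += 3.0
    return X, y


@pytest.fixture(scope="module")
def separable_run():
    rng = np.random.default_rng(3)
    X = rng.normal(size=(300, 24, 8))
    y = (rng.random(300) < 0.5).astype(int)
    X[y == 1, 4:8, :] += 3.0  # disjoint gamma-row ranges
    model = build_model(InputTensorSpec(24, 8), CNNConfig(seed=1, max_epochs=30))
    result = train(model, (X[:240], y[:240]), (X[240:], y[240:]))
    return model, result, X, y


class TestTrainingAndInference:
    def test_learns_separable_synthetic_maps(self, separable_run):
        model, result, X, y = separable_run
        assert result.stopped_epoch <= 150
        assert min(result.history["val_error"]) <= 0.05

    def test_probabilities_sum_to_one(self, separable_run, rng):
        model, *_ = separable_run
        p = model.predict_proba(rng.normal(size=(10, 24, 8)))
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-6)
        assert np.all((p >= 0) & (p <= 1))

    def test_duplicated_inputs_get_identical_outputs(self, separable_run, rng):
        model, *_ = separable_run
        x = rng.normal(size=(1, 24, 8))
        p = model.predict_proba(np.concatenate([x, x]))
        assert np.array_equal(p[0], p[1])

    def test_true_preictal_windows_score_higher(self, separable_run):
        model, _, X, y = separable_run
        probs = predict_proba(model, X[240:])
        assert probs[y[240:] == 1].mean() > probs[y[240:] == 0].mean()

    def test_shape_mismatch_rejected(self, separable_run):
        model, *_ = separable_run
        with pytest.raises(ValueError, match="do not match"):
            model.predict_proba(np.zeros((2, 10, 8)))


class TestAblationVariants:
    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            ablation_variant("bogus")

    def test_shallow_variant_has_strictly_fewer_parameters(self):
        full = build_model(InputTensorSpec(48, 8), CNNConfig(seed=0))
        shallow = build_model(InputTensorSpec(48, 8), shallow_config(CNNConfig(seed=0)))
        assert shallow.count_parameters() < full.count_parameters()
        assert ablation_variant("shallow")["conv_layers"] == 2

    def test_no_multiresolution_uses_single_band_row(self):
        assert ablation_variant("no_multiresolution")["bands"] == "fb"
        assert ablation_variant("no_multiresolution")["mraf"] is False

    def test_vote_fusion_breaks_ties_toward_interictal(self):
        class Stub:
            def __init__(self, p):
                self.p = p

            def predict_proba(self, x):
                return np.column_stack([np.full(len(x), 1 - self.p), np.full(len(x), self.p)])

        x = np.zeros((3, 4, 8))
        tie = SubbandEnsemble([Stub(0.9), Stub(0.1)], [slice(0, 2), slice(2, 4)], "vote")
        assert np.all(tie.predict_proba(x)[:, 1] == 0.0)  # 1-1 tie -> inter-ictal
        avg = SubbandEnsemble([Stub(0.9), Stub(0.1)], [slice(0, 2), slice(2, 4)], "average")
        assert np.allclose(avg.predict_proba(x)[:, 1], 0.5)
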