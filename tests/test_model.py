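"""Architecture tracing, parameter accounting, prediction contract, and
numerical correctness of the network engine."""

import numpy as np
import pytest

from afibnet import _nn
from afibnet.model import (
    LayerSpec,
    ModelConfig,
    build_model,
    count_parameters,
    format_trace,
    load_checkpoint,
    save_checkpoint,
    shape_trace,
)

# Published layer-by-layer contract of the full architecture:
# (name, output length, output channels, trainable parameters).
FULL_TRACE = [
    ("conv1", 2698, 64, 256),
    ("conv2", 2696, 64, 12352),
    ("maxpool1", 1348, 64, 0),
    ("conv3", 1346, 128, 24704),
    ("conv4", 1344, 128, 49280),
    ("maxpool2", 672, 128, 0),
    ("conv5", 670, 256, 98560),
    ("conv6", 668, 256, 196864),
    ("conv7", 666, 256, 196864),
    ("maxpool3", 333, 256, 0),
    ("conv8", 331, 512, 393728),
    ("conv9", 329, 512, 786944),
    ("conv10", 327, 512, 786944),
    ("maxpool4", 163, 512, 0),
    ("conv11", 161, 512, 786944),
    ("conv12", 159, 512, 786944),
    ("conv13", 157, 512, 786944),
    ("maxpool5", 78, 512, 0),
    ("flatten", 39936, 1, 0),
    ("dense1", 1000, 1, 39937000),
    ("dense2", 1000, 1, 1001000),
    ("output", 1, 1, 1001),
]
TOTAL_PARAMETERS = 45_846_329


class TestShapeTrace:
    def test_full_binary_architecture_row_for_row(self):
        rows = shape_trace(ModelConfig.afibnet(2))
        assert [(r.name, r.output_length, r.output_channels, r.parameters) for r in rows] == FULL_TRACE

    def test_total_parameter_count(self):
        assert count_parameters(ModelConfig.afibnet(2)) == TOTAL_PARAMETERS
        assert count_parameters(ModelConfig.afibnet(2)) == sum(r[3] for r in FULL_TRACE)

    def test_three_class_head_differs_only_in_output(self):
        rows2 = shape_trace(ModelConfig.afibnet(2))
        rows3 = shape_trace(ModelConfig.afibnet(3))
        assert [(r.name, r.parameters) for r in rows3[:-1]] == [(r.name, r.parameters) for r in rows2[:-1]]
        assert rows3[-1].output_length == 3
        assert rows3[-1].parameters == 1001 * 3

    def test_toy_single_conv(self):
        # one conv (1 filter, kernel 3) on a length-5 single-channel input:
        # output length 3, parameters 3 weights + 1 bias.
        cfg = ModelConfig(
            layers=(LayerSpec("conv", filters=1, activation="relu"),
                    LayerSpec("flatten"),
                    LayerSpec("output", units=1, activation="sigmoid")),
            n_classes=2, input_length=5)
        rows = shape_trace(cfg)
        assert (rows[0].output_length, rows[0].parameters) == (3, 4)

    def test_invalid_template_names_offending_layer(self):
        with pytest.raises(ValueError, match="layer 0"):
            ModelConfig(layers=(LayerSpec("conv", filters=8, kernel=5),
                                LayerSpec("flatten"),
                                LayerSpec("output", units=1)), n_classes=2)
        with pytest.raises(ValueError, match="output"):
            ModelConfig(layers=(LayerSpec("conv", filters=8),
                                LayerSpec("flatten"),
                                LayerSpec("output", units=3)), n_classes=2)

    def test_network_allocation_agrees_with_closed_form(self):
        cfg = ModelConfig.scaled(2)
        model = build_model(cfg, seed=0)
        assert model.network.n_parameters() == count_parameters(cfg)

    def test_format_trace_mentions_feature_reduction_end(self):
        text = format_trace(ModelConfig.afibnet(2))
        assert "maxpool5" in text and "78×512" in text and "45,846,329" in text


class TestPredict:
    @pytest.fixture(scope="class")
    def model(self):
        return build_model(ModelConfig.scaled(2), seed=7)

    def test_deterministic_probabilities(self, model, rng):
        x = rng.normal(size=(4, 2700))
        p1 = model.predict_proba(x)
        p2 = model.predict_proba(x)
        np.testing.assert_array_equal(p1, p2)

    def test_same_seed_same_weights(self, rng):
        a = build_model(ModelConfig.scaled(2), seed=3)
        b = build_model(ModelConfig.scaled(2), seed=3)
        for pa, pb in zip(a.network.params, b.network.params):
            np.testing.assert_array_equal(pa, pb)

    def test_probabilities_valid_and_sum_to_one(self, model, rng):
        p = model.predict_proba(rng.normal(size=(8, 2700)) * 5)
        assert np.all(np.isfinite(p)) and np.all((0 <= p) & (p <= 1))
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-12)

    def test_three_class_probabilities(self, rng):
        m = build_model(ModelConfig.scaled(3), seed=1)
        p = m.predict_proba(rng.normal(size=(5, 2700)))
        assert p.shape == (5, 3)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-12)

    def test_tie_breaks_toward_af(self, model, monkeypatch):
        monkeypatch.setattr(model, "predict_proba",
                            lambda v: np.array([[0.5, 0.5]]))
        _, labels = model.predict(np.zeros((1, 2700)))
        assert labels == ["AF"]

    def test_wrong_length_names_offending_index(self, model):
        good = np.zeros(2700)
        bad = np.zeros(100)
        with pytest.raises(ValueError, match="episode 1"):
            model.predict([good, bad])

    def test_batch_order_preserved(self, model, rng):
        x = rng.normal(size=(6, 2700))
        p = model.predict_proba(x)
        perm = [3, 1, 5, 0, 2, 4]
        p_perm = model.predict_proba(x[perm])
        np.testing.assert_allclose(p_perm, p[perm], rtol=1e-5)


class TestCheckpoint:
    def test_round_trip_preserves_predictions(self, tmp_path, rng):
        m = build_model(ModelConfig.scaled(2), seed=11)
        x = rng.normal(size=(3, 2700))
        path = tmp_path / "ckpt.npz"
        save_checkpoint(m, path)
        back = load_checkpoint(path)
        np.testing.assert_array_equal(back.predict_proba(x), m.predict_proba(x))
        assert back.config.to_dict() == m.config.to_dict()


class TestEngineGradients:
    def test_backprop_matches_finite_differences(self):
        """Analytic gradients of a small conv-pool-dense net agree with
        central finite differences on a weighted BCE objective."""
        rng = np.random.Generator(np.random.Philox(key=0))
        length = 20
        layers = [
            _nn.Conv1D(1, 3, 3, rng), _nn.ReLU(), _nn.MaxPool1D(),
            _nn.Conv1D(3, 4, 3, rng), _nn.ReLU(), _nn.MaxPool1D(),
            _nn.Flatten(), _nn.Dense(4 * 3, 5, rng), _nn.ReLU(),
            _nn.Dense(5, 1, rng),
        ]
        net = _nn.Sequential(layers)
        x = rng.normal(size=(4, length, 1)).astype(np.float32)
        y = np.array([0.0, 1.0, 1.0, 0.0])
        w = np.array([1.0, 2.0, 0.5, 1.0])

        logits = net.forward(x)
        _, grad = _nn.weighted_bce(logits, y, w)
        net.backward(grad.reshape(logits.shape))

        def loss():
            l, _ = _nn.weighted_bce(net.forward(x), y, w)
            return l

        worst = 0.0
        for p, g in zip(net.params, net.grads):
            flat, gflat = p.ravel(), g.ravel()
            for i in np.linspace(0, flat.size - 1, min(8, flat.size)).astype(int):
                orig = flat[i]
                flat[i] = orig + 1e-3
                lp = loss()
                flat[i] = orig - 1e-3
                lm = loss()
                flat[i] = orig
                num = (lp - lm) / 2e-3
                worst = max(worst, abs(num - gflat[i]) / max(1e-6, abs(num) + abs(gflat[i])))
        assert worst < 5e-3  # float32 finite-difference noise floor

    def test_softmax_cce_gradient(self):
        rng = np.random.Generator(np.random.Philox(key=1))
        net = _nn.Sequential([_nn.Dense(6, 3, rng)])
        x = rng.normal(size=(5, 6)).astype(np.float32)
        y = np.array([0, 1, 2, 1, 0])
        w = np.ones(5)
        logits = net.forward(x)
        _, grad = _nn.weighted_cce(logits, y, w)
        net.backward(grad)

        def loss():
            l, _ = _nn.weighted_cce(net.forward(x), y, w)
            return l

        p = net.params[0]
        flat, gflat = p.ravel(), net.grads[0].ravel()
        for i in range(0, flat.size, 5):
            orig = flat[i]
            flat[i] = orig + 1e-3
            lp = loss()
            flat[i] = orig - 1e-3
            lm = loss()
            flat[i] = orig
            num = (lp - lm) / 2e-3
            assert abs(num - gflat[i]) < 5e-3 * max(1.0, abs(num))
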