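import numpy as np
import pytest

from reedcover.cnn import ClassProbability, CNNClassifier, ModelSpec, build_model, softmax


class TestModelSpec:
    def test_flatten_length_traces_spatial_dims(self):
        # 32 -> conv(same) 32 -> pool 16 -> conv(same) 16 -> pool 8; 16 channels
        spec = ModelSpec(tile_size=32, conv_channels=(8, 16), kernel_size=3, pool_size=2)
        assert spec.flatten_length == 16 * 8 * 8 == 1024

    def test_minimum_tile_size_boundary(self):
        spec = ModelSpec(tile_size=4, pool_size=2)
        assert spec.feature_size == 1
        model = build_model(spec)
        x = np.zeros((1, 4, 4, 3))
        assert model.forward(x).shape == (1, 2)

    def test_incompatible_tile_size_names_minimum(self):
        with pytest.raises(ValueError, match="minimum admissible size 4"):
            ModelSpec(tile_size=6, pool_size=2)

    def test_binary_only(self):
        with pytest.raises(ValueError):
            ModelSpec(n_classes=3)


class TestDeterminism:
    def test_same_seed_bit_identical(self):
        a, b = build_model(ModelSpec(seed=9)), build_model(ModelSpec(seed=9))
        for k in a.params:
            np.testing.assert_array_equal(a.params[k], b.params[k])

    def test_different_seed_differs(self):
        a, b = build_model(ModelSpec(seed=1)), build_model(ModelSpec(seed=2))
        assert any(not np.array_equal(a.params[k], b.params[k]) for k in a.params)

    def test_parameter_count_is_reported(self):
        spec = ModelSpec()
        model = build_model(spec)
        expected = (
            3 * 9 * 8 + 8  # conv1
            + 8 * 9 * 16 + 16  # conv2
            + spec.flatten_length * 2 + 2  # fully connected
        )
        assert model.parameter_count == expected


class TestPredictProba:
    def test_probabilities_sum_to_one(self):
        model = build_model(ModelSpec(seed=0))
        rng = np.random.default_rng(0)
        tiles = rng.integers(0, 256, size=(5, 32, 32, 3), dtype=np.uint8)
        out = model.predict_proba(list(tiles))
        assert len(out) == 5
        for p in out:
            assert isinstance(p, ClassProbability)
            assert abs(p.p_reed + p.p_nonreed - 1.0) < 1e-6

    def test_zero_final_layer_gives_half_half(self):
        model = build_model(ModelSpec(seed=0))
        model.params["Wfc"][:] = 0.0
        model.params["bfc"][:] = 0.0
        probs = model.predict_proba_array(
            np.random.default_rng(1).integers(0, 256, (3, 32, 32, 3), dtype=np.uint8)
        )
        np.testing.assert_allclose(probs, 0.5, atol=1e-12)

    def test_scalar_chain_oracle(self):
        """1x1 kernels on a 1-channel constant tile reduce the whole forward
        pass to scalar arithmetic; check the network against that chain."""
        spec = ModelSpec(tile_size=4, in_channels=1, conv_channels=(1, 1), kernel_size=1)
        model = build_model(spec)
        a, b1, b, b2, wr, wn, br, bn = 1.7, 0.2, -0.8, 0.1, 0.9, -0.4, 0.05, -0.02
        model.params["W1"][:] = a
        model.params["b1"][:] = b1
        model.params["W2"][:] = b
        model.params["b2"][:] = b2
        model.params["Wfc"][:, 0] = wn
        model.params["Wfc"][:, 1] = wr
        model.params["bfc"][:] = [bn, br]
        for v in (0.0, 0.3, 1.0):
            h1 = max(a * v + b1, 0.0)  # conv1 + ReLU; pooling of a constant is identity
            h2 = max(b * h1 + b2, 0.0)
            ln, lr = wn * h2 + bn, wr * h2 + br
            expected = np.exp(lr) / (np.exp(lr) + np.exp(ln))
            tile = np.full((4, 4, 1), v)
            got = model.predict_proba_array(tile[None])[0, 1]
            assert got == pytest.approx(expected, abs=1e-12)

    def test_softmax_shift_invariance(self):
        model = build_model(ModelSpec(seed=3))
        x = np.random.default_rng(2).integers(0, 256, (2, 32, 32, 3), dtype=np.uint8)
        before = model.predict_proba_array(x)
        model.params["bfc"] += 17.0  # same constant on both logits
        np.testing.assert_allclose(model.predict_proba_array(x), before, atol=1e-9)

    def test_average_equals_max_pooling_on_constant_field(self):
        from reedcover.cnn import _pool_forward

        field = np.full((2, 8, 8, 3), 0.37)
        out_max, _ = _pool_forward(field, 2, "max")
        out_avg, _ = _pool_forward(field, 2, "average")
        np.testing.assert_allclose(out_max, out_avg, atol=1e-15)
        # and max dominates average on any non-negative field
        rng = np.random.default_rng(0)
        field = rng.uniform(0, 1, size=(2, 8, 8, 3))
        out_max, _ = _pool_forward(field, 2, "max")
        out_avg, _ = _pool_forward(field, 2, "average")
        assert (out_max >= out_avg).all()

    def test_batch_equals_single_tile_predictions(self):
        model = build_model(ModelSpec(seed=5))
        tiles = np.random.default_rng(3).integers(0, 256, (7, 32, 32, 3), dtype=np.uint8)
        batch = model.predict_proba_array(tiles)
        singles = np.concatenate([model.predict_proba_array(t[None]) for t in tiles])
        np.testing.assert_allclose(batch, singles, atol=1e-6)

    def test_shape_mismatch_names_shapes(self):
        model = build_model(ModelSpec(seed=0))
        with pytest.raises(ValueError, match=r"\(32, 32, 3\)"):
            model.predict_proba_array(np.zeros((1, 16, 16, 3)))


class TestGradients:
    def test_loss_gradients_match_finite_differences(self):
        spec = ModelSpec(tile_size=8, conv_channels=(2, 3), seed=11)
        model = build_model(spec)
        rng = np.random.default_rng(4)
        x = rng.uniform(0, 1, size=(4, 8, 8, 3))
        y = np.array([0, 1, 1, 0])
        _, grads = model.loss_and_grads(x, y)
        eps = 1e-6
        for name in ("W1", "b2", "Wfc", "bfc"):
            flat = model.params[name].ravel()
            idx = rng.integers(0, flat.size, size=min(5, flat.size))
            for i in idx:
                orig = flat[i]
                flat[i] = orig + eps
                lp, _ = model.loss_and_grads(x, y)
                flat[i] = orig - eps
                lm, _ = model.loss_and_grads(x, y)
                flat[i] = orig
                numeric = (lp - lm) / (2 * eps)
                assert grads[name].ravel()[i] == pytest.approx(numeric, rel=1e-4, abs=1e-7)


class TestCheckpoint:
    def test_round_trip(self, tmp_path):
        model = build_model(ModelSpec(seed=6, pooling="average"))
        path = tmp_path / "model.npz"
        model.save(path)
        loaded = CNNClassifier.load(path)
        assert loaded.spec == model.spec
        x = np.random.default_rng(5).integers(0, 256, (3, 32, 32, 3), dtype=np.uint8)
        np.testing.assert_array_equal(
            loaded.predict_proba_array(x), model.predict_proba_array(x)
        )


def test_softmax_rows_normalised():
    z = np.array([[1000.0, 1000.0], [-5.0, 3.0]])
    p = softmax(z)
    np.testing.assert_allclose(p.sum(axis=1), 1.0)
    np.testing.assert_allclose(p[0], [0.5, 0.5])
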