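"""Architecture assembly, the adaptive lambda schedule, gradient reversal."""

import math

import numpy as np
import pytest

from ecgadapt import nn
from ecgadapt.model import (DannModel, LambdaSchedule, NetworkConfig,
                            adaptive_lambda, grad_reverse)


class TestAdaptiveLambda:
    def test_initial_value_is_a(self):
        sch = LambdaSchedule(10, 10)
        assert adaptive_lambda(0, 0, sch) == 0.85

    def test_closed_form_spot_checks(self):
        sch = LambdaSchedule(10, 10)
        # p = 0.5 at b=0, E=5
        assert adaptive_lambda(0, 5, sch) == pytest.approx(
            0.85 * math.exp(2.75), abs=1e-9)
        # p = 1 at the final batch boundary
        assert adaptive_lambda(0, 10, sch) == pytest.approx(
            0.85 * math.exp(5.5), abs=1e-9)

    def test_monotone_in_batch_and_epoch(self):
        sch = LambdaSchedule(7, 5)
        vals = [adaptive_lambda(b, E, sch) for E in range(5) for b in range(7)]
        assert all(a <= b for a, b in zip(vals, vals[1:]))

    def test_progress_clipped_to_unit_interval(self):
        sch = LambdaSchedule(4, 3)
        assert adaptive_lambda(0, 99, sch) == pytest.approx(
            0.85 * math.exp(5.5), rel=1e-12)

    def test_invalid_schedule_rejected(self):
        with pytest.raises(ValueError):
            LambdaSchedule(0, 5)
        with pytest.raises(ValueError):
            LambdaSchedule(5, 5, a=-1.0)


class TestGradReverse:
    def test_forward_is_identity_bitwise(self):
        x = np.random.default_rng(0).standard_normal(10)
        out, layer = grad_reverse(x, 2.0)
        assert out is x or np.array_equal(out, x)

    def test_backward_flips_sign_and_scales(self):
        _, layer = grad_reverse(np.zeros(2), 2.0)
        g = np.array([1.0, -2.0])
        np.testing.assert_array_equal(layer.backward(g), [-2.0, 4.0])

    def test_zero_lambda_zeroes_gradient(self):
        _, layer = grad_reverse(np.zeros(3), 0.0)
        np.testing.assert_array_equal(layer.backward(np.ones(3)), np.zeros(3))

    def test_gradient_against_finite_differences(self):
        """d/dx L(grad_reverse(x, lam)) must equal -lam * dL/dx."""
        rng = np.random.default_rng(1)
        for lam in (0.5, 1.0, 3.7):
            x = rng.standard_normal(10)
            w = rng.standard_normal(10)

            def loss(v):
                return float(np.sum(np.tanh(v) * w))

            _, layer = grad_reverse(x, lam)
            upstream = np.cosh(x) ** -2 * w  # dL/dy at y = x
            analytic = layer.backward(upstream)
            eps = 1e-6
            fd = np.array([
                (loss(x + eps * e) - loss(x - eps * e)) / (2 * eps)
                for e in np.eye(10)
            ])
            np.testing.assert_allclose(analytic, -lam * fd, rtol=1e-4)


class TestNetworkConfig:
    def test_full_scale_spatial_recursion(self):
        cfg = NetworkConfig.full()
        assert cfg.spatial_dims() == (14, 26)
        assert cfg.feature_dim() == 14 * 26 * 512 == 186368

    def test_quarter_resolution_spatial_recursion(self):
        cfg = NetworkConfig(input_h=220, input_w=412)
        assert cfg.spatial_dims() == (4, 7)
        assert cfg.feature_dim() == 4 * 7 * 512 == 14336

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            NetworkConfig(channels=(8, 16), strides=(1,))
        with pytest.raises(ValueError):
            NetworkConfig(dropout_p=1.0)
        with pytest.raises(ValueError):
            NetworkConfig(strides=(0,) * 7)


@pytest.fixture(scope="module")
def tiny_model():
    cfg = NetworkConfig(input_h=24, input_w=40, channels=(4, 8),
                        strides=(2, 2), kernel=7, dropout_p=0.25, seed=3)
    return DannModel(cfg)


class TestDannModel:
    def test_batch_rows_preserved_and_finite(self, tiny_model):
        X = np.random.default_rng(0).random((5, 24, 40, 3), dtype=np.float32)
        f = tiny_model.feature_extractor_forward(X)
        assert f.shape == (5, tiny_model.config.feature_dim())
        assert np.all(np.isfinite(f))

    def test_eval_forward_bitwise_deterministic(self, tiny_model):
        X = np.random.default_rng(1).random((4, 24, 40, 3), dtype=np.float32)
        a = tiny_model.predict_proba(X)
        b = tiny_model.predict_proba(X)
        assert np.array_equal(a, b)

    def test_heads_output_open_unit_interval(self, tiny_model):
        X = np.random.default_rng(2).random((3, 24, 40, 3), dtype=np.float32)
        f = tiny_model.feature_extractor_forward(X)
        for probs in (tiny_model.label_head_forward(f),
                      tiny_model.domain_head_forward(f)):
            assert np.all((probs > 0) & (probs < 1))

    def test_zero_head_weights_give_half(self, tiny_model):
        f = np.random.default_rng(3).standard_normal(
            (4, tiny_model.config.feature_dim())).astype(np.float32)
        saved = [p.copy() for p in tiny_model.label_head.params]
        for p in tiny_model.label_head.params:
            p[...] = 0
        np.testing.assert_allclose(tiny_model.label_head_forward(f), 0.5)
        for p, s in zip(tiny_model.label_head.params, saved):
            p[...] = s

    def test_large_logit_saturates(self, tiny_model):
        f = np.ones((1, tiny_model.config.feature_dim()), dtype=np.float32)
        saved = [p.copy() for p in tiny_model.label_head.params]
        tiny_model.label_head.params[0][...] = 1.0
        assert tiny_model.label_head_forward(f)[0] == pytest.approx(1.0)
        for p, s in zip(tiny_model.label_head.params, saved):
            p[...] = s

    def test_batch_permutation_equivariance(self, tiny_model):
        X = np.random.default_rng(4).random((6, 24, 40, 3), dtype=np.float32)
        perm = np.array([3, 1, 5, 0, 2, 4])
        a = tiny_model.predict_proba(X)[perm]
        b = tiny_model.predict_proba(X[perm])
        np.testing.assert_allclose(a, b, atol=1e-6)

    def test_seeded_init_reproducible(self):
        cfg = NetworkConfig(input_h=24, input_w=40, channels=(4,),
                            strides=(2,), seed=7)
        a, b = DannModel(cfg), DannModel(cfg)
        for pa, pb in zip(a._param_arrays(), b._param_arrays()):
            assert np.array_equal(pa, pb)

    def test_checkpoint_round_trip(self, tiny_model, tmp_path):
        path = tmp_path / "ckpt.npz"
        tiny_model.save(path)
        back = DannModel.load(path)
        assert back.config == tiny_model.config
        X = np.random.default_rng(5).random((3, 24, 40, 3), dtype=np.float32)
        np.testing.assert_array_equal(back.predict_proba(X),
                                      tiny_model.predict_proba(X))

    def test_wrong_input_size_rejected(self, tiny_model):
        with pytest.raises(ValueError):
            tiny_model.feature_extractor_forward(
                np.zeros((1, 10, 10, 3), dtype=np.float32))
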