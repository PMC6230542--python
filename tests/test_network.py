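"""Encoder-decoder architecture contracts and gradient correctness."""

import numpy as np
import pytest

from oracles import closed_form_param_count

from pseudoct.nn import (
    Adam, EncoderDecoder, NetworkSpec, build_network, load_checkpoint,
    save_checkpoint)

REDUCED = NetworkSpec.reduced()  # stages (1,16),(1,32),(2,64)
TINY = NetworkSpec.reduced(stages=((1, 4), (1, 6)))


class TestBuild:
    @pytest.mark.parametrize("shape", [(32, 32), (64, 64), (32, 64)])
    def test_output_shape_equals_input_shape(self, shape, rng):
        net = build_network(REDUCED, shape, seed=0)
        x = rng.normal(size=(2, 1, *shape)).astype(np.float32) * 0.3
        assert net.forward(x).shape == x.shape

    def test_indivisible_shape_rejected_with_valid_sizes(self):
        with pytest.raises(ValueError, match="divisible"):
            EncoderDecoder(REDUCED, (50, 50))

    def test_parameter_count_matches_closed_form(self):
        for spec in (TINY, REDUCED):
            net = EncoderDecoder(spec, (32, 32))
            assert net.param_count() == closed_form_param_count(spec)

    def test_internal_shortcuts_are_parameter_free(self):
        with_sc = EncoderDecoder(REDUCED, (32, 32))
        without = EncoderDecoder(
            NetworkSpec.reduced(shortcut_stages=()), (32, 32))
        assert with_sc.param_count() == without.param_count()

    def test_full_scale_spec_invariants(self):
        spec = NetworkSpec()
        assert spec.n_conv_layers == 13
        assert spec.stages[0][1] == 64 and max(f for _, f in spec.stages) == 512
        assert len(spec.resolved_shortcuts()) == 4
        assert spec.is_full_scale

    def test_stage_resolution_halves_each_stage(self, rng):
        net = build_network(REDUCED, (64, 64), seed=0)
        x = rng.normal(size=(1, 1, 64, 64)).astype(np.float32)
        h = x
        for s, units in enumerate(net.enc):
            for conv, bn, relu in units:
                h = relu.forward(bn.forward(conv.forward(h)))
            assert h.shape[2] == 64 // 2**s
            h = net.pools[s].forward(h)


class TestInit:
    def test_same_seed_identical_weights(self):
        n1 = build_network(REDUCED, (32, 32), seed=9)
        n2 = build_network(REDUCED, (32, 32), seed=9)
        for (a, pa, _), (b, pb, _) in zip(n1.parameters(), n2.parameters()):
            assert a == b
            np.testing.assert_array_equal(pa, pb)

    def test_he_std_matches_fan_in(self):
        net = build_network(REDUCED, (32, 32), seed=4)
        conv = net.enc[2][0][0]  # 3x3, 32 input channels -> fan_in 288
        w = conv.params["W"]
        expected = np.sqrt(2.0 / (9 * conv.in_ch))
        assert abs(w.std() - expected) / expected < 0.2

    def test_batchnorm_init_scale_one_shift_zero(self):
        net = build_network(REDUCED, (32, 32), seed=4)
        for name, p, _ in net.parameters():
            if name.endswith(".beta"):
                assert (p == 0).all()
            if name.endswith(".gamma"):
                assert (p == 1).all()


class TestPredict:
    def test_inference_is_deterministic(self, rng):
        net = build_network(REDUCED, (32, 32), seed=2)
        x = rng.normal(size=(32, 32)) * 0.3
        np.testing.assert_array_equal(net.predict(x), net.predict(x))

    def test_batch_matches_single_slice_calls(self, rng):
        net = build_network(REDUCED, (32, 32), seed=2)
        xs = rng.normal(size=(3, 32, 32)) * 0.3
        batch = net.predict(xs)
        for i in range(3):
            np.testing.assert_allclose(batch[i], net.predict(xs[i]),
                                       rtol=1e-5, atol=1e-6)

    def test_zero_final_conv_with_input_shortcut_is_identity(self, rng):
        net = build_network(REDUCED, (32, 32), seed=1)
        net.final_conv.params["W"][...] = 0.0
        net.final_conv.params["b"][...] = 0.0
        x = (rng.normal(size=(32, 32)) * 0.3).astype(np.float32)
        np.testing.assert_array_equal(net.predict(x), x)

    def test_predict_pads_and_crops_odd_sizes(self, rng):
        net = build_network(REDUCED, (48, 48), seed=1)
        x = rng.normal(size=(40, 44)) * 0.2
        out = net.predict(x)
        assert out.shape == (40, 44)

    def test_checkpoint_round_trip(self, tmp_path, rng):
        net = build_network(REDUCED, (32, 32), seed=7)
        x = rng.normal(size=(32, 32)) * 0.3
        save_checkpoint(net, tmp_path / "ck.npz")
        restored = load_checkpoint(tmp_path / "ck.npz")
        np.testing.assert_array_equal(net.predict(x), restored.predict(x))


class TestGradients:
    def test_backward_matches_finite_differences(self):
        """Analytic gradients of the full network (conv, batch-norm,
        pooling, un-pooling, shortcuts) against central differences."""
        net = EncoderDecoder(TINY, (8, 8), dtype=np.float64).initialize_weights(3)
        rng = np.random.default_rng(0)
        x = rng.normal(size=(3, 1, 8, 8)) * 0.4
        t = rng.normal(size=(3, 1, 8, 8)) * 0.4

        net.zero_grad()
        y = net.forward(x, train=True)
        net.backward(2 * (y - t) / t.size)
        grads = {n: g.copy() for n, _, g in net.parameters()}

        def loss():
            return float(((net.forward(x, train=True) - t) ** 2).mean())

        for name, p, _ in net.parameters():
            flat = p.ravel()
            for idx in rng.choice(flat.size, size=min(3, flat.size), replace=False):
                eps, orig = 1e-6, flat[idx]
                flat[idx] = orig + eps
                lp = loss()
                flat[idx] = orig - eps
                lm = loss()
                flat[idx] = orig
                num = (lp - lm) / (2 * eps)
                assert grads[name].ravel()[idx] == pytest.approx(num, abs=1e-7, rel=1e-4)

    def test_gradient_reaches_first_conv_layer(self, rng):
        """Shortcut connections keep the early layers trainable: the loss
        gradient at the first convolution is nonzero at initialisation."""
        net = build_network(REDUCED, (32, 32), seed=6)
        x = (rng.normal(size=(4, 1, 32, 32)) * 0.3).astype(np.float32)
        t = (rng.normal(size=(4, 1, 32, 32)) * 0.3).astype(np.float32)
        net.zero_grad()
        y = net.forward(x, train=True)
        net.backward(2 * (y - t) / t.size)
        first_conv_grad = net.enc[0][0][0].grads["W"]
        assert np.abs(first_conv_grad).max() > 0


def test_adam_reduces_loss_on_quadratic(rng):
    net = EncoderDecoder(TINY, (8, 8), dtype=np.float64).initialize_weights(0)
    x = rng.normal(size=(4, 1, 8, 8)) * 0.3
    t = rng.normal(size=(4, 1, 8, 8)) * 0.3
    opt = Adam(net, lr=0.01)
    losses = []
    for _ in range(30):
        net.zero_grad()
        y = net.forward(x, train=True)
        losses.append(float(((y - t) ** 2).mean()))
        net.backward(2 * (y - t) / t.size)
        opt.step()
    assert losses[-1] < losses[0]
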