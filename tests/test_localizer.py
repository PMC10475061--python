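import numpy as np
import pytest

from svpnet import localizer as loc
from svpnet.errors import ContractError
from svpnet.nn import tensor as T

from .oracles import attention_gate_loop, depthwise_separable_loop, rr_block_unrolled


@pytest.fixture()
def rng():
    return np.random.default_rng(31337)


class TestDepthwiseSeparableConv:
    def test_identity_kernels_reproduce_input(self, rng):
        x = rng.random((3, 6, 6))
        delta = np.zeros((3, 3, 3))
        delta[:, 1, 1] = 1.0
        out = loc.depthwise_separable_conv(x, delta, np.eye(3))
        assert np.allclose(out, x, atol=1e-12)

    def test_matches_nested_loop_oracle(self, rng):
        x = rng.normal(size=(3, 8, 8))
        dw = rng.normal(size=(3, 3, 3))
        pw = rng.normal(size=(5, 3))
        b = rng.normal(size=5)
        ours = loc.depthwise_separable_conv(x, dw, pw, b)
        ref = depthwise_separable_loop(x, dw, pw, b)
        assert np.abs(ours - ref).max() <= 1e-6

    def test_parameter_count_closed_form(self):
        assert loc.separable_conv_param_count(4, 8, 3) == 4 * 9 + 4 * 8 == 68
        assert loc.full_conv_param_count(4, 8, 3) == 288
        assert loc.separable_conv_param_count(4, 8, 3) < loc.full_conv_param_count(4, 8, 3)

    def test_kernel_channel_mismatch_raises(self, rng):
        with pytest.raises(ContractError):
            loc.depthwise_separable_conv(rng.random((3, 4, 4)),
                                         rng.random((2, 3, 3)),
                                         np.eye(3))


class TestRecurrentResidualBlock:
    def _params(self, rng, c=3):
        return {"depthwise": rng.normal(size=(c, 3, 3)) * 0.3,
                "pointwise": rng.normal(size=(c, c)) * 0.3,
                "bias": rng.normal(size=c) * 0.1}

    def test_zero_weights_identity_residual_passes_input(self, rng):
        x = rng.random((2, 5, 5))
        params = {"depthwise": np.zeros((2, 3, 3)),
                  "pointwise": np.zeros((2, 2))}
        out = loc.recurrent_residual_block(x, params, t=1)
        assert np.allclose(out, x)

    def test_t0_equals_manual_composition(self, rng):
        x = rng.random((3, 6, 6))
        params = self._params(rng)
        out = loc.recurrent_residual_block(x, params, t=0)
        g = np.maximum(loc.depthwise_separable_conv(
            x, params["depthwise"], params["pointwise"], params["bias"]), 0.0)
        assert np.allclose(out, x + g, atol=1e-12)

    def test_t1_matches_unrolled_oracle(self, rng):
        x = rng.normal(size=(3, 6, 6))
        params = self._params(rng)
        ours = loc.recurrent_residual_block(x, params, t=1)
        ref = rr_block_unrolled(x, params, t=1)
        assert np.abs(ours - ref).max() <= 1e-6

    def test_projection_residual(self, rng):
        x = rng.normal(size=(2, 4, 4))
        params = {"depthwise": np.zeros((2, 3, 3)),
                  "pointwise": np.zeros((2, 2)),
                  "proj": rng.normal(size=(2, 2))}
        out = loc.recurrent_residual_block(x, params, t=2)
        assert np.allclose(out, np.einsum("oc,chw->ohw", params["proj"], x))


class TestAttentionGate:
    def _params(self, rng, cu=3, cg=2, ci=2):
        return loc.AttentionGateParams(
            W_u=rng.normal(size=(ci, cu)), W_g=rng.normal(size=(ci, cg)),
            b_g=rng.normal(size=ci), psi=rng.normal(size=ci),
            b_psi=float(rng.normal()))

    def test_all_zero_params_halve_input(self, rng):
        u = rng.random((3, 4, 4))
        g = rng.random((2, 4, 4))
        params = loc.AttentionGateParams(
            W_u=np.zeros((2, 3)), W_g=np.zeros((2, 2)),
            b_g=np.zeros(2), psi=np.zeros(2), b_psi=0.0)
        out = loc.attention_gate(u, g, params)
        assert np.allclose(out, 0.5 * u)

    def test_large_bias_saturates_to_identity(self, rng):
        u = rng.random((3, 4, 4))
        g = rng.random((2, 4, 4))
        params = self._params(rng)
        params.b_psi = 100.0
        params.psi = np.zeros_like(params.psi)
        out = loc.attention_gate(u, g, params)
        assert np.abs(out - u).max() <= 1e-6

    def test_matches_scalar_loop_oracle(self, rng):
        u = rng.normal(size=(3, 5, 5))
        g = rng.normal(size=(2, 5, 5))
        p = self._params(rng)
        ours = loc.attention_gate(u, g, p)
        ref = attention_gate_loop(u, g, p.W_u, p.W_g, p.b_g, p.psi, p.b_psi)
        assert np.abs(ours - ref).max() <= 1e-6

    def test_coarser_gate_is_upsampled(self, rng):
        u = rng.random((3, 8, 8))
        g = rng.random((2, 4, 4))
        out = loc.attention_gate(u, g, self._params(rng))
        assert out.shape == u.shape

    def test_gated_output_bounded_by_input(self, rng):
        u = rng.normal(size=(3, 6, 6))
        g = rng.normal(size=(2, 6, 6))
        out = loc.attention_gate(u, g, self._params(rng))
        assert np.all(np.abs(out) <= np.abs(u) + 1e-12)

    def test_mismatched_intermediate_channels_rejected(self, rng):
        params = loc.AttentionGateParams(
            W_u=np.zeros((2, 3)), W_g=np.zeros((3, 2)),
            b_g=np.zeros(2), psi=np.zeros(2), b_psi=0.0)
        with pytest.raises(ContractError):
            loc.attention_gate(rng.random((3, 4, 4)), rng.random((2, 4, 4)),
                               params)


class TestDiceLoss:
    def test_perfect_overlap_near_zero(self):
        mask = np.zeros((8, 8))
        mask[2:5, 2:5] = 1
        assert loc.dice_loss(mask, mask) < 1e-6

    def test_disjoint_masks_near_one(self):
        a = np.zeros((8, 8))
        b = np.zeros((8, 8))
        a[:2] = 1
        b[6:] = 1
        assert loc.dice_loss(a, b) > 1 - 1e-6

    def test_hand_arithmetic(self):
        pred = np.array([1.0, 1.0, 0.0, 0.0])
        target = np.array([1.0, 0.0, 1.0, 0.0])
        assert loc.dice_loss(pred, target) == pytest.approx(0.5, abs=1e-6)

    def test_symmetry_and_range(self):
        rng = np.random.default_rng(5)
        for _ in range(25):
            a = (rng.random((6, 6)) > 0.5).astype(float)
            b = (rng.random((6, 6)) > 0.5).astype(float)
            lab = loc.dice_loss(a, b)
            assert lab == pytest.approx(loc.dice_loss(b, a), abs=1e-12)
            assert 0.0 <= lab <= 1.0

    def test_shape_mismatch_raises(self):
        with pytest.raises(ContractError):
            loc.dice_loss(np.zeros((2, 2)), np.zeros((3, 3)))

    def test_tensor_path_matches_numpy_path(self):
        rng = np.random.default_rng(8)
        pred = rng.random((5, 5))
        target = (rng.random((5, 5)) > 0.5).astype(float)
        tensor_val = float(loc.dice_loss(T.Tensor(pred), target).data)
        assert tensor_val == pytest.approx(loc.dice_loss(pred, target), abs=1e-9)


class TestLocalizerModel:
    def test_output_shape_equals_input_shape(self):
        for depth, size in ((2, 16), (3, 24)):
            cfg = loc.LocalizerConfig(depth=depth, base_filters=4,
                                      input_size=size, epochs=1)
            model = loc.build_localizer(cfg)
            x = np.random.default_rng(0).random((2, 1, size, size))
            out = model(T.Tensor(x))
            assert out.shape == (2, 1, size, size)
            assert np.all(out.data > 0) and np.all(out.data < 1)

    def test_indivisible_input_size_rejected(self):
        with pytest.raises(ContractError):
            loc.build_localizer(loc.LocalizerConfig(depth=4, input_size=100))

    def test_separable_model_smaller_than_full_conv_equivalent(self):
        cfg = loc.LocalizerConfig(depth=2, base_filters=4, input_size=16)
        model = loc.build_localizer(cfg)
        total_sep = 0
        total_full = 0
        for name, p in model.named_parameters().items():
            total_sep += p.data.size
            if name.endswith("depthwise"):
                c, kh, kw = p.data.shape
                total_full += c * kh * kw          # per-channel kernels
            elif name.endswith("pointwise"):
                cout, cin = p.data.shape[:2]
                # the same mixing realized inside a full conv costs k^2 more
                total_full += cout * cin * 9
            else:
                total_full += p.data.size
        assert total_sep < total_full

    def test_predict_mask_zeroed_head_gives_all_ones(self):
        cfg = loc.LocalizerConfig(depth=2, base_filters=4, input_size=16)
        model = loc.build_localizer(cfg)
        model.head.weight.data[:] = 0.0
        model.head.bias.data[:] = 0.0
        mask = loc.predict_mask(model, np.random.default_rng(0).random((16, 16)))
        # sigmoid(0) = 0.5 and the threshold rule is ">=", so everything is on
        assert np.all(mask == 1)

    def test_predict_mask_dims_follow_frame(self):
        cfg = loc.LocalizerConfig(depth=2, base_filters=4, input_size=16)
        model = loc.build_localizer(cfg)
        mask = loc.predict_mask(model, np.zeros((40, 50)))
        assert mask.shape == (40, 50)
        assert set(np.unique(mask)) <= {0, 1}

    def test_non_2d_input_rejected(self):
        cfg = loc.LocalizerConfig(depth=2, base_filters=4, input_size=16)
        model = loc.build_localizer(cfg)
        with pytest.raises(ContractError):
            loc.predict_mask(model, np.zeros((2, 3, 4, 5)))


class TestSplit:
    def test_75_20_5_floor_remainder_to_train(self):
        rng = np.random.default_rng(0)
        train, val, test = loc.split_75_20_5(40, rng)
        assert len(val) == 8 and len(test) == 2 and len(train) == 30
        all_idx = np.sort(np.concatenate([train, val, test]))
        assert np.array_equal(all_idx, np.arange(40))

    def test_split_is_seed_deterministic(self):
        a = loc.split_75_20_5(23, np.random.default_rng(9))
        b = loc.split_75_20_5(23, np.random.default_rng(9))
        for x, y in zip(a, b):
            assert np.array_equal(x, y)


class TestTraining:
    def test_loss_decreases_and_deterministic(self):
        from svpnet import phantom as ph
        images, _ = ph.make_dataset(12, 0, seed=3)
        cfg = loc.LocalizerConfig(depth=2, base_filters=4, input_size=128,
                                  epochs=3, batch_size=4, seed=1)
        _, hist1 = loc.train_localizer(images, cfg)
        _, hist2 = loc.train_localizer(images, cfg)
        assert min(hist1["train_loss"]) < hist1["train_loss"][0] + 1e-9
        assert hist1["train_loss"] == hist2["train_loss"]
        assert hist1["val_loss"] == hist2["val_loss"]

    def test_checkpoint_roundtrip(self, tmp_path):
        cfg = loc.LocalizerConfig(depth=2, base_filters=4, input_size=16)
        model = loc.build_localizer(cfg)
        loc.save_localizer(tmp_path / "ckpt.npz", model)
        loaded = loc.load_localizer(tmp_path / "ckpt.npz")
        x = np.random.default_rng(1).random((1, 1, 16, 16))
        assert np.allclose(model.eval()(T.Tensor(x)).data,
                           loaded(T.Tensor(x)).data)
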