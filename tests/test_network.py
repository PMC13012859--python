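"""CRFE architecture: shapes, attention semantics, recurrent symmetry."""

import numpy as np
import pytest

from crferad.autograd import Tensor
from crferad.network import CRFENet, SegmentationModelSpec, relu, sigmoid
from oracles import attention_bruteforce

TINY = SegmentationModelSpec(
    input_size=64, encoder_channels=(4, 8, 16), recurrent_units=8, seed=0
)


@pytest.fixture(scope="module")
def net():
    return CRFENet(TINY)


class TestActivations:
    @pytest.mark.parametrize("x,expected", [(-3.0, 0.0), (5.0, 5.0), (0.0, 0.0)])
    def test_relu_values(self, x, expected):
        assert relu(x) == expected

    def test_sigmoid_midpoint_and_symmetry(self, rng):
        assert sigmoid(0.0) == 0.5
        x = rng.normal(size=100) * 5
        assert np.allclose(sigmoid(x) + sigmoid(-x), 1.0)


class TestEncoder:
    def test_pyramid_shapes(self, net, rng):
        x = Tensor(rng.normal(size=(2, 1, 64, 64)))
        deepest, skips = net.encode(x)
        assert deepest.data.shape == (2, 16, 8, 8)
        assert [s.data.shape for s in skips] == [
            (2, 4, 64, 64), (2, 8, 32, 32), (2, 16, 16, 16)
        ]

    def test_indivisible_side_rejected(self, net, rng):
        with pytest.raises(ValueError):
            net.encode(Tensor(rng.normal(size=(1, 1, 60, 60))))

    def test_full_scale_shape_arithmetic(self):
        spec = SegmentationModelSpec(seed=0)
        net = CRFENet(spec)
        x = Tensor(np.zeros((1, 1, 256, 256)))
        deepest, _ = net.encode(x)
        assert deepest.data.shape == (1, 128, 32, 32)


class TestRecurrentContext:
    def test_output_shape_matches_input(self, net, rng):
        f = Tensor(rng.normal(size=(2, 16, 8, 8)))
        out = net.recurrent_context(f)
        assert out.data.shape == f.data.shape

    def test_zero_input_zero_params_gives_zero(self):
        net = CRFENet(TINY)
        for k, p in net.params.items():
            if k.startswith(("lstm", "ctx_proj")):
                p.data = np.zeros_like(p.data)
        out = net.recurrent_context(Tensor(np.zeros((1, 16, 4, 4))))
        assert np.allclose(out.data, 0.0)

    def test_direction_swap_symmetry(self, rng):
        """Reversing the serialized sequence while swapping the forward and
        backward parameter sets must reverse the fused sequence."""
        net = CRFENet(TINY)
        f = rng.normal(size=(1, 16, 2, 4))
        out = net.recurrent_context(Tensor(f))
        swapped = CRFENet(TINY)
        swapped.load_state_dict(net.state_dict())
        for nm in ("wx", "wh", "b"):
            a = swapped.params[f"lstm_fwd_{nm}"].data.copy()
            swapped.params[f"lstm_fwd_{nm}"].data = swapped.params[f"lstm_bwd_{nm}"].data.copy()
            swapped.params[f"lstm_bwd_{nm}"].data = a
        rev = f.reshape(1, 16, 8)[:, :, ::-1].reshape(1, 16, 2, 4)
        out_rev = swapped.recurrent_context(Tensor(rev))
        back = out_rev.data.reshape(1, 16, 8)[:, :, ::-1].reshape(1, 16, 2, 4)
        assert np.allclose(out.data, back, atol=1e-10)


class TestPositionAttention:
    def test_alpha_zero_is_identity(self, net, rng):
        a = Tensor(rng.normal(size=(2, 16, 4, 4)))
        e = net.position_attention(a)
        assert np.array_equal(e.data, a.data)

    def test_constant_input_gives_uniform_attention(self, net):
        a = Tensor(np.ones((1, 16, 3, 3)) * 0.7)
        bm = np.einsum("oc,bchw->bohw", net.params["att_b_w"].data[:, :, 0, 0],
                       a.data) + net.params["att_b_b"].data[None, :, None, None]
        cm = np.einsum("oc,bchw->bohw", net.params["att_c_w"].data[:, :, 0, 0],
                       a.data) + net.params["att_c_b"].data[None, :, None, None]
        scores = np.einsum("bci,bcj->bji", bm.reshape(1, 16, 9), cm.reshape(1, 16, 9))
        s = np.exp(scores - scores.max())
        s = s / s.sum(axis=-1, keepdims=True)
        assert np.allclose(s, 1.0 / 9.0)

    def test_matches_bruteforce_oracle(self, rng):
        net = CRFENet(TINY)
        alpha = 0.37
        net.params["att_alpha"].data = np.array(alpha)
        a = rng.normal(size=(1, 16, 4, 4))
        e = net.position_attention(Tensor(a)).data[0].reshape(16, 16)

        def project(prefix):
            w = net.params[f"att_{prefix}_w"].data[:, :, 0, 0]
            b = net.params[f"att_{prefix}_b"].data
            return (w @ a[0].reshape(16, 16)) + b[:, None]

        expected = attention_bruteforce(
            a[0].reshape(16, 16), project("b"), project("c"), project("d"), alpha
        )
        assert np.abs(e - expected).max() < 1e-6

    def test_nonfinite_input_rejected(self, net):
        bad = np.ones((1, 16, 2, 2))
        bad[0, 0, 0, 0] = np.nan
        with pytest.raises(ValueError):
            net.position_attention(Tensor(bad))


class TestForward:
    def test_end_to_end_shape_and_range(self, net, rng):
        x = rng.normal(size=(2, 64, 64))
        prob = net.forward(x)
        assert prob.data.shape == (2, 1, 64, 64)
        assert prob.data.min() > 0.0 and prob.data.max() < 1.0

    def test_deterministic_forward(self, net, rng):
        x = rng.normal(size=(1, 64, 64))
        assert np.array_equal(net.forward(x).data, net.forward(x).data)

    def test_checkpoint_roundtrip(self, net, rng, tmp_path):
        x = rng.normal(size=(1, 64, 64))
        before = net.forward(x).data
        net.save(tmp_path / "ckpt.npz")
        loaded = CRFENet.load(tmp_path / "ckpt.npz")
        assert loaded.spec == net.spec
        assert np.array_equal(loaded.forward(x).data, before)
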