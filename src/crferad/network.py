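"""CRFE segmentation network: convolutional encoder, bidirectional
recurrent context module, position attention, and decoder with sigmoid head.

The architecture follows a U-Net-style layout.  Three 3x3 convolution
blocks (32/64/128 channels by default) with ReLU and 2x2 max pooling
encode the slice; the deepest feature map is serialized row-major into a
sequence of per-position channel vectors and passed through a
bidirectional LSTM whose forward and backward outputs are fused by
summation and projected back to the encoder channel count; a position
attention block then lets every spatial location aggregate features from
every other location through a softmax-normalized N x N affinity map
(N = H*W), scaled by a learnable coefficient alpha initialized to zero so
the block starts as the identity; the decoder restores resolution with
factor-2 bilinear upsampling, skip concatenation and 64-/32-channel 3x3
convolutions, ending in a 1x1 convolution and a sigmoid that yields a
per-pixel lesion probability.  A 1x1 auxiliary head on the context block
provides deep supervision at the coarsest scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from .autograd import Tensor, concat, conv2d, maxpool2x2, upsample2x_bilinear

__all__ = ["SegmentationModelSpec", "CRFENet", "relu", "sigmoid"]


def relu(x):
    """Rectified linear unit, elementwise max(0, x)."""
    return np.maximum(np.asarray(x, dtype=float), 0.0)


def sigmoid(x):
    """Logistic function 1 / (1 + e^-x), mapping reals into (0, 1)."""
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


@dataclass(frozen=True)
class SegmentationModelSpec:
    input_size: int = 256
    encoder_channels: tuple = (32, 64, 128)
    recurrent_units: int = 256
    attention_alpha_init: float = 0.0
    decoder_channels: tuple = (64, 32)
    scan_order: str = "row-major"  # serialization of the deepest feature map
    seed: int = 0

    def __post_init__(self) -> None:
        if any(c <= 0 for c in self.encoder_channels + self.decoder_channels):
            raise ValueError("channel counts must be positive")
        if not np.isfinite(self.attention_alpha_init):
            raise ValueError("attention_alpha_init must be finite")
        if self.scan_order not in ("row-major", "column-major"):
            raise ValueError("scan_order must be row-major or column-major")

    @property
    def n_pool_stages(self) -> int:
        return len(self.encoder_channels)


def _he(rng, shape, fan_in):
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class CRFENet:
    """Parameter container + forward pass of the CRFE architecture."""

    def __init__(self, spec: SegmentationModelSpec):
        self.spec = spec
        rng = np.random.default_rng(spec.seed)
        p = {}
        cin = 1
        for i, cout in enumerate(spec.encoder_channels):
            p[f"enc{i}_w"] = _he(rng, (cout, cin, 3, 3), cin * 9)
            p[f"enc{i}_b"] = np.zeros(cout)
            cin = cout
        c3 = spec.encoder_channels[-1]
        r = spec.recurrent_units
        for d in ("fwd", "bwd"):
            p[f"lstm_{d}_wx"] = rng.normal(0, 1.0 / np.sqrt(c3), size=(c3, 4 * r))
            p[f"lstm_{d}_wh"] = rng.normal(0, 1.0 / np.sqrt(r), size=(r, 4 * r))
            b = np.zeros(4 * r)
            b[r:2 * r] = 1.0  # forget-gate bias
            p[f"lstm_{d}_b"] = b
        p["ctx_proj_w"] = rng.normal(0, 1.0 / np.sqrt(r), size=(r, c3))
        p["ctx_proj_b"] = np.zeros(c3)
        for nm in ("att_b", "att_c", "att_d"):
            p[f"{nm}_w"] = _he(rng, (c3, c3, 1, 1), c3)
            p[f"{nm}_b"] = np.zeros(c3)
        p["att_alpha"] = np.array(spec.attention_alpha_init)
        # decoder: up+concat(skip3) -> conv d0; up+concat(skip2) -> conv d1;
        # up+concat(skip1) -> 1x1 head
        d0, d1 = spec.decoder_channels
        e0, e1, e2 = spec.encoder_channels
        p["dec0_w"] = _he(rng, (d0, c3 + e2, 3, 3), (c3 + e2) * 9)
        p["dec0_b"] = np.zeros(d0)
        p["dec1_w"] = _he(rng, (d1, d0 + e1, 3, 3), (d0 + e1) * 9)
        p["dec1_b"] = np.zeros(d1)
        p["head_w"] = _he(rng, (1, d1 + e0, 1, 1), d1 + e0)
        p["head_b"] = np.zeros(1)
        p["aux_w"] = _he(rng, (1, c3, 1, 1), c3)
        p["aux_b"] = np.zeros(1)
        self.params = {k: Tensor(v, requires_grad=True, name=k) for k, v in p.items()}

    # -- stages --------------------------------------------------------------

    def encode(self, x: Tensor):
        """Return (deepest block, skip pyramid).  The input side must be
        divisible by 2**n_pool_stages."""
        h, w = x.data.shape[-2:]
        div = 2**self.spec.n_pool_stages
        if h % div or w % div:
            raise ValueError(
                f"input sides must be divisible by {div}, got {h}x{w}"
            )
        skips = []
        out = x
        for i in range(len(self.spec.encoder_channels)):
            out = conv2d(out, self.params[f"enc{i}_w"], self.params[f"enc{i}_b"]).relu()
            skips.append(out)
            out = maxpool2x2(out)
        return out, skips

    def _lstm_direction(self, seq, direction: str):
        """Run one LSTM direction over a list of (B, C) tensors."""
        wx = self.params[f"lstm_{direction}_wx"]
        wh = self.params[f"lstm_{direction}_wh"]
        b = self.params[f"lstm_{direction}_b"]
        r = self.spec.recurrent_units
        bsz = seq[0].data.shape[0]
        h = Tensor(np.zeros((bsz, r)))
        c = Tensor(np.zeros((bsz, r)))
        outs = []
        for x_t in seq:
            gates = x_t @ wx + h @ wh + b
            i_g = gates[:, 0 * r:1 * r].sigmoid()
            f_g = gates[:, 1 * r:2 * r].sigmoid()
            g_g = gates[:, 2 * r:3 * r].tanh()
            o_g = gates[:, 3 * r:4 * r].sigmoid()
            c = f_g * c + i_g * g_g
            h = o_g * c.tanh()
            outs.append(h)
        return outs

    def recurrent_context(self, features: Tensor) -> Tensor:
        """Bidirectional LSTM over the serialized deepest feature map.

        The (B, C, H, W) block is scanned into an H*W-long sequence of
        C-vectors, processed in both directions, fused by summation and
        linearly projected back to C channels, then reshaped to (B,C,H,W).
        """
        bsz, c, h, w = features.data.shape
        if self.spec.scan_order == "row-major":
            flat = features.reshape(bsz, c, h * w).transpose(2, 0, 1)  # (T,B,C)
        else:
            flat = features.transpose(0, 1, 3, 2).reshape(bsz, c, h * w).transpose(2, 0, 1)
        seq = [flat[t] for t in range(h * w)]
        fwd = self._lstm_direction(seq, "fwd")
        bwd = self._lstm_direction(seq[::-1], "bwd")[::-1]
        fused = [f + bk for f, bk in zip(fwd, bwd)]
        proj = [t @ self.params["ctx_proj_w"] + self.params["ctx_proj_b"] for t in fused]
        stacked = concat([t.reshape(1, bsz, c) for t in proj], axis=0)  # (T,B,C)
        out = stacked.transpose(1, 2, 0)  # (B,C,T)
        if self.spec.scan_order == "row-major":
            return out.reshape(bsz, c, h, w)
        return out.reshape(bsz, c, w, h).transpose(0, 1, 3, 2)

    def position_attention(self, a: Tensor, alpha: Tensor | None = None) -> Tensor:
        """Position attention E_j = alpha * sum_i S_ji D_i + A_j.

        B, C, D are 1x1-convolution projections of A; S is an N x N map
        (N = H*W) whose row j is the softmax over source positions i of the
        similarity B_i . C_j.  With alpha = 0 the block is the identity.
        """
        if not np.all(np.isfinite(a.data)):
            raise ValueError("non-finite activations entering attention")
        if alpha is None:
            alpha = self.params["att_alpha"]
        bsz, c, h, w = a.data.shape
        n = h * w
        bm = conv2d(a, self.params["att_b_w"], self.params["att_b_b"]).reshape(bsz, c, n)
        cm = conv2d(a, self.params["att_c_w"], self.params["att_c_b"]).reshape(bsz, c, n)
        dm = conv2d(a, self.params["att_d_w"], self.params["att_d_b"]).reshape(bsz, c, n)
        scores = cm.transpose(0, 2, 1) @ bm  # scores[b, j, i] = C_j . B_i
        s = scores.softmax(axis=-1)  # rows (fixed j) sum to 1 over i
        ctx = dm @ s.transpose(0, 2, 1)  # ctx[b, c, j] = sum_i D_i S_ji
        e = alpha * ctx.reshape(bsz, c, h, w) + a
        return e

    def decode(self, context: Tensor, skips) -> Tensor:
        """Upsample, fuse skips by concatenation, and emit the probability map."""
        s0, s1, s2 = skips
        x = upsample2x_bilinear(context)
        if x.data.shape[-2:] != s2.data.shape[-2:]:
            raise ValueError("skip pyramid does not match decoder shapes")
        x = conv2d(concat([x, s2], axis=1), self.params["dec0_w"], self.params["dec0_b"]).relu()
        x = upsample2x_bilinear(x)
        x = conv2d(concat([x, s1], axis=1), self.params["dec1_w"], self.params["dec1_b"]).relu()
        x = upsample2x_bilinear(x)
        x = conv2d(concat([x, s0], axis=1), self.params["head_w"], self.params["head_b"])
        return x.sigmoid()

    def forward(self, batch: np.ndarray | Tensor, with_aux: bool = False):
        """Full forward pass.

        ``batch``: (B, H, W) or (B, 1, H, W) standardized slices.  Returns
        the (B, 1, H, W) probability map, plus the coarse auxiliary
        probability map when ``with_aux`` is set.
        """
        x = batch if isinstance(batch, Tensor) else Tensor(batch)
        if x.data.ndim == 3:
            x = x.reshape(x.data.shape[0], 1, *x.data.shape[1:])
        deepest, skips = self.encode(x)
        context = self.recurrent_context(deepest)
        attended = self.position_attention(context)
        prob = self.decode(attended, skips)
        if not with_aux:
            return prob
        aux = conv2d(attended, self.params["aux_w"], self.params["aux_b"]).sigmoid()
        return prob, aux

    # -- serialization -------------------------------------------------------

    def state_dict(self) -> dict:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict) -> None:
        for k, v in state.items():
            self.params[k].data = np.asarray(v, dtype=np.float64)

    def save(self, path) -> None:
        """Write parameters (npz) with a JSON sidecar recording the spec."""
        np.savez(path, **self.state_dict())
        sidecar = str(path) + ".json" if not str(path).endswith(".npz") else str(path)[:-4] + ".json"
        with open(sidecar, "w") as fh:
            json.dump(asdict(self.spec), fh, indent=2)

    @classmethod
    def load(cls, path) -> "CRFENet":
        sidecar = str(path) + ".json" if not str(path).endswith(".npz") else str(path)[:-4] + ".json"
        with open(sidecar) as fh:
            spec = SegmentationModelSpec(**{k: tuple(v) if isinstance(v, list) else v
                                            for k, v in json.load(fh).items()})
        net = cls(spec)
        with np.load(path) as data:
            net.load_state_dict({k: data[k] for k in data.files})
        return net
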