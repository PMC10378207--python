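"""The three-branch attention flow network.

Each of the three optical-flow channels (horizontal flow u, vertical flow v,
optical strain os) is processed by its own shallow inception backbone; a
multi-scale fusion module (MSFF) combines the two pyramid levels of each
branch under spatial attention, and a cross-branch reweighting module
(MOFRW) lets the three flow modalities compete for channel attention through
an elementwise softmax before a residual merge. A global-average-pooled
fully connected head produces the class logits.

Channel arithmetic with the default configuration (28x28 input, 6 and 16
kernels per inception scale):

    1 x 28 x 28  -> inception(6)  ->  24 x 28 x 28 -> pool ->  24 x 14 x 14
                 -> inception(16) ->  64 x 14 x 14 -> pool ->  64 x  7 x  7
                 -> MSFF(prev=24x14x14, curr=64x7x7) -> 128 x 7 x 7  (per branch)
    MOFRW over the three 128 x 7 x 7 maps -> 384 x 7 x 7 -> GAP -> FC -> logits
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Optional, Tuple

import numpy as np

from .autodiff import Tensor, concat, stack_backwardable
from .nn import Adam, Conv2d, Linear, Module
from .types import InputError, NetConfig

__all__ = ["InceptionBlock", "SpatialAttention", "ChannelAttention",
           "MSFF", "MOFRW", "FlowNet", "save_checkpoint", "load_checkpoint"]


class InceptionBlock(Module):
    """Four parallel paths, each emitting ``k`` channels (output 4k).

    Paths: 1x1 conv; 1x1 reduce then 3x3 conv; 1x1 reduce then 5x5 conv;
    3x3 max pool (stride 1) then 1x1 conv. All convolutions are 'same'
    padded and ReLU-activated, outputs are concatenated along channels.
    The 1x1 reduction width equals ``k``.
    """

    def __init__(self, in_ch: int, k: int, rng: np.random.Generator):
        super().__init__()
        self.conv1 = Conv2d(in_ch, k, 1, rng, relu=True)
        self.reduce3 = Conv2d(in_ch, k, 1, rng, relu=True)
        self.conv3 = Conv2d(k, k, 3, rng, relu=True)
        self.reduce5 = Conv2d(in_ch, k, 1, rng, relu=True)
        self.conv5 = Conv2d(k, k, 5, rng, relu=True)
        self.pool_proj = Conv2d(in_ch, k, 1, rng, relu=True)
        self.out_channels = 4 * k

    def forward(self, x: Tensor) -> Tensor:
        p1 = self.conv1(x)
        p2 = self.conv3(self.reduce3(x))
        p3 = self.conv5(self.reduce5(x))
        p4 = self.pool_proj(x.maxpool2d(3, stride=1, padding=1))
        return concat([p1, p2, p3, p4], axis=1)


class SpatialAttention(Module):
    """Spatial gate: sigmoid(conv_k([channel-mean, channel-max])) times input."""

    def __init__(self, kernel: int, rng: np.random.Generator):
        super().__init__()
        if kernel % 2 != 1:
            raise InputError("spatial-attention kernel must be odd")
        self.conv = Conv2d(2, 1, kernel, rng)

    def attention(self, x: Tensor) -> Tensor:
        avg = x.mean(axis=1, keepdims=True)
        mx = x.max(axis=1, keepdims=True)
        return self.conv(concat([avg, mx], axis=1)).sigmoid()

    def forward(self, x: Tensor) -> Tuple[Tensor, Tensor]:
        attn = self.attention(x)
        return x * attn, attn


class ChannelAttention(Module):
    """Squeeze-excitation channel gate: sigmoid(W2 relu(W1 GAP(x)))."""

    def __init__(self, channels: int, reduction: int, rng: np.random.Generator):
        super().__init__()
        if channels < reduction:
            warnings.warn("channel count below reduction; clamping reduction to 1")
            reduction = 1
        hidden = max(channels // reduction, 1)
        self.fc1 = Linear(channels, hidden, rng)
        self.fc2 = Linear(hidden, channels, rng)

    def forward(self, x: Tensor) -> Tensor:
        z = x.mean(axis=(2, 3))                       # GAP -> (B, C)
        return self.fc2(self.fc1(z).relu()).sigmoid()


class MSFF(Module):
    """Multi-scale fusion of two adjacent pyramid levels.

    The previous (higher-resolution) level is 2x2 max-pooled and aligned to
    the current channel width by a 1x1 convolution, summed with the current
    level and gated by spatial attention; the current level passes through
    its own spatial-attention gate; the two gated maps are concatenated, so
    the output doubles the current channel count at the current resolution.
    """

    def __init__(self, prev_ch: int, curr_ch: int, sam_kernel: int,
                 rng: np.random.Generator):
        super().__init__()
        self.align = Conv2d(prev_ch, curr_ch, 1, rng)
        self.sam_fused = SpatialAttention(sam_kernel, rng)
        self.sam_curr = SpatialAttention(sam_kernel, rng)
        self.out_channels = 2 * curr_ch

    def forward(self, prev: Tensor, curr: Tensor) -> Tensor:
        _, _, hp, wp = prev.shape
        _, _, hc, wc = curr.shape
        if (hp, wp) != (2 * hc, 2 * wc):
            raise InputError(
                f"previous level {hp}x{wp} must be twice the current {hc}x{wc}"
            )
        down = self.align(prev.maxpool2d(2))
        fused, _ = self.sam_fused(down + curr)
        gated, _ = self.sam_curr(curr)
        return concat([fused, gated], axis=1)


class MOFRW(Module):
    """Cross-branch reweighting of the u / v / os feature maps.

    One shared channel-attention module scores each branch; the three score
    vectors compete through an elementwise softmax across branches, so the
    weights form a 3-way probability simplex per channel. Each branch map is
    scaled by its weight and the concatenation is added residually to the
    concatenated input features.
    """

    def __init__(self, branch_channels: int, reduction: int,
                 rng: np.random.Generator):
        super().__init__()
        self.cam = ChannelAttention(branch_channels, reduction, rng)
        self.out_channels = 3 * branch_channels

    def branch_weights(self, f_u: Tensor, f_v: Tensor, f_os: Tensor) -> Tensor:
        """Softmax-recalibrated weights, shape (3, B, C); sums to 1 over axis 0."""
        z = stack_backwardable([self.cam(f) for f in (f_u, f_v, f_os)], axis=0)
        e = z.exp()
        return e / e.sum(axis=0, keepdims=True)

    def forward(self, f_u: Tensor, f_v: Tensor, f_os: Tensor) -> Tensor:
        shapes = {f.shape for f in (f_u, f_v, f_os)}
        if len(shapes) != 1:
            raise InputError("branch feature maps must share shape")
        att = self.branch_weights(f_u, f_v, f_os)
        b, c = f_u.shape[0], f_u.shape[1]
        # scale each branch by its per-channel weight, broadcast over H, W
        outs = []
        for i, f in enumerate((f_u, f_v, f_os)):
            sl = _take_axis0(att, i)                 # (B, C)
            outs.append(f * sl.reshape(b, c, 1, 1))
        f_input = concat([f_u, f_v, f_os], axis=1)
        return f_input + concat(outs, axis=1)


def _take_axis0(t: Tensor, i: int) -> Tensor:
    """Differentiable selection t[i] along axis 0."""
    out_data = t.data[i]

    def bw(g):
        full = np.zeros_like(t.data)
        full[i] = g
        t._accum(full)

    return Tensor(out_data, parents=(t,), backward=bw)


class FlowNet(Module):
    """Three-branch inception network with MSFF and MOFRW attention."""

    def __init__(self, cfg: NetConfig):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        k1, k2 = cfg.kernels_block1, cfg.kernels_block2
        self.branches = []
        for _ in range(3):
            branch = Module()
            branch.inc1 = InceptionBlock(1, k1, rng)
            branch.inc2 = InceptionBlock(4 * k1, k2, rng)
            branch.msff = MSFF(4 * k1, 4 * k2, cfg.sam_kernel, rng)
            self.branches.append(branch)
        self.mofrw = MOFRW(8 * k2, cfg.cam_reduction, rng)
        self.head = Linear(3 * 8 * k2, cfg.n_classes, rng)

    def _branch_features(self, branch: Module, x: Tensor) -> Tensor:
        a = branch.inc1(x).maxpool2d(2)      # 4*k1 @ S/2
        b = branch.inc2(a).maxpool2d(2)      # 4*k2 @ S/4
        return branch.msff(a, b)             # 8*k2 @ S/4

    def branch_maps(self, x: Tensor) -> Tuple[Tensor, Tensor, Tensor]:
        if x.ndim != 4 or x.shape[1] != 3:
            raise InputError(f"expected input (B, 3, S, S), got {x.shape}")
        maps = []
        for i, branch in enumerate(self.branches):
            xi = _slice_channel(x, i)
            maps.append(self._branch_features(branch, xi))
        return tuple(maps)

    def features(self, x: Tensor) -> Tensor:
        """Post-MOFRW feature map, (B, 3*8*k2, S/4, S/4)."""
        f_u, f_v, f_os = self.branch_maps(x)
        return self.mofrw(f_u, f_v, f_os)

    def forward(self, x) -> Tensor:
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=np.float32))
        feat = self.features(x)
        pooled = feat.mean(axis=(2, 3))
        return self.head(pooled)

    def predict(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """Argmax class per sample (ties resolved toward the lower index)."""
        self.eval()
        preds = []
        for lo in range(0, len(x), batch_size):
            logits = self.forward(Tensor(x[lo:lo + batch_size])).data
            preds.append(np.argmax(logits, axis=1))
        return np.concatenate(preds) if preds else np.empty(0, dtype=np.int64)


def _slice_channel(x: Tensor, i: int) -> Tensor:
    """Differentiable x[:, i:i+1] on a (B, 3, H, W) tensor."""
    out_data = x.data[:, i:i + 1]

    def bw(g):
        full = np.zeros_like(x.data)
        full[:, i:i + 1] = g
        x._accum(full)

    return Tensor(out_data, parents=(x,), backward=bw)


def save_checkpoint(model: FlowNet, path) -> None:
    """Serialize weights (.npz) with a JSON config sidecar."""
    path = Path(path)
    np.savez(path, **model.state_dict())
    sidecar = path.with_suffix(".json")
    sidecar.write_text(json.dumps(model.cfg.to_dict(), indent=2))


def load_checkpoint(path) -> FlowNet:
    path = Path(path)
    cfg = NetConfig(**json.loads(path.with_suffix(".json").read_text()))
    model = FlowNet(cfg)
    with np.load(path if path.suffix == ".npz" else path.with_suffix(".npz")) as z:
        model.load_state_dict({k: z[k] for k in z.files})
    return model
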