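"""Attention blocks used on the skip connections of the segmentation U-Net.

Three mechanisms are implemented:

* **CBAM** — convolutional block attention: a per-channel gate built from
  global average/max pooling through a shared bottleneck MLP, followed by a
  per-pixel spatial gate built from channel-wise average/max maps passed
  through a dilated 7x7 convolution. Both gates are sigmoid-squashed and
  applied multiplicatively.
* **PAM** — position attention: a softmax-normalized N x N affinity matrix
  (N = H*W) over spatial positions re-weights a value projection; the
  attended features are scaled by a learnable ``alpha`` (initialized to 0,
  so the block starts as the identity) and added back to the input.
* **PCBAM** — the additive fusion ``PAM(F) + CBAM(F)`` of the two blocks
  applied to the same input feature.

All blocks are shape preserving on (batch, H, W, C) feature grids. The
module-level functions offer a batch-free numpy interface over single
(H, W, C) grids, which is the natural unit for tests and exploration.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Parameter, Tensor, concatenate, relu, sigmoid
from .layers import Conv2d, Dense, Module

__all__ = [
    "ChannelAttention",
    "SpatialAttention",
    "CBAM",
    "PositionAttention",
    "PCBAM",
    "channel_attention",
    "apply_channel_gate",
    "spatial_attention",
    "cbam",
    "position_affinity",
    "position_attention",
    "pcbam",
]


def _check_grid(f: np.ndarray) -> np.ndarray:
    f = np.asarray(f, dtype=np.float64)
    if f.ndim != 3:
        raise ValueError(f"expected an (H, W, C) feature grid, got shape {f.shape}")
    if not np.all(np.isfinite(f)):
        raise ValueError("feature grid contains non-finite entries")
    return f


def _as_batch(f: np.ndarray) -> Tensor:
    return Tensor(f[None])


class ChannelAttention(Module):
    """Per-channel sigmoid gate from pooled descriptors through a shared MLP.

    The MLP is a bottleneck of two dense layers, C -> max(1, C // reduction)
    -> C; the same MLP is applied to the global-average and global-max
    descriptors and the two responses are summed before the sigmoid. The
    bottleneck is linear by default (two plain dense layers); a ReLU between
    them can be enabled, but at small hidden widths a ReLU unit that starts
    dead never recovers (its weights receive no gradient), so linear is the
    safer default for narrow models.
    """

    def __init__(self, channels: int, *, reduction: int = 8, mlp_activation: str = "linear",
                 rng: np.random.Generator, dtype=np.float32):
        if mlp_activation not in ("linear", "relu"):
            raise ValueError("mlp_activation must be 'linear' or 'relu'")
        hidden = max(1, channels // reduction)
        self.fc1 = Dense(channels, hidden, rng=rng, dtype=dtype)
        self.fc2 = Dense(hidden, channels, rng=rng, dtype=dtype)
        self.channels = channels
        self.mlp_activation = mlp_activation

    def _mlp(self, pooled: Tensor) -> Tensor:
        hidden = self.fc1(pooled)
        if self.mlp_activation == "relu":
            hidden = relu(hidden)
        return self.fc2(hidden)

    def gate(self, x: Tensor) -> Tensor:
        if x.shape[-1] != self.channels:
            raise ValueError(f"channel mismatch: grid has {x.shape[-1]} channels, gate expects {self.channels}")
        gap = x.mean(axis=(1, 2))
        gmp = x.max(axis=(1, 2))
        g = sigmoid(self._mlp(gap) + self._mlp(gmp))
        return g.reshape((x.shape[0], 1, 1, self.channels))

    def forward(self, x: Tensor) -> Tensor:
        return x * self.gate(x)


class SpatialAttention(Module):
    """Per-pixel sigmoid gate from channel-pooled maps.

    Channel-wise average and max maps are (optionally) passed through a
    per-position 1 -> 1 dense layer each, concatenated, and convolved with a
    7x7 kernel of dilation 4 under 'same' padding so the gate matches the
    input's spatial dims.
    """

    def __init__(self, *, kernel: int = 7, dilation: int = 4, inner_dense: bool = True,
                 rng: np.random.Generator, dtype=np.float32):
        self.dense_avg = Dense(1, 1, rng=rng, dtype=dtype) if inner_dense else None
        self.dense_max = Dense(1, 1, rng=rng, dtype=dtype) if inner_dense else None
        self.conv = Conv2d(2, 1, kernel, dilation=dilation, padding="same", rng=rng, dtype=dtype)

    def gate(self, x: Tensor) -> Tensor:
        avg = x.mean(axis=3, keepdims=True)
        mx = x.max(axis=3, keepdims=True)
        if self.dense_avg is not None:
            avg = self.dense_avg(avg)
            mx = self.dense_max(mx)
        return sigmoid(self.conv(concatenate([avg, mx], axis=3)))

    def forward(self, x: Tensor) -> Tensor:
        return x * self.gate(x)


class CBAM(Module):
    """Channel gate followed by spatial gate, both multiplicative."""

    def __init__(self, channels: int, *, reduction: int = 8, kernel: int = 7, dilation: int = 4,
                 inner_dense: bool = True, rng: np.random.Generator, dtype=np.float32):
        self.channel = ChannelAttention(channels, reduction=reduction, rng=rng, dtype=dtype)
        self.spatial = SpatialAttention(kernel=kernel, dilation=dilation, inner_dense=inner_dense,
                                        rng=rng, dtype=dtype)

    def forward(self, x: Tensor) -> Tensor:
        gated = self.channel(x)
        return self.spatial(gated)


def _softmax_rows(logits: np.ndarray) -> np.ndarray:
    logits -= logits.max(axis=1, keepdims=True)
    np.exp(logits, out=logits)
    logits /= logits.sum(axis=1, keepdims=True)
    return logits


def _pam_attend(bm: Tensor, zm: Tensor, dm: Tensor) -> Tensor:
    """Fused ``softmax(Z B^T) @ D`` over (batch, N, C) projections.

    Row ``j`` of the affinity holds the softmax over source positions ``i``
    of the logits ``Z_j . B_i`` (max-subtracted for stability). The affinity
    is evaluated in row blocks and recomputed during the backward pass, so
    memory stays at a few row blocks rather than the full N x N matrix —
    which matters at full skip resolution, where N = 16384 and the dense
    affinity alone would occupy gigabytes.
    """
    batch, n, _ = zm.shape
    c_out = dm.shape[2]
    block = max(1, min(n, (1 << 24) // max(n, 1)))  # ~64 MB of float32 rows
    data = np.empty((batch, n, c_out), dtype=dm.data.dtype)
    for b in range(batch):
        bt = bm.data[b].T
        for j0 in range(0, n, block):
            rows = slice(j0, min(j0 + block, n))
            s = _softmax_rows(zm.data[b, rows] @ bt)
            data[b, rows] = s @ dm.data[b]
    out = Tensor(data, requires_grad=any(t.requires_grad for t in (bm, zm, dm)), parents=(bm, zm, dm))

    def backward(g):
        gb = np.zeros_like(bm.data) if bm.requires_grad else None
        gz = np.zeros_like(zm.data) if zm.requires_grad else None
        gd = np.zeros_like(dm.data) if dm.requires_grad else None
        for b in range(batch):
            bt = bm.data[b].T
            for j0 in range(0, n, block):
                rows = slice(j0, min(j0 + block, n))
                s = _softmax_rows(zm.data[b, rows] @ bt)
                if gd is not None:
                    gd[b] += s.T @ g[b, rows]
                ds = g[b, rows] @ dm.data[b].T
                ds -= (ds * s).sum(axis=1, keepdims=True)
                ds *= s  # ds is now the gradient w.r.t. the logits
                if gz is not None:
                    gz[b, rows] = ds @ bm.data[b]
                if gb is not None:
                    gb[b] += ds.T @ zm.data[b, rows]
        if gb is not None:
            bm._accum(gb)
        if gz is not None:
            zm._accum(gz)
        if gd is not None:
            dm._accum(gd)

    out._backward = backward
    return out


class PositionAttention(Module):
    """Softmax spatial self-attention with a zero-initialized residual scale.

    ``alpha`` starts at exactly 0, so a freshly built block is the identity;
    training moves it away from zero as the attended context becomes useful.
    The query/key projections may optionally be channel-reduced; the value
    projection always keeps C channels because its output is added to the
    input feature.
    """

    def __init__(self, channels: int, *, reduction: int | None = None,
                 rng: np.random.Generator, dtype=np.float32):
        proj = channels if reduction is None else max(1, channels // reduction)
        self.conv_b = Conv2d(channels, proj, 1, rng=rng, dtype=dtype)
        self.conv_z = Conv2d(channels, proj, 1, rng=rng, dtype=dtype)
        self.conv_d = Conv2d(channels, channels, 1, rng=rng, dtype=dtype)
        self.alpha = Parameter(np.zeros((), dtype=dtype))
        self.channels = channels
        self._proj = proj

    def _projections(self, x: Tensor) -> tuple[Tensor, Tensor, Tensor, int]:
        b, h, w, c = x.shape
        n = h * w
        bm = self.conv_b(x).reshape((b, n, self._proj))
        zm = self.conv_z(x).reshape((b, n, self._proj))
        dm = self.conv_d(x).reshape((b, n, c))
        return bm, zm, dm, n

    def affinity(self, x: Tensor) -> np.ndarray:
        """The (batch, N, N) softmax affinity matrix; each row sums to 1."""
        bm, zm, _, _ = self._projections(x)
        s = zm.data @ np.swapaxes(bm.data, 1, 2)
        s -= s.max(axis=2, keepdims=True)
        np.exp(s, out=s)
        s /= s.sum(axis=2, keepdims=True)
        return s

    def forward(self, x: Tensor) -> Tensor:
        bm, zm, dm, _ = self._projections(x)
        attended = _pam_attend(bm, zm, dm)
        return self.alpha * attended.reshape(x.shape) + x


class PCBAM(Module):
    """Additive fusion of position attention and CBAM on the same input."""

    def __init__(self, channels: int, *, reduction: int = 8, pam_reduction: int | None = None,
                 inner_dense: bool = True, rng: np.random.Generator, dtype=np.float32):
        self.pam = PositionAttention(channels, reduction=pam_reduction, rng=rng, dtype=dtype)
        self.cbam = CBAM(channels, reduction=reduction, inner_dense=inner_dense, rng=rng, dtype=dtype)

    def forward(self, x: Tensor) -> Tensor:
        return self.pam(x) + self.cbam(x)


# --------------------------------------------------------- numpy convenience
def channel_attention(f: np.ndarray, block: ChannelAttention) -> np.ndarray:
    """Per-channel gate vector (length C) for a single (H, W, C) grid."""
    f = _check_grid(f)
    return block.gate(_as_batch(f)).data.reshape(-1)


def apply_channel_gate(f: np.ndarray, gate: np.ndarray) -> np.ndarray:
    f = _check_grid(f)
    gate = np.asarray(gate, dtype=np.float64).reshape(-1)
    if gate.shape[0] != f.shape[-1]:
        raise ValueError(f"gate length {gate.shape[0]} does not match {f.shape[-1]} channels")
    return f * gate


def spatial_attention(f: np.ndarray, block: SpatialAttention) -> np.ndarray:
    """Per-pixel gate map (H, W, 1) for a single grid."""
    f = _check_grid(f)
    return block.gate(_as_batch(f)).data[0]


def cbam(f: np.ndarray, block: CBAM) -> np.ndarray:
    f = _check_grid(f)
    return block(_as_batch(f)).data[0]


def position_affinity(f: np.ndarray, block: PositionAttention) -> np.ndarray:
    """The N x N affinity matrix (N = H*W) for a single grid."""
    f = _check_grid(f)
    return block.affinity(_as_batch(f))[0]


def position_attention(f: np.ndarray, block: PositionAttention) -> np.ndarray:
    f = _check_grid(f)
    return block(_as_batch(f)).data[0]


def pcbam(f: np.ndarray, block: PCBAM) -> np.ndarray:
    f = _check_grid(f)
    return block(_as_batch(f)).data[0]
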