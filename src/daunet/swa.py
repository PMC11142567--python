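"""Bottleneck attention block with convolutional q/k/v fusion.

Each spatial position is projected by three learnable C x C weight matrices
into query, key, and value grids; the three are concatenated along channels
and fused by a 1x1 convolution (3C -> C) to form an attention map that is
added residually to the input. With a zero fusion kernel and bias the block
is the exact identity, so it can be inserted without perturbing a trained
model.

An optional windowed softmax attention (non-overlapping windows, scaled
dot-product over positions within each window) can be enabled for
experimentation; the default is the convolutional fusion described above.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, concatenate, softmax
from .layers import Conv2d, Dense, Module

__all__ = ["Swa", "swa", "swa_project", "swa_attention_map"]


class Swa(Module):
    def __init__(self, channels: int, *, window_softmax: bool = False, window: int = 4,
                 rng: np.random.Generator, dtype=np.float32):
        self.w_q = Dense(channels, channels, bias=False, rng=rng, dtype=dtype)
        self.w_k = Dense(channels, channels, bias=False, rng=rng, dtype=dtype)
        self.w_v = Dense(channels, channels, bias=False, rng=rng, dtype=dtype)
        self.fusion = Conv2d(3 * channels, channels, 1, rng=rng, dtype=dtype)
        self.window_softmax = window_softmax
        self.window = window
        self.channels = channels

    def project(self, x: Tensor) -> tuple[Tensor, Tensor, Tensor]:
        if x.shape[-1] != self.channels:
            raise ValueError(f"channel mismatch: grid has {x.shape[-1]} channels, block expects {self.channels}")
        return self.w_q(x), self.w_k(x), self.w_v(x)

    def attention_map(self, q: Tensor, k: Tensor, v: Tensor) -> Tensor:
        if not (q.shape == k.shape == v.shape):
            raise ValueError("q, k, v must share a shape")
        if self.window_softmax:
            return self._windowed(q, k, v)
        return self.fusion(concatenate([q, k, v], axis=3))

    def _windowed(self, q: Tensor, k: Tensor, v: Tensor) -> Tensor:
        b, h, w, c = q.shape
        ws = self.window
        if h % ws or w % ws:
            raise ValueError(f"spatial dims {(h, w)} not divisible by window size {ws}")
        # (b, h/ws, ws, w/ws, ws, c) -> (b*nw, ws*ws, c)
        def to_windows(t: Tensor) -> Tensor:
            t = t.reshape((b, h // ws, ws, w // ws, ws, c)).transpose((0, 1, 3, 2, 4, 5))
            return t.reshape((b * (h // ws) * (w // ws), ws * ws, c))

        qw, kw, vw = to_windows(q), to_windows(k), to_windows(v)
        scores = qw @ kw.transpose((0, 2, 1)) * (1.0 / np.sqrt(c))
        attended = softmax(scores, axis=-1) @ vw
        attended = attended.reshape((b, h // ws, w // ws, ws, ws, c)).transpose((0, 1, 3, 2, 4, 5))
        return attended.reshape((b, h, w, c))

    def forward(self, x: Tensor) -> Tensor:
        q, k, v = self.project(x)
        return x + self.attention_map(q, k, v)


# --------------------------------------------------------- numpy convenience
def _grid(f: np.ndarray) -> Tensor:
    f = np.asarray(f, dtype=np.float64)
    if f.ndim != 3:
        raise ValueError(f"expected an (H, W, C) feature grid, got shape {f.shape}")
    if not np.all(np.isfinite(f)):
        raise ValueError("feature grid contains non-finite entries")
    return Tensor(f[None])


def swa_project(f: np.ndarray, block: Swa) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    q, k, v = block.project(_grid(f))
    return q.data[0], k.data[0], v.data[0]


def swa_attention_map(q: np.ndarray, k: np.ndarray, v: np.ndarray, block: Swa) -> np.ndarray:
    return block.attention_map(_grid(q), _grid(k), _grid(v)).data[0]


def swa(f: np.ndarray, block: Swa) -> np.ndarray:
    return block(_grid(f)).data[0]
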