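"""Attention blocks versus straight-line brute-force oracles.

The oracles evaluate the gate/affinity definitions term by term in plain
numpy (explicit loops where the block uses matrix algebra), independently
of the autodiff path under test.
"""

import numpy as np
import pytest

from daunet.attention import (
    CBAM,
    PCBAM,
    ChannelAttention,
    PositionAttention,
    SpatialAttention,
    apply_channel_gate,
    cbam,
    channel_attention,
    pcbam,
    position_affinity,
    position_attention,
    spatial_attention,
)
from daunet.autodiff import Tensor

from conftest import zero_params


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


# ------------------------------------------------------------------- oracles
def channel_gate_oracle(f: np.ndarray, block: ChannelAttention) -> np.ndarray:
    w1, b1 = block.fc1.weight.data.astype(float), block.fc1.bias.data.astype(float)
    w2, b2 = block.fc2.weight.data.astype(float), block.fc2.bias.data.astype(float)

    def mlp(v):
        hidden = v @ w1 + b1
        if block.mlp_activation == "relu":
            hidden = np.maximum(hidden, 0.0)
        return hidden @ w2 + b2

    gap = f.mean(axis=(0, 1))
    gmp = f.max(axis=(0, 1))
    return _sigmoid(mlp(gap) + mlp(gmp))


def spatial_gate_oracle(f: np.ndarray, block: SpatialAttention) -> np.ndarray:
    avg = f.mean(axis=2)
    mx = f.max(axis=2)
    if block.dense_avg is not None:
        avg = avg * float(block.dense_avg.weight.data[0, 0]) + float(block.dense_avg.bias.data[0])
        mx = mx * float(block.dense_max.weight.data[0, 0]) + float(block.dense_max.bias.data[0])
    maps = np.stack([avg, mx], axis=2)
    k, dil = block.conv.weight.data.shape[0], block.conv.dilation
    pad = (k - 1) * dil // 2
    padded = np.pad(maps, ((pad, pad), (pad, pad), (0, 0)))
    h, w = f.shape[:2]
    out = np.zeros((h, w))
    kernel = block.conv.weight.data.astype(float)
    for i in range(h):
        for j in range(w):
            for di in range(k):
                for dj in range(k):
                    out[i, j] += (padded[i + di * dil, j + dj * dil, :] * kernel[di, dj, :, 0]).sum()
    return _sigmoid(out + float(block.conv.bias.data[0]))[..., None]


def cbam_oracle(f: np.ndarray, block: CBAM) -> np.ndarray:
    gated = f * channel_gate_oracle(f, block.channel)
    return gated * spatial_gate_oracle(gated, block.spatial)


def _conv1x1(f: np.ndarray, conv) -> np.ndarray:
    return f @ conv.weight.data[0, 0].astype(float) + conv.bias.data.astype(float)


def affinity_oracle(f: np.ndarray, block: PositionAttention) -> np.ndarray:
    h, w, _ = f.shape
    b = _conv1x1(f, block.conv_b).reshape(h * w, -1)
    z = _conv1x1(f, block.conv_z).reshape(h * w, -1)
    n = h * w
    s = np.zeros((n, n))
    for j in range(n):
        logits = np.array([np.dot(b[i], z[j]) for i in range(n)])
        e = np.exp(logits - logits.max())
        s[j] = e / e.sum()
    return s


def pam_oracle(f: np.ndarray, block: PositionAttention) -> np.ndarray:
    h, w, c = f.shape
    s = affinity_oracle(f, block)
    d = _conv1x1(f, block.conv_d).reshape(h * w, c)
    alpha = float(block.alpha.data)
    out = np.zeros((h * w, c))
    for j in range(h * w):
        acc = np.zeros(c)
        for i in range(h * w):
            acc += s[j, i] * d[i]
        out[j] = alpha * acc + f.reshape(h * w, c)[j]
    return out.reshape(h, w, c)


# --------------------------------------------------------------------- tests
def test_zero_weight_channel_gate_is_half(rng):
    block = ChannelAttention(8, rng=rng)
    zero_params(block)
    gate = channel_attention(rng.uniform(-1, 1, (4, 4, 8)), block)
    np.testing.assert_allclose(gate, 0.5)
    assert gate.shape == (8,)


def test_channel_gate_matches_hand_oracle(rng):
    block = ChannelAttention(2, rng=rng)
    block.fc1.weight.data = np.array([[0.3], [-0.2]], dtype=np.float32)
    block.fc1.bias.data = np.array([0.1], dtype=np.float32)
    block.fc2.weight.data = np.array([[0.5, -0.4]], dtype=np.float32)
    block.fc2.bias.data = np.array([0.05, 0.2], dtype=np.float32)
    f = np.stack([np.full((2, 2), 1.0), np.full((2, 2), 3.0)], axis=-1)
    gate = channel_attention(f, block)
    np.testing.assert_allclose(gate, channel_gate_oracle(f, block), rtol=1e-6)


def test_apply_channel_gate_scales_per_channel(rng):
    f = np.ones((2, 2, 2))
    out = apply_channel_gate(f, np.array([0.25, 0.5]))
    np.testing.assert_allclose(out[..., 0], 0.25)
    np.testing.assert_allclose(out[..., 1], 0.5)
    np.testing.assert_allclose(apply_channel_gate(f, np.ones(2)), f)
    np.testing.assert_allclose(apply_channel_gate(f, np.zeros(2)), 0.0)
    with pytest.raises(ValueError):
        apply_channel_gate(f, np.ones(3))


def test_zero_weight_spatial_gate_is_half(rng):
    block = SpatialAttention(rng=rng)
    zero_params(block)
    gate = spatial_attention(rng.uniform(-1, 1, (8, 8, 3)), block)
    assert gate.shape == (8, 8, 1)
    np.testing.assert_allclose(gate, 0.5)


def test_spatial_gate_matches_dilated_conv_oracle(rng):
    block = SpatialAttention(rng=rng)
    f = rng.uniform(-1, 1, (9, 9, 4))
    np.testing.assert_allclose(spatial_attention(f, block), spatial_gate_oracle(f, block), rtol=1e-5)
    # constant input: every pooled map is constant, so the gate is constant
    # in the interior where the padded kernel support is fully inside
    const = np.full((16, 16, 4), 0.7)
    gate = spatial_attention(const, block)[..., 0]
    interior = gate[12:-12 or None, 12:-12 or None] if gate.shape[0] > 24 else gate[12:13, 12:13]
    np.testing.assert_allclose(interior, interior.flat[0], rtol=1e-6)


def test_cbam_zero_weights_scale_quarter(rng):
    block = CBAM(4, rng=rng)
    zero_params(block)
    f = rng.uniform(-1, 1, (4, 4, 4))
    np.testing.assert_allclose(cbam(f, block), 0.25 * f, rtol=1e-6)
    np.testing.assert_allclose(cbam(np.zeros((4, 4, 4)), block), 0.0)


def test_cbam_matches_composed_oracle(rng):
    block = CBAM(4, rng=rng)
    f = rng.uniform(-1, 1, (4, 4, 4))
    np.testing.assert_allclose(cbam(f, block), cbam_oracle(f, block), rtol=1e-5)


def test_affinity_uniform_for_constant_projections(rng):
    block = PositionAttention(3, rng=rng)
    for conv in (block.conv_b, block.conv_z):
        conv.weight.data = np.zeros_like(conv.weight.data)
        conv.bias.data = np.full_like(conv.bias.data, 0.7)
    s = position_affinity(rng.uniform(-1, 1, (3, 3, 3)), block)
    np.testing.assert_allclose(s, 1.0 / 9.0, rtol=1e-6)


def test_affinity_single_position(rng):
    block = PositionAttention(2, rng=rng)
    s = position_affinity(rng.uniform(-1, 1, (1, 1, 2)), block)
    np.testing.assert_allclose(s, [[1.0]])


def test_affinity_matches_double_loop_oracle(rng):
    block = PositionAttention(2, rng=rng)
    f = rng.uniform(-1, 1, (2, 2, 2))
    s = position_affinity(f, block)
    np.testing.assert_allclose(s, affinity_oracle(f, block), rtol=1e-5, atol=1e-8)
    np.testing.assert_allclose(s.sum(axis=1), 1.0, atol=1e-6)


def test_position_attention_alpha_zero_is_exact_identity(rng):
    block = PositionAttention(4, rng=rng)
    f = rng.uniform(-1, 1, (4, 4, 4))
    out = position_attention(f, block)
    assert np.array_equal(out, f)  # alpha = 0: bitwise identity


def test_position_attention_alpha_one_uniform_affinity_adds_mean(rng):
    block = PositionAttention(3, rng=rng)
    for conv in (block.conv_b, block.conv_z):
        conv.weight.data = np.zeros_like(conv.weight.data)
        conv.bias.data = np.zeros_like(conv.bias.data)
    block.alpha.data = np.array(1.0, dtype=np.float32)
    f = rng.uniform(-1, 1, (3, 3, 3))
    d = f @ block.conv_d.weight.data[0, 0].astype(float) + block.conv_d.bias.data.astype(float)
    expected = f + d.reshape(9, 3).mean(axis=0)
    np.testing.assert_allclose(position_attention(f, block), expected, rtol=1e-5)


def test_position_attention_matches_loop_oracle(rng):
    block = PositionAttention(2, rng=rng)
    block.alpha.data = np.array(0.5, dtype=np.float32)
    f = rng.uniform(-1, 1, (2, 2, 2))
    np.testing.assert_allclose(position_attention(f, block), pam_oracle(f, block), rtol=1e-5)


def test_pcbam_zero_weights_is_1_25_f(rng):
    block = PCBAM(4, rng=rng)
    zero_params(block)
    f = rng.uniform(-1, 1, (4, 4, 4))
    np.testing.assert_allclose(pcbam(f, block), 1.25 * f, rtol=1e-6, atol=1e-7)
    np.testing.assert_allclose(pcbam(np.zeros((4, 4, 4)), block), 0.0)


def test_pcbam_equals_sum_of_branches(rng):
    block = PCBAM(4, rng=rng)
    block.pam.alpha.data = np.array(0.3, dtype=np.float32)
    f = rng.uniform(-1, 1, (4, 4, 4))
    expected = position_attention(f, block.pam) + cbam(f, block.cbam)
    np.testing.assert_allclose(pcbam(f, block), expected, rtol=1e-6)


@pytest.mark.parametrize("shape", [(1, 1, 1), (2, 3, 5), (4, 4, 4), (5, 2, 3)])
def test_shape_preservation_and_gate_ranges(rng, shape):
    h, w, c = shape
    f = rng.normal(0.0, 2.0, shape)
    ca = ChannelAttention(c, rng=rng)
    sa = SpatialAttention(rng=rng)
    block = PCBAM(c, rng=rng)
    gate_c = channel_attention(f, ca)
    gate_s = spatial_attention(f, sa)
    assert gate_c.shape == (c,) and np.all((gate_c > 0) & (gate_c < 1))
    assert gate_s.shape == (h, w, 1) and np.all((gate_s > 0) & (gate_s < 1))
    assert pcbam(f, block).shape == shape
    assert position_affinity(f, block.pam).shape == (h * w, h * w)


def test_affinity_rows_sum_to_one_many_random_inputs(rng):
    block = PositionAttention(3, rng=rng)
    for _ in range(25):
        f = rng.normal(0.0, 3.0, (3, 4, 3))
        s = position_affinity(f, block)
        np.testing.assert_allclose(s.sum(axis=1), 1.0, atol=1e-6)
        assert np.all(s >= 0)


def test_non_finite_input_rejected(rng):
    block = PCBAM(2, rng=rng)
    f = np.zeros((2, 2, 2))
    f[0, 0, 0] = np.nan
    with pytest.raises(ValueError):
        pcbam(f, block)


def test_every_pcbam_parameter_receives_gradient(rng):
    """With alpha moved off its zero initialization (as training does after
    its first step), every learnable parameter of PCBAM gets gradient."""
    block = PCBAM(4, rng=rng)
    block.pam.alpha.data = np.array(0.2, dtype=np.float32)
    f = Tensor(rng.normal(0.0, 1.0, (2, 4, 4, 4)))
    target = rng.normal(0.0, 1.0, (2, 4, 4, 4))
    ((block(f) - Tensor(target)) ** 2.0).mean().backward()
    for name, p in block.named_parameters():
        assert p.grad is not None and np.any(p.grad != 0), f"dead parameter {name}"
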