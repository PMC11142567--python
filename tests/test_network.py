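"""U-Net assembly: shape contracts, variants, determinism, checkpoints."""

import numpy as np
import pytest

from daunet.attention import PCBAM
from daunet.autodiff import Tensor
from daunet.layers import BatchNorm
from daunet.network import (
    ModelConfig,
    ResidualBlock,
    build_model,
    forward_with_taps,
    load_checkpoint,
    parameter_count,
    save_checkpoint,
    variant_config,
)

from conftest import zero_params

SMALL = dict(depth=3, base_filters=8, input_size=(32, 32, 1))


def _bn_identity(bn: BatchNorm) -> None:
    bn.running_mean = np.zeros_like(bn.running_mean)
    bn.running_var = np.ones_like(bn.running_var) - bn.eps


def test_residual_block_degenerate_parameters_pass_input_through(rng):
    block = ResidualBlock(4, 4, rng=rng)
    zero_params(block)
    block.bn1.gamma.data = np.ones_like(block.bn1.gamma.data)
    block.bn2.gamma.data = np.ones_like(block.bn2.gamma.data)
    _bn_identity(block.bn1)
    _bn_identity(block.bn2)
    block.eval()
    f = rng.uniform(-1.0, 1.0, (1, 5, 5, 4)).astype(np.float32)
    out = block(Tensor(f)).data
    np.testing.assert_allclose(out, f, atol=1e-6)


def test_residual_block_changes_channels(rng):
    block = ResidualBlock(8, 16, rng=rng)
    block.eval()
    out = block(Tensor(np.zeros((1, 16, 16, 8), dtype=np.float32)))
    assert out.shape == (1, 16, 16, 16)
    assert block.shortcut is not None  # 1x1 projection on channel change


def test_residual_block_matches_direct_conv_oracle(rng):
    """Eval-mode block with identity BN equals two explicit 3x3 convolutions
    plus the shortcut, evaluated by a plain numpy loop."""
    block = ResidualBlock(2, 2, rng=rng)
    _bn_identity(block.bn1)
    _bn_identity(block.bn2)
    block.eval()
    f = rng.uniform(-1.0, 1.0, (4, 4, 2)).astype(np.float32)

    def conv3x3(x, w, b):
        xp = np.pad(x, ((1, 1), (1, 1), (0, 0)))
        out = np.zeros((4, 4, w.shape[-1]))
        for i in range(4):
            for j in range(4):
                for di in range(3):
                    for dj in range(3):
                        out[i, j] += xp[i + di, j + dj, :] @ w[di, dj]
        return out + b

    w1, b1 = block.conv1.weight.data.astype(float), block.conv1.bias.data.astype(float)
    w2, b2 = block.conv2.weight.data.astype(float), block.conv2.bias.data.astype(float)
    h = np.maximum(conv3x3(f, w1, b1), 0.0)
    expected = np.maximum(conv3x3(h, w2, b2), 0.0) + f
    got = block(Tensor(f[None].astype(np.float32))).data[0]
    np.testing.assert_allclose(got, expected, rtol=1e-4, atol=1e-5)


def test_downsample_halves_and_rejects_odd(rng):
    from daunet.network import Downsample

    down = Downsample(4, 8, rng=rng)
    down.eval()
    out = down(Tensor(np.zeros((1, 8, 8, 4), dtype=np.float32)))
    assert out.shape == (1, 4, 4, 8)
    with pytest.raises(ValueError):
        down(Tensor(np.zeros((1, 7, 8, 4), dtype=np.float32)))


def test_downsample_averaging_kernel_preserves_constant(rng):
    from daunet.network import Downsample

    down = Downsample(1, 1, rng=rng)
    down.block.conv.weight.data = np.full((2, 2, 1, 1), 0.25, dtype=np.float32)
    down.block.conv.bias.data = np.zeros(1, dtype=np.float32)
    _bn_identity(down.block.bn)
    down.block.bn.gamma.data = np.ones(1, dtype=np.float32)
    down.eval()
    out = down(Tensor(np.full((1, 6, 6, 1), 0.8, dtype=np.float32))).data
    np.testing.assert_allclose(out, 0.8, rtol=1e-5)


@pytest.mark.parametrize("name,mode,use_swa", [
    ("i", "none", False), ("ii", "pam", False), ("iii", "cbam", False),
    ("iv", "pcbam", False), ("v", "pcbam", True),
])
def test_variant_configs_map_to_table(name, mode, use_swa):
    cfg = variant_config(name)
    assert cfg.attention_mode == mode and cfg.use_swa is use_swa


def test_pcbam_variant_instantiates_one_block_per_skip():
    model = build_model(variant_config("iv", **SMALL))
    blocks = [b for b in model.att_blocks if b is not None]
    assert len(blocks) == 3 and all(isinstance(b, PCBAM) for b in blocks)
    baseline = build_model(variant_config("i", **SMALL))
    assert all(b is None for b in baseline.att_blocks)


def test_forward_shape_and_sigmoid_range(rng):
    model = build_model(variant_config("v", **SMALL))
    out = model.predict_proba(np.zeros((32, 32, 1), dtype=np.float32))
    assert out.shape == (32, 32, 1)
    assert np.all((out > 0.0) & (out < 1.0))


def test_wrong_input_shape_rejected():
    model = build_model(variant_config("i", **SMALL))
    with pytest.raises(ValueError):
        model.predict_proba(np.zeros((16, 16, 1), dtype=np.float32))


def test_indivisible_input_dims_rejected():
    with pytest.raises(ValueError):
        ModelConfig(depth=4, input_size=(72, 72, 1)).validate()


def test_same_seed_builds_identical_models(rng):
    x = rng.uniform(0, 1, (32, 32, 1)).astype(np.float32)
    a = build_model(variant_config("v", seed=11, **SMALL))
    b = build_model(variant_config("v", seed=11, **SMALL))
    for (na, pa), (nb, pb) in zip(a.named_parameters(), b.named_parameters()):
        assert na == nb and np.array_equal(pa.data, pb.data)
    np.testing.assert_array_equal(a.predict_proba(x), b.predict_proba(x))
    c = build_model(variant_config("v", seed=12, **SMALL))
    assert not np.array_equal(a.predict_proba(x), c.predict_proba(x))


def test_forward_with_taps_names_and_resolutions(rng):
    model = build_model(variant_config("v", **SMALL))
    x = rng.uniform(0, 1, (32, 32, 1)).astype(np.float32)
    prob, taps = forward_with_taps(model, x)
    assert prob.shape == (32, 32, 1)
    assert taps["F_c"].shape[0] == 32 // 2 ** 3  # bottleneck resolution
    assert taps["F_a"].shape[:2] == (32, 32)
    assert "pcbam_1" in taps and "pcbam_3" in taps
    prob2, taps2 = forward_with_taps(model, x)
    np.testing.assert_array_equal(prob, prob2)
    np.testing.assert_array_equal(taps["F_c"], taps2["F_c"])


def test_attention_branch_is_identity_at_init_vs_baseline(rng):
    """PAM-gated skips start as the identity (alpha = 0), so a fresh pam
    variant differs from the baseline only through parameter draws; with
    parameters copied over, the forward passes agree exactly."""
    base = build_model(variant_config("i", seed=3, **SMALL))
    pam = build_model(variant_config("ii", seed=3, **SMALL))
    pam_params = dict(pam.named_parameters())
    for name, p in base.named_parameters():
        pam_params[name].data = p.data.copy()
    x = rng.uniform(0, 1, (32, 32, 1)).astype(np.float32)
    np.testing.assert_allclose(pam.predict_proba(x), base.predict_proba(x), atol=1e-6)


@pytest.mark.parametrize("name,count", [
    ("i", 159425), ("ii", 163628), ("iii", 160133), ("iv", 164336), ("v", 188976),
])
def test_parameter_count_is_a_function_of_config(name, count):
    assert parameter_count(build_model(variant_config(name, **SMALL))) == count


def test_checkpoint_roundtrip(tmp_path, rng):
    model = build_model(variant_config("v", seed=5, **SMALL))
    x = rng.uniform(0, 1, (32, 32, 1)).astype(np.float32)
    before = model.predict_proba(x)
    path = tmp_path / "model.npz"
    save_checkpoint(model, path)
    restored = load_checkpoint(path)
    assert restored.cfg == model.cfg
    np.testing.assert_array_equal(restored.predict_proba(x), before)


def test_checkpoint_version_and_shape_errors(tmp_path, rng):
    import json

    model = build_model(variant_config("i", **SMALL))
    path = tmp_path / "model.npz"
    save_checkpoint(model, path)
    data = dict(np.load(path))
    meta = json.loads(bytes(data["__meta__"]).decode())
    meta["version"] = "999"
    data["__meta__"] = np.bytes_(json.dumps(meta).encode())
    bad = tmp_path / "bad.npz"
    np.savez(bad, **data)
    with pytest.raises(ValueError, match="version"):
        load_checkpoint(bad)
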