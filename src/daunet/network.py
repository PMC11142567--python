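"""Residual U-Net with attention-gated skip connections.

The encoder stacks residual blocks (two 3x3 conv/BN/ReLU stages plus a
shortcut) and halves resolution with 2x2 stride-2 convolutions, doubling
channels at each stage. Each skip connection optionally passes through an
attention block (position attention, CBAM, or their PCBAM fusion) before
being concatenated with the upsampled decoder feature and refined by
another residual block. A q/k/v fusion attention block (:class:`~daunet.swa.Swa`)
can be inserted at the bottleneck (default) or after the first decoder
stage. The head is a 1x1 convolution with a sigmoid, so outputs are
per-pixel foreground probabilities.

Ablation variants:

===========  ==================  ========
variant      attention_mode      use_swa
===========  ==================  ========
``i``        none                False
``ii``       pam                 False
``iii``      cbam                False
``iv``       pcbam               False
``v``        pcbam               True
===========  ==================  ========
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

import numpy as np

from .attention import CBAM, PCBAM, PositionAttention
from .autodiff import Tensor, concatenate, relu, sigmoid
from .layers import BatchNorm, Conv2d, ConvBnRelu, ConvTranspose2d, Module
from .swa import Swa

__all__ = [
    "ModelConfig",
    "ResidualBlock",
    "SegModel",
    "build_model",
    "variant_config",
    "forward_with_taps",
    "parameter_count",
    "save_checkpoint",
    "load_checkpoint",
]

CHECKPOINT_VERSION = "1"

ATTENTION_MODES = ("none", "pam", "cbam", "pcbam")


@dataclass
class ModelConfig:
    """Architecture hyperparameters; the defaults build the full model."""

    depth: int = 4
    base_filters: int = 32
    attention_mode: str = "pcbam"
    use_swa: bool = True
    swa_placement: str = "bottleneck"  # or "decoder"
    input_size: tuple[int, int, int] = (128, 128, 1)
    seed: int = 0
    skip_fusion: str = "concat"  # or "add"
    ca_reduction: int = 8
    sa_inner_dense: bool = True
    pam_reduction: int | None = None
    swa_window_softmax: bool = False

    def validate(self) -> None:
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.base_filters < 1:
            raise ValueError("base_filters must be >= 1")
        if self.attention_mode not in ATTENTION_MODES:
            raise ValueError(f"attention_mode must be one of {ATTENTION_MODES}")
        if self.swa_placement not in ("bottleneck", "decoder"):
            raise ValueError("swa_placement must be 'bottleneck' or 'decoder'")
        if self.skip_fusion not in ("concat", "add"):
            raise ValueError("skip_fusion must be 'concat' or 'add'")
        h, w, c = self.input_size
        div = 2 ** self.depth
        if h % div or w % div:
            raise ValueError(
                f"input spatial dims {(h, w)} must be divisible by 2**depth = {div}"
            )
        if c != 1:
            raise ValueError("the model is single-channel (grayscale) only")


_VARIANTS = {
    "i": {"attention_mode": "none", "use_swa": False},
    "ii": {"attention_mode": "pam", "use_swa": False},
    "iii": {"attention_mode": "cbam", "use_swa": False},
    "iv": {"attention_mode": "pcbam", "use_swa": False},
    "v": {"attention_mode": "pcbam", "use_swa": True},
}


def variant_config(name: str, **overrides) -> ModelConfig:
    """Config for one of the ablation variants ``i`` ... ``v``."""
    if name not in _VARIANTS:
        raise ValueError(f"unknown variant {name!r}; choose from {sorted(_VARIANTS)}")
    kwargs = dict(_VARIANTS[name])
    kwargs.update(overrides)
    return ModelConfig(**kwargs)


class ResidualBlock(Module):
    """Two conv/BN/ReLU stages plus a (projected) shortcut, summed."""

    def __init__(self, c_in: int, c_out: int, *, rng: np.random.Generator, dtype=np.float32):
        self.conv1 = Conv2d(c_in, c_out, 3, rng=rng, dtype=dtype)
        self.bn1 = BatchNorm(c_out, dtype=dtype)
        self.conv2 = Conv2d(c_out, c_out, 3, rng=rng, dtype=dtype)
        self.bn2 = BatchNorm(c_out, dtype=dtype)
        self.shortcut = None if c_in == c_out else Conv2d(c_in, c_out, 1, rng=rng, dtype=dtype)

    def forward(self, x: Tensor) -> Tensor:
        h = relu(self.bn1(self.conv1(x)))
        h = relu(self.bn2(self.conv2(h)))
        sc = x if self.shortcut is None else self.shortcut(x)
        return h + sc


class Downsample(Module):
    """2x2 stride-2 convolution with BN/ReLU; halves both spatial dims."""

    def __init__(self, c_in: int, c_out: int, *, rng: np.random.Generator, dtype=np.float32):
        self.block = ConvBnRelu(c_in, c_out, 2, stride=2, rng=rng, dtype=dtype)

    def forward(self, x: Tensor) -> Tensor:
        _, h, w, _ = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"cannot downsample odd spatial dims {(h, w)}")
        return self.block(x)


def _make_attention(cfg: ModelConfig, channels: int, rng: np.random.Generator, dtype) -> Module | None:
    if cfg.attention_mode == "none":
        return None
    if cfg.attention_mode == "pam":
        return PositionAttention(channels, reduction=cfg.pam_reduction, rng=rng, dtype=dtype)
    if cfg.attention_mode == "cbam":
        return CBAM(channels, reduction=cfg.ca_reduction, inner_dense=cfg.sa_inner_dense, rng=rng, dtype=dtype)
    return PCBAM(channels, reduction=cfg.ca_reduction, pam_reduction=cfg.pam_reduction,
                 inner_dense=cfg.sa_inner_dense, rng=rng, dtype=dtype)


class SegModel(Module):
    """The assembled encoder/decoder; see the module docstring."""

    def __init__(self, cfg: ModelConfig, *, dtype=np.float32):
        cfg.validate()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        d, base = cfg.depth, cfg.base_filters
        widths = [base * 2 ** s for s in range(d)]        # encoder stages
        bottleneck_width = base * 2 ** d

        # stage s sees the output of downsample s-1, which already carries
        # widths[s] channels; only the first block changes the channel count
        self.enc_blocks = [ResidualBlock(cfg.input_size[2], widths[0], rng=rng, dtype=dtype)]
        self.enc_blocks += [ResidualBlock(widths[s], widths[s], rng=rng, dtype=dtype) for s in range(1, d)]
        self.downs = [
            Downsample(widths[s], widths[s + 1] if s + 1 < d else bottleneck_width, rng=rng, dtype=dtype)
            for s in range(d)
        ]
        self.bottleneck = ResidualBlock(bottleneck_width, bottleneck_width, rng=rng, dtype=dtype)
        self.swa = Swa(bottleneck_width if cfg.swa_placement == "bottleneck" else widths[-1],
                       window_softmax=cfg.swa_window_softmax, rng=rng, dtype=dtype) if cfg.use_swa else None
        self.att_blocks = [_make_attention(cfg, c, rng, dtype) for c in widths]

        self.ups = []
        self.dec_blocks = []
        c_prev = bottleneck_width
        for c_skip in reversed(widths):
            self.ups.append(ConvTranspose2d(c_prev, c_skip, rng=rng, dtype=dtype))
            c_fused = 2 * c_skip if cfg.skip_fusion == "concat" else c_skip
            self.dec_blocks.append(ResidualBlock(c_fused, c_skip, rng=rng, dtype=dtype))
            c_prev = c_skip
        self.head = Conv2d(base, 1, 1, rng=rng, dtype=dtype)
        self._dtype = dtype

    # ----------------------------------------------------------------- passes
    def _check_input(self, x) -> Tensor:
        if isinstance(x, Tensor):
            data = x.data
        else:
            data = np.asarray(x, dtype=self._dtype)
        if data.ndim == 3:
            data = data[None]
        h, w, c = self.cfg.input_size
        if data.ndim != 4 or data.shape[1:] != (h, w, c):
            raise ValueError(f"expected input of shape (batch, {h}, {w}, {c}), got {data.shape}")
        return x if isinstance(x, Tensor) else Tensor(data)

    def forward(self, x, collect_taps: dict | None = None) -> Tensor:
        x = self._check_input(x)
        skips: list[Tensor] = []
        h = x
        for block, down in zip(self.enc_blocks, self.downs):
            h = block(h)
            skips.append(h)
            h = down(h)
        h = self.bottleneck(h)
        if self.swa is not None and self.cfg.swa_placement == "bottleneck":
            h = self.swa(h)
        if collect_taps is not None:
            collect_taps["F_c"] = h.data.copy()

        depth = self.cfg.depth
        for stage, (up, dec) in enumerate(zip(self.ups, self.dec_blocks)):
            skip_index = depth - 1 - stage  # deepest skip first
            skip = skips[skip_index]
            att = self.att_blocks[skip_index]
            if att is not None:
                skip = att(skip)
            if collect_taps is not None:
                collect_taps[f"skip_{skip_index + 1}"] = skip.data.copy()
                if att is not None:
                    collect_taps[f"{self.cfg.attention_mode}_{stage + 1}"] = skip.data.copy()
            h = up(h)
            if self.cfg.skip_fusion == "concat":
                h = concatenate([h, skip], axis=3)
            else:
                h = h + skip
            h = dec(h)
            if self.swa is not None and self.cfg.swa_placement == "decoder" and stage == 0:
                h = self.swa(h)
        # confine probabilities to the open interval in float arithmetic:
        # extreme logits would otherwise round the sigmoid to exactly 0 or 1
        # (where its gradient is zero anyway); 1e-7 is the losses' clip floor
        return sigmoid(self.head(h)).clip(1e-7, 1.0 - 1e-7)

    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        """Eval-mode forward; accepts (H, W, 1) or (batch, H, W, 1)."""
        single = np.asarray(images).ndim == 3
        was_training = self.training
        self.eval()
        try:
            probs = self.forward(images).data
        finally:
            self.train(was_training)
        return probs[0] if single else probs


def build_model(cfg: ModelConfig) -> SegModel:
    return SegModel(cfg)


def forward_with_taps(model: SegModel, image) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Eval-mode prediction plus named intermediate activations.

    Taps: ``skip_k`` is the attention-gated skip at encoder stage ``k``
    (1 = shallowest), ``F_a``/``F_b`` alias the first two, ``F_c`` is the
    bottleneck output, and ``<mode>_j`` numbers attention outputs from the
    deepest skip upward (``pcbam_1`` sits just above the bottleneck).
    """
    taps: dict[str, np.ndarray] = {}
    was_training = model.training
    model.eval()
    try:
        out = model.forward(image, collect_taps=taps)
    finally:
        model.train(was_training)
    if "skip_1" in taps:
        taps["F_a"] = taps["skip_1"]
    if "skip_2" in taps:
        taps["F_b"] = taps["skip_2"]
    probs = out.data
    if np.asarray(image if not isinstance(image, Tensor) else image.data).ndim == 3:
        probs = probs[0]
        taps = {k: v[0] for k, v in taps.items()}
    return probs, taps


def parameter_count(model: SegModel) -> int:
    return int(sum(p.data.size for p in model.parameters()))


# ---------------------------------------------------------------- checkpoints
def save_checkpoint(model: SegModel, path) -> None:
    arrays = {f"param/{name}": p.data for name, p in model.named_parameters()}
    arrays.update({f"buffer/{name}": b for name, b in model.named_buffers()})
    meta = {"version": CHECKPOINT_VERSION, "config": dataclasses.asdict(model.cfg)}
    np.savez(path, __meta__=np.bytes_(json.dumps(meta).encode()), **arrays)


def load_checkpoint(path) -> SegModel:
    with np.load(path) as archive:
        if "__meta__" not in archive:
            raise ValueError(f"{path}: not a daunet checkpoint (missing metadata)")
        meta = json.loads(bytes(archive["__meta__"]).decode())
        if meta.get("version") != CHECKPOINT_VERSION:
            raise ValueError(
                f"{path}: checkpoint version {meta.get('version')!r} is not supported "
                f"(expected {CHECKPOINT_VERSION!r})"
            )
        cfg_dict = meta["config"]
        cfg_dict["input_size"] = tuple(cfg_dict["input_size"])
        cfg = ModelConfig(**cfg_dict)
        model = build_model(cfg)
        for name, p in model.named_parameters():
            stored = archive[f"param/{name}"]
            if stored.shape != p.data.shape:
                raise ValueError(
                    f"{path}: parameter {name} has shape {stored.shape}, "
                    f"model expects {p.data.shape} — incompatible checkpoint"
                )
            p.data = stored.astype(p.data.dtype)
        for name, _ in model.named_buffers():
            key = f"buffer/{name}"
            if key in archive:
                _assign_buffer(model, name, archive[key])
    return model


def _assign_buffer(model: Module, dotted: str, value: np.ndarray) -> None:
    obj = model
    parts = dotted.split(".")
    for part in parts[:-1]:
        obj = obj[int(part)] if isinstance(obj, (list, tuple)) else getattr(obj, part)
    setattr(obj, parts[-1], value)
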