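"""Training loop and run orchestration.

``fit`` is the library-level loop: seeded shuffling, Adam on the combined
Dice+BCE+Focal loss, per-epoch train/validation tracking, and
best-validation-Dice checkpoint selection. ``run_training`` wraps it with
data resolution (directory or synthetic phantoms), run-directory layout
(resolved config snapshot, log, history, checkpoints), and is what the CLI
calls.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .autodiff import Tensor
from .data import ImageMaskPair, PhantomConfig, generate_phantoms, load_image_mask_dir, split_dataset
from .evaluation import DatasetReport, binarize, evaluate_dataset, format_report, write_report
from .network import ModelConfig, SegModel, build_model, forward_with_taps, load_checkpoint, save_checkpoint
from .objectives import LossConfig, combined_loss
from .optim import Adam, SGD

__all__ = ["RunConfig", "TrainingHistory", "fit", "run_training", "predict_to_dir", "evaluate_to_dir", "export_heatmaps"]


@dataclass
class RunConfig:
    model: ModelConfig = field(default_factory=ModelConfig)
    loss: LossConfig = field(default_factory=LossConfig)
    optimizer: str = "adam"
    learning_rate: float = 1e-4
    epochs: int = 50
    batch_size: int = 8
    seed: int = 0
    threshold: float = 0.5
    data_dir: str | None = None            # BUSI-layout directory ...
    phantoms: PhantomConfig | None = None  # ... or a synthetic source
    split_fractions: tuple[float, float, float] = (0.70, 0.10, 0.20)
    early_stop_train_dice: float | None = None
    eval_every: int = 1

    def validate(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        self.model.validate()
        self.loss.validate()


@dataclass
class TrainingHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    train_dice: list[float] = field(default_factory=list)
    val_dice: list[float] = field(default_factory=list)
    epoch_seconds: list[float] = field(default_factory=list)
    best_epoch: int = -1

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def _batch_arrays(pairs: list[ImageMaskPair]) -> tuple[np.ndarray, np.ndarray]:
    images = np.stack([p.image for p in pairs]).astype(np.float32)
    masks = np.stack([p.mask for p in pairs]).astype(np.float32)
    return images, masks


def _mean_hard_dice(model: SegModel, pairs: list[ImageMaskPair], threshold: float) -> float:
    report = evaluate_dataset(model, pairs, threshold=threshold)
    return report.mean.dice


def _dataset_loss(model: SegModel, pairs: list[ImageMaskPair], cfg: RunConfig) -> float:
    images, masks = _batch_arrays(pairs)
    probs = model.predict_proba(images)
    return float(combined_loss(masks.astype(np.float64), probs.astype(np.float64), cfg.loss))


def fit(
    model: SegModel,
    train_pairs: list[ImageMaskPair],
    val_pairs: list[ImageMaskPair] | None = None,
    cfg: RunConfig | None = None,
    checkpoint_path=None,
    log=None,
) -> TrainingHistory:
    """Train in place; returns the history. Checkpoints best validation Dice.

    When no validation set is given, the best epoch tracks training Dice
    instead. ``log`` is an optional callable receiving one line per epoch.
    """
    cfg = cfg or RunConfig(model=model.cfg)
    cfg.validate()
    if not train_pairs:
        raise ValueError("empty training set")
    optimizer_cls = {"adam": Adam, "sgd": SGD}.get(cfg.optimizer.lower())
    if optimizer_cls is None:
        raise ValueError(f"unknown optimizer {cfg.optimizer!r}")
    optimizer = optimizer_cls(model.parameters(), lr=cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed)
    history = TrainingHistory()
    best_dice = -1.0
    for epoch in range(cfg.epochs):
        tic = time.perf_counter()
        model.train()
        order = rng.permutation(len(train_pairs))
        epoch_losses = []
        for start in range(0, len(order), cfg.batch_size):
            chunk = [train_pairs[i] for i in order[start : start + cfg.batch_size]]
            images, masks = _batch_arrays(chunk)
            probs = model.forward(Tensor(images))
            loss = combined_loss(Tensor(masks), probs, cfg.loss)
            value = float(loss.data)
            if not np.isfinite(value):
                raise RuntimeError(
                    f"non-finite loss ({value}) at epoch {epoch + 1}; "
                    "check learning rate and input scaling"
                )
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            epoch_losses.append(value)
        model.eval()
        history.train_loss.append(float(np.mean(epoch_losses)))
        monitor = None
        if epoch % cfg.eval_every == 0 or epoch == cfg.epochs - 1:
            train_dice = _mean_hard_dice(model, train_pairs, cfg.threshold)
            history.train_dice.append(train_dice)
            if val_pairs:
                history.val_loss.append(_dataset_loss(model, val_pairs, cfg))
                history.val_dice.append(_mean_hard_dice(model, val_pairs, cfg.threshold))
                monitor = history.val_dice[-1]
            else:
                monitor = train_dice
        history.epoch_seconds.append(time.perf_counter() - tic)
        if log is not None:
            log(
                f"epoch {epoch + 1}/{cfg.epochs} "
                f"loss={history.train_loss[-1]:.4f} "
                + (f"train_dice={history.train_dice[-1]:.4f} " if monitor is not None else "")
                + (f"val_dice={history.val_dice[-1]:.4f}" if val_pairs and monitor is not None else "")
            )
        if monitor is not None and monitor > best_dice:
            best_dice = monitor
            history.best_epoch = epoch
            if checkpoint_path is not None:
                save_checkpoint(model, checkpoint_path)
        if (
            cfg.early_stop_train_dice is not None
            and history.train_dice
            and history.train_dice[-1] >= cfg.early_stop_train_dice
        ):
            break
    return history


def _resolve_pairs(cfg: RunConfig) -> list[ImageMaskPair]:
    if (cfg.data_dir is None) == (cfg.phantoms is None):
        raise ValueError("exactly one of data_dir or phantoms must be set")
    if cfg.data_dir is not None:
        size = cfg.model.input_size[0]
        pairs = load_image_mask_dir(cfg.data_dir, size=size)
    else:
        pairs = generate_phantoms(cfg.phantoms)
    if not pairs:
        raise ValueError("data source resolved to an empty dataset")
    return pairs


def run_training(cfg: RunConfig, out_dir) -> tuple[SegModel, TrainingHistory, DatasetReport]:
    """End-to-end run: resolve data, split, train, checkpoint, evaluate.

    Writes into ``out_dir``: ``config.json`` (resolved config snapshot),
    ``train.log``, ``history.json``, ``best.npz`` / ``last.npz``
    checkpoints, and ``metrics.tsv`` / ``metrics.txt`` for the test split.
    """
    cfg.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    from . import __version__  # local import to avoid a cycle at import time

    snapshot = dataclasses.asdict(cfg)
    snapshot["daunet_version"] = __version__
    snapshot["numpy_version"] = np.__version__
    (out_dir / "config.json").write_text(json.dumps(snapshot, indent=2, default=str))

    pairs = _resolve_pairs(cfg)
    train_pairs, val_pairs, test_pairs = split_dataset(pairs, cfg.split_fractions, seed=cfg.seed)
    model = build_model(cfg.model)
    log_path = out_dir / "train.log"
    with open(log_path, "w") as log_file:
        log_file.write(f"seed={cfg.seed} n_train={len(train_pairs)} n_val={len(val_pairs)} n_test={len(test_pairs)}\n")

        def log(line: str) -> None:
            log_file.write(line + "\n")
            log_file.flush()

        history = fit(model, train_pairs, val_pairs, cfg, checkpoint_path=out_dir / "best.npz", log=log)
    save_checkpoint(model, out_dir / "last.npz")
    (out_dir / "history.json").write_text(json.dumps(history.as_dict(), indent=2))

    best = load_checkpoint(out_dir / "best.npz") if (out_dir / "best.npz").exists() else model
    report = evaluate_dataset(best, test_pairs or val_pairs or train_pairs, threshold=cfg.threshold)
    write_report(report, out_dir / "metrics.tsv")
    (out_dir / "metrics.txt").write_text(format_report(report) + "\n")
    return model, history, report


# ------------------------------------------------------------------ inference
def predict_to_dir(checkpoint_path, inputs, out_dir, threshold: float = 0.5, save_probability: bool = False) -> list[Path]:
    """Write one binary mask PNG (0/255) per input image; returns the paths."""
    from PIL import Image

    model = load_checkpoint(checkpoint_path)
    size = model.cfg.input_size[0]
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    inputs = Path(inputs)
    if inputs.is_dir():
        files = sorted(p for p in inputs.rglob("*.png") if "_mask" not in p.stem)
    else:
        files = [inputs]
    written: list[Path] = []
    from .data import _load_gray
    from skimage.transform import resize as _resize

    for path in files:
        image = _load_gray(path)
        if image.shape != (size, size):
            image = _resize(image, (size, size), order=1, anti_aliasing=True, preserve_range=True)
        prob = model.predict_proba(image.astype(np.float32)[..., None])[..., 0]
        mask = binarize(prob, threshold)
        out_path = out_dir / f"{path.stem}_pred.png"
        Image.fromarray((mask * 255).astype(np.uint8), mode="L").save(out_path)
        written.append(out_path)
        if save_probability:
            prob_path = out_dir / f"{path.stem}_prob.png"
            Image.fromarray(np.round(prob * 255).astype(np.uint8), mode="L").save(prob_path)
            written.append(prob_path)
    return written


def evaluate_to_dir(checkpoint_path, data, out_dir, threshold: float = 0.5) -> DatasetReport:
    """Evaluate a checkpoint on a directory or phantom config; write reports."""
    model = load_checkpoint(checkpoint_path)
    size = model.cfg.input_size[0]
    if isinstance(data, PhantomConfig):
        pairs = generate_phantoms(data)
    else:
        pairs = load_image_mask_dir(data, size=size)
    report = evaluate_dataset(model, pairs, threshold=threshold)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_report(report, out_dir / "metrics.tsv")
    (out_dir / "metrics.txt").write_text(format_report(report) + "\n")
    return report


def _normalize_heatmap(tap: np.ndarray) -> np.ndarray:
    """Channel-mean activation, min-max normalized with a guarded divide."""
    heat = np.asarray(tap, dtype=np.float64).mean(axis=-1)
    span = heat.max() - heat.min()
    if span < 1e-12:
        return np.full(heat.shape, 0.5)
    return (heat - heat.min()) / span


def export_heatmaps(model_or_checkpoint, image, out_dir, taps: list[str] | None = None, mask: np.ndarray | None = None) -> dict[str, Path]:
    """Export per-tap activation heatmaps plus an overview panel.

    Each requested tap is reduced to its channel-mean map, min-max
    normalized, upsampled to the model resolution, and written as a PNG;
    a matplotlib panel with input, (optional) ground truth, prediction, and
    all heatmaps is written alongside.
    """
    from PIL import Image as PILImage
    from skimage.transform import resize as _resize

    model = model_or_checkpoint if isinstance(model_or_checkpoint, SegModel) else load_checkpoint(model_or_checkpoint)
    size = model.cfg.input_size[0]
    image = np.asarray(image, dtype=np.float32)
    if image.ndim == 2:
        image = image[..., None]
    prob, all_taps = forward_with_taps(model, image)
    if taps is None:
        taps = sorted(all_taps)
    unknown = [t for t in taps if t not in all_taps]
    if unknown:
        raise KeyError(f"unknown tap(s) {unknown}; available: {sorted(all_taps)}")

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    heats: dict[str, np.ndarray] = {}
    for name in taps:
        heat = _normalize_heatmap(all_taps[name])
        if heat.shape != (size, size):
            heat = _resize(heat, (size, size), order=1, preserve_range=True)
        heats[name] = heat
        path = out_dir / f"heatmap_{name}.png"
        PILImage.fromarray(np.round(heat * 255).astype(np.uint8), mode="L").save(path)
        written[name] = path

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    panels = [("input", image[..., 0])]
    if mask is not None:
        panels.append(("ground truth", np.squeeze(mask)))
    panels.append(("prediction", prob[..., 0]))
    panels.extend((name, heats[name]) for name in taps)
    fig, axes = plt.subplots(1, len(panels), figsize=(2.2 * len(panels), 2.6))
    for ax, (title, data) in zip(np.atleast_1d(axes), panels):
        ax.imshow(data, cmap="gray" if title in ("input", "ground truth", "prediction") else "jet")
        ax.set_title(title, fontsize=8)
        ax.axis("off")
    panel_path = out_dir / "panel.png"
    fig.tight_layout()
    fig.savefig(panel_path, dpi=120)
    plt.close(fig)
    written["panel"] = panel_path
    return written
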