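"""Hard segmentation metrics: Dice, IoU, accuracy, precision, recall.

Predictions are thresholded (ties go to foreground: ``p >= threshold``),
tallied into integer confusion counts, and summarized per image. Dataset
aggregation reports both the mean of per-image metrics (the primary figure
in the breast-ultrasound segmentation literature) and micro-pooled metrics
computed from the summed counts.

Zero-denominator convention: when ground truth and prediction are both
empty, overlap metrics (precision, recall, IoU, Dice) are 1.0; when exactly
one is empty they are 0.0.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass

import numpy as np

from .objectives import ConfusionCounts

__all__ = [
    "MetricsReport",
    "binarize",
    "confusion",
    "metrics",
    "DatasetReport",
    "evaluate_dataset",
    "evaluate_pairs",
    "write_report",
    "format_report",
]

_METRIC_NAMES = ("dice", "iou", "accuracy", "precision", "recall")


@dataclass
class MetricsReport:
    dice: float
    iou: float
    accuracy: float
    precision: float
    recall: float
    granularity: str = "per_image"
    image_id: str = ""

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in _METRIC_NAMES}


def binarize(p: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Hard mask: 1 where p >= threshold."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    p = np.asarray(p)
    return (p >= threshold).astype(np.uint8)


def confusion(y: np.ndarray, y_hat: np.ndarray) -> ConfusionCounts:
    """Integer pixel tallies between two binary masks."""
    y = np.asarray(y)
    y_hat = np.asarray(y_hat)
    if y.shape != y_hat.shape:
        raise ValueError(f"shape mismatch: {y.shape} vs {y_hat.shape}")
    for name, arr in (("ground truth", y), ("prediction", y_hat)):
        if not np.isin(arr, (0, 1)).all():
            raise ValueError(f"{name} mask is not binary")
    y = y.astype(bool)
    y_hat = y_hat.astype(bool)
    tp = int(np.count_nonzero(y & y_hat))
    fp = int(np.count_nonzero(~y & y_hat))
    fn = int(np.count_nonzero(y & ~y_hat))
    tn = int(np.count_nonzero(~y & ~y_hat))
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def _ratio(num: float, denom: float, both_empty: bool) -> float:
    if denom == 0:
        return 1.0 if both_empty else 0.0
    return num / denom


def metrics(counts: ConfusionCounts, granularity: str = "per_image", image_id: str = "") -> MetricsReport:
    counts.validate()
    if counts.total == 0:
        raise ValueError("confusion counts are all zero; nothing to score")
    tp, fp, fn, tn = counts.tp, counts.fp, counts.fn, counts.tn
    both_empty = (tp + fn == 0) and (tp + fp == 0)  # no foreground anywhere
    return MetricsReport(
        dice=_ratio(2 * tp, 2 * tp + fp + fn, both_empty),
        iou=_ratio(tp, tp + fp + fn, both_empty),
        accuracy=(tp + tn) / counts.total,
        precision=_ratio(tp, tp + fp, both_empty),
        recall=_ratio(tp, tp + fn, both_empty),
        granularity=granularity,
        image_id=image_id,
    )


@dataclass
class DatasetReport:
    per_image: list[MetricsReport]
    mean: MetricsReport
    micro: MetricsReport


def evaluate_pairs(
    masks: list[np.ndarray], probs: list[np.ndarray], threshold: float = 0.5, ids: list[str] | None = None
) -> DatasetReport:
    """Score predicted probability maps against ground-truth masks."""
    if len(masks) == 0:
        raise ValueError("cannot evaluate an empty dataset")
    if len(masks) != len(probs):
        raise ValueError("masks and predictions differ in length")
    ids = ids or [str(i) for i in range(len(masks))]
    per_image: list[MetricsReport] = []
    pooled = ConfusionCounts(0.0, 0.0, 0.0, 0.0)
    for mask, prob, image_id in zip(masks, probs, ids):
        counts = confusion(mask, binarize(prob, threshold))
        per_image.append(metrics(counts, image_id=image_id))
        pooled.tp += counts.tp
        pooled.fp += counts.fp
        pooled.fn += counts.fn
        pooled.tn += counts.tn
    mean = MetricsReport(
        **{name: float(np.mean([getattr(r, name) for r in per_image])) for name in _METRIC_NAMES},
        granularity="mean_over_images",
        image_id="MEAN",
    )
    micro = metrics(pooled, granularity="micro_pooled", image_id="MICRO")
    return DatasetReport(per_image=per_image, mean=mean, micro=micro)


def evaluate_dataset(model, pairs, threshold: float = 0.5, batch_size: int = 8) -> DatasetReport:
    """Run ``model`` over :class:`~daunet.data.ImageMaskPair` items and score."""
    pairs = list(pairs)
    if not pairs:
        raise ValueError("cannot evaluate an empty dataset")
    probs: list[np.ndarray] = []
    for start in range(0, len(pairs), batch_size):
        chunk = pairs[start : start + batch_size]
        batch = np.stack([p.image for p in chunk])
        out = model.predict_proba(batch)
        probs.extend(out[i] for i in range(len(chunk)))
    masks = [p.mask for p in pairs]
    ids = [p.id for p in pairs]
    return evaluate_pairs(masks, probs, threshold=threshold, ids=ids)


def format_report(report: DatasetReport) -> str:
    header = f"{'image':<24}" + "".join(f"{name:>11}" for name in _METRIC_NAMES)
    lines = [header, "-" * len(header)]
    for row in report.per_image + [report.mean, report.micro]:
        lines.append(
            f"{row.image_id:<24}" + "".join(f"{getattr(row, name):>11.4f}" for name in _METRIC_NAMES)
        )
    return "\n".join(lines)


def write_report(report: DatasetReport, path) -> None:
    """Write one row per image plus MEAN / MICRO aggregate rows (TSV)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["image_id", "granularity", *_METRIC_NAMES])
        for row in report.per_image + [report.mean, report.micro]:
            writer.writerow([row.image_id, row.granularity, *[f"{getattr(row, name):.6f}" for name in _METRIC_NAMES]])
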