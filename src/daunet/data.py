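"""Synthetic ultrasound phantoms, BUSI-layout I/O, and dataset splitting.

The phantom generator emulates the gross appearance of a breast-ultrasound
B-scan: a smooth low-frequency background field, multiplied by unit-mean
gamma-distributed speckle, containing a single darker (hypoechoic) lesion
whose boundary is a harmonically perturbed ellipse (star-convex around its
center). The binary ground-truth mask is the exact lesion indicator taken
before the point-spread blur, so mask and image are related the way a
manual annotation relates to a physical scan. Every phantom is a pure
function of ``(seed, index)``.

Real data follows the BUSI directory dialect: ``<root>/<class>/<name>.png``
with sibling ``<name>_mask.png`` (multiple ``_mask_*`` files are unioned).
Images are converted to grayscale, resized to the working resolution
(bilinear), rescaled to [0, 1]; masks are resized with nearest-neighbor
interpolation and re-binarized at 0.5.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage
from skimage.transform import resize

__all__ = [
    "ImageMaskPair",
    "PhantomConfig",
    "generate_phantom",
    "generate_phantoms",
    "save_dataset",
    "load_image_mask_dir",
    "find_pairs",
    "split_dataset",
    "kfold_split",
]


@dataclass
class ImageMaskPair:
    image: np.ndarray  # (H, W, 1) float32 in [0, 1]
    mask: np.ndarray   # (H, W, 1) float32, strictly {0, 1}
    id: str
    class_label: str = "synthetic"

    def validate(self) -> None:
        if self.image.shape != self.mask.shape:
            raise ValueError(f"image shape {self.image.shape} != mask shape {self.mask.shape}")
        if not np.all(np.isfinite(self.image)):
            raise ValueError("image contains non-finite values")
        if not np.isin(self.mask, (0.0, 1.0)).all():
            raise ValueError("mask is not strictly binary")


@dataclass
class PhantomConfig:
    n_images: int = 32
    seed: int = 0
    lesion_area_fraction: tuple[float, float] = (0.02, 0.25)
    lesion_contrast: float = 0.35   # mean fractional intensity drop inside the lesion
    speckle_strength: float = 0.15  # variance of the unit-mean multiplicative speckle
    blur_sigma: float = 1.5         # point-spread smoothing, pixels
    shape_irregularity: float = 0.3  # boundary harmonic perturbation amplitude
    image_size: int = 128

    def validate(self) -> None:
        lo, hi = self.lesion_area_fraction
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError(f"lesion_area_fraction must satisfy 0 < lo <= hi < 1, got {(lo, hi)}")
        if self.n_images < 1:
            raise ValueError("n_images must be >= 1")
        if np.sqrt(lo * self.image_size ** 2 / np.pi) < 2.0:
            raise ValueError("lesion area range infeasible: minimum radius below 2 pixels")


def _rng_for(cfg: PhantomConfig, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([cfg.seed, index]))


def generate_phantom(cfg: PhantomConfig, index: int) -> ImageMaskPair:
    """One speckled phantom with a single hypoechoic lesion; deterministic."""
    cfg.validate()
    rng = _rng_for(cfg, index)
    size = cfg.image_size

    # smooth low-frequency background echogenicity in roughly [0.45, 0.8]
    coarse = rng.uniform(0.0, 1.0, size=(size, size))
    background = ndimage.gaussian_filter(coarse, sigma=size / 8.0, mode="reflect")
    span = background.max() - background.min()
    background = 0.45 + 0.35 * (background - background.min()) / max(span, 1e-12)

    # star-convex lesion: perturbed ellipse in polar form around its center
    area = rng.uniform(*cfg.lesion_area_fraction) * size * size
    r0 = np.sqrt(area / np.pi)
    cy, cx = rng.uniform(0.3 * size, 0.7 * size, size=2)
    aspect = rng.uniform(0.7, 1.4)
    theta0 = rng.uniform(0.0, 2 * np.pi)
    harmonics = np.arange(2, 6)
    amp = cfg.shape_irregularity * rng.uniform(-1.0, 1.0, size=harmonics.size) / harmonics
    phase = rng.uniform(0.0, 2 * np.pi, size=harmonics.size)

    yy, xx = np.mgrid[0:size, 0:size]
    dy, dx = yy - cy, xx - cx
    rot_y = np.cos(theta0) * dy - np.sin(theta0) * dx
    rot_x = np.sin(theta0) * dy + np.cos(theta0) * dx
    radius = np.hypot(rot_y * aspect, rot_x / aspect)
    angle = np.arctan2(rot_y, rot_x)
    boundary = r0 * (1.0 + np.sum(amp[:, None, None] * np.cos(harmonics[:, None, None] * angle + phase[:, None, None]), axis=0))
    boundary = np.maximum(boundary, 0.2 * r0)
    mask = (radius <= boundary).astype(np.float32)

    image = background * (1.0 - cfg.lesion_contrast * mask)
    if cfg.speckle_strength > 0:
        shape_k = 1.0 / cfg.speckle_strength
        image = image * rng.gamma(shape_k, scale=1.0 / shape_k, size=image.shape)
    image = ndimage.gaussian_filter(image, sigma=cfg.blur_sigma, mode="reflect")
    image = np.clip(image, 0.0, 1.0)
    # quantize to the 8-bit grid so PNG round-trips are lossless
    image = np.round(image * 255.0) / 255.0

    pair = ImageMaskPair(
        image=image.astype(np.float32)[..., None],
        mask=mask[..., None],
        id=f"synthetic_{index:04d}",
        class_label="synthetic",
    )
    pair.validate()
    return pair


def generate_phantoms(cfg: PhantomConfig) -> list[ImageMaskPair]:
    return [generate_phantom(cfg, i) for i in range(cfg.n_images)]


# ------------------------------------------------------------------ PNG I/O
def _save_png(array: np.ndarray, path: Path) -> None:
    data = np.round(np.squeeze(np.asarray(array, dtype=np.float64)) * 255.0).astype(np.uint8)
    Image.fromarray(data, mode="L").save(path)


def save_dataset(pairs: list[ImageMaskPair], out_dir) -> Path:
    """Write pairs in the BUSI directory dialect, grouped by class label."""
    out_dir = Path(out_dir)
    for pair in pairs:
        pair.validate()
        class_dir = out_dir / pair.class_label
        class_dir.mkdir(parents=True, exist_ok=True)
        _save_png(pair.image, class_dir / f"{pair.id}.png")
        _save_png(pair.mask, class_dir / f"{pair.id}_mask.png")
    return out_dir


def find_pairs(root) -> tuple[list[tuple[Path, list[Path]]], list[Path]]:
    """Match image PNGs with their ``*_mask*`` siblings.

    Returns (matched, images_without_mask); mask files themselves are never
    treated as images.
    """
    root = Path(root)
    matched: list[tuple[Path, list[Path]]] = []
    missing: list[Path] = []
    for image_path in sorted(root.rglob("*.png")):
        if "_mask" in image_path.stem:
            continue
        stem = image_path.stem
        masks = sorted(p for p in image_path.parent.glob(f"{stem}_mask*.png"))
        if masks:
            matched.append((image_path, masks))
        else:
            missing.append(image_path)
    return matched, missing


def _load_gray(path: Path) -> np.ndarray:
    with Image.open(path) as img:
        return np.asarray(img.convert("L"), dtype=np.float64) / 255.0


def load_image_mask_dir(
    root,
    size: int = 128,
    include_normal: bool = False,
    skip_report: list | None = None,
) -> list[ImageMaskPair]:
    """Load a BUSI-layout directory into resized, normalized pairs.

    Images without a mask are skipped (collected into ``skip_report`` when
    given, and warned about otherwise); the tumor-free "normal" class is
    excluded unless ``include_normal``.
    """
    matched, missing = find_pairs(root)
    if missing:
        if skip_report is not None:
            skip_report.extend(missing)
        else:
            warnings.warn(f"{len(missing)} image(s) without masks were skipped", stacklevel=2)
    pairs: list[ImageMaskPair] = []
    for image_path, mask_paths in matched:
        label = image_path.parent.name
        if label.lower() == "normal" and not include_normal:
            continue
        image = _load_gray(image_path)
        mask = np.zeros_like(image)
        for mask_path in mask_paths:
            mask = np.maximum(mask, _load_gray(mask_path))
        if image.shape != (size, size):
            image = resize(image, (size, size), order=1, anti_aliasing=True, preserve_range=True)
        if mask.shape != (size, size):
            mask = resize(mask, (size, size), order=0, anti_aliasing=False, preserve_range=True)
        mask = (mask >= 0.5).astype(np.float32)
        pair = ImageMaskPair(
            image=np.clip(image, 0.0, 1.0).astype(np.float32)[..., None],
            mask=mask[..., None],
            id=image_path.stem,
            class_label=label,
        )
        pair.validate()
        pairs.append(pair)
    return pairs


# ------------------------------------------------------------------ splitting
def split_dataset(pairs, fractions=(0.70, 0.10, 0.20), seed: int = 0):
    """Shuffled (train, val, test) split; rounding remainder goes to train."""
    pairs = list(pairs)
    n = len(pairs)
    if n < 3:
        raise ValueError("need at least 3 items to split")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {fractions}")
    order = np.random.default_rng(seed).permutation(n)
    n_val = int(np.floor(fractions[1] * n))
    n_test = int(np.floor(fractions[2] * n))
    n_train = n - n_val - n_test
    train = [pairs[i] for i in order[:n_train]]
    val = [pairs[i] for i in order[n_train : n_train + n_val]]
    test = [pairs[i] for i in order[n_train + n_val :]]
    return train, val, test


def kfold_split(pairs, k: int = 5, seed: int = 0):
    """k shuffled (train, test) folds; test folds partition the input."""
    pairs = list(pairs)
    n = len(pairs)
    if k < 2:
        raise ValueError("k must be >= 2")
    if n < k:
        raise ValueError(f"need at least k={k} items, got {n}")
    order = np.random.default_rng(seed).permutation(n)
    folds = []
    for chunk in np.array_split(order, k):
        test = [pairs[i] for i in chunk]
        test_set = set(chunk.tolist())
        train = [pairs[i] for i in order if i not in test_set]
        folds.append((train, test))
    return folds
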