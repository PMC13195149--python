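"""Dataset I/O, splitting, and the offline augmentation pipeline.

Annotations use the plain-text one-file-per-image format: each line is
``class cx cy w h`` with center/size normalised to image dimensions.  The
offline augmentation generates, per training image, a fixed number of
perturbed copies through rotation -> noise injection -> brightness
adjustment, alternating Gaussian and salt-and-pepper noise deterministically
so the two noise families appear in an exact 1:1 ratio.
"""
from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml
from PIL import Image
from scipy import ndimage


@dataclass(frozen=True)
class YoloLabel:
    class_id: int
    cx: float
    cy: float
    w: float
    h: float

    def __post_init__(self):
        for n in ("cx", "cy", "w", "h"):
            v = getattr(self, n)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{n}={v} outside [0,1]")
        if self.w * self.h <= 0:
            raise ValueError("box must have positive area")
        if self.class_id < 0:
            raise ValueError("class id must be non-negative")


@dataclass
class ImageSample:
    image: np.ndarray          # H x W x 3, uint8
    labels: list[YoloLabel]
    id: str

    def __post_init__(self):
        if self.image.ndim != 3 or self.image.shape[2] != 3 or self.image.size == 0:
            raise ValueError("image must be non-empty HxWx3")


@dataclass
class AugmentationConfig:
    rotation_range: tuple = (-15.0, 15.0)
    gaussian_sigma_range: tuple = (5.0, 15.0)
    sp_density_range: tuple = (0.002, 0.01)
    brightness_range: tuple = (0.7, 1.3)
    n_aug_per_image: int = 2
    seed: int = 0

    def __post_init__(self):
        if self.n_aug_per_image < 0:
            raise ValueError("n_aug_per_image must be >= 0")
        for r in (self.rotation_range, self.gaussian_sigma_range,
                  self.sp_density_range, self.brightness_range):
            if r[0] > r[1]:
                raise ValueError(f"interval {r} not ordered")


# ---------------------------------------------------------------------------
# Label I/O
# ---------------------------------------------------------------------------

def read_yolo_labels(path) -> list[YoloLabel]:
    labels = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 5:
                raise ValueError(f"{path}:{ln}: expected 5 fields, got {len(parts)}")
            try:
                cid = int(parts[0])
                vals = [float(p) for p in parts[1:]]
            except ValueError as e:
                raise ValueError(f"{path}:{ln}: non-numeric token") from e
            try:
                labels.append(YoloLabel(cid, *vals))
            except ValueError as e:
                raise ValueError(f"{path}:{ln}: {e}") from e
    return labels


def write_yolo_labels(labels: list[YoloLabel], path):
    with open(path, "w") as fh:
        for l in labels:
            fh.write(f"{l.class_id} {l.cx:.6f} {l.cy:.6f} {l.w:.6f} {l.h:.6f}\n")


def labels_to_xyxy(labels, width: int, height: int) -> list:
    """Normalised center/size labels -> pixel (x1,y1,x2,y2) boxes."""
    out = []
    for l in labels:
        out.append(((l.cx - l.w / 2) * width, (l.cy - l.h / 2) * height,
                    (l.cx + l.w / 2) * width, (l.cy + l.h / 2) * height))
    return out


def load_image_sample(img_path, label_path=None) -> ImageSample:
    img_path = Path(img_path)
    img = np.asarray(Image.open(img_path).convert("RGB"))
    if label_path is None:
        label_path = img_path.with_suffix(".txt")
    labels = read_yolo_labels(label_path) if os.path.exists(label_path) else []
    return ImageSample(image=img, labels=labels, id=img_path.stem)


def save_image_sample(sample: ImageSample, img_dir, label_dir):
    img_dir, label_dir = Path(img_dir), Path(label_dir)
    img_dir.mkdir(parents=True, exist_ok=True)
    label_dir.mkdir(parents=True, exist_ok=True)
    Image.fromarray(sample.image).save(img_dir / f"{sample.id}.png")
    write_yolo_labels(sample.labels, label_dir / f"{sample.id}.txt")


# ---------------------------------------------------------------------------
# Splitting
# ---------------------------------------------------------------------------

def split_dataset(samples, ratios=(0.7, 0.2, 0.1), seed: int = 0):
    """Random train/val/test partition.

    Subset sizes are round(n * ratio) for val and test, with the remainder
    (favouring training data) assigned to train.
    """
    if len(samples) == 0:
        raise ValueError("cannot split an empty dataset")
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError("ratios must sum to 1")
    n = len(samples)
    n_val, n_test = round(n * ratios[1]), round(n * ratios[2])
    n_train = n - n_val - n_test
    if min(n_train, n_val, n_test) < 0:
        raise ValueError("ratios produce a negative subset")
    idx = np.random.default_rng(seed).permutation(n)
    train = [samples[i] for i in idx[:n_train]]
    val = [samples[i] for i in idx[n_train:n_train + n_val]]
    test = [samples[i] for i in idx[n_train + n_val:]]
    return train, val, test


# ---------------------------------------------------------------------------
# Geometric / photometric transforms
# ---------------------------------------------------------------------------

def rotate_box_corners(label: YoloLabel, angle_deg: float, width: int, height: int):
    """Rotate a box's 4 corners about the image center; return the axis-
    aligned enclosing rectangle in pixels (unclipped)."""
    cx, cy = label.cx * width, label.cy * height
    w2, h2 = label.w * width / 2, label.h * height / 2
    corners = np.array([[cx - w2, cy - h2], [cx + w2, cy - h2],
                        [cx + w2, cy + h2], [cx - w2, cy + h2]])
    th = np.deg2rad(angle_deg)
    # image-coordinate rotation (y grows downward): rotating the image content
    # by +angle maps point p to R(p - c) + c with R = [[cos, sin], [-sin, cos]]
    R = np.array([[np.cos(th), np.sin(th)], [-np.sin(th), np.cos(th)]])
    c = np.array([(width - 1) / 2, (height - 1) / 2])
    rot = (corners - c) @ R.T + c
    return rot[:, 0].min(), rot[:, 1].min(), rot[:, 0].max(), rot[:, 1].max()


def rotate_with_boxes(sample: ImageSample, angle: float, min_area_frac: float = 0.2) -> ImageSample:
    """Rotate image about its center (same canvas, zero fill); boxes follow by
    corner rotation + axis-aligned hull, clipped; boxes whose clipped area
    falls below ``min_area_frac`` of the original are dropped."""
    if abs(angle) > 45:
        raise ValueError("|angle| must be <= 45 degrees")
    h, w = sample.image.shape[:2]
    if angle == 0:
        return ImageSample(sample.image.copy(), list(sample.labels), sample.id)
    img = ndimage.rotate(sample.image, angle, axes=(1, 0), reshape=False,
                         order=1, mode="constant", cval=0)
    img = np.clip(img, 0, 255).astype(np.uint8)
    new_labels = []
    for l in sample.labels:
        x1, y1, x2, y2 = rotate_box_corners(l, angle, w, h)
        area0 = (x2 - x1) * (y2 - y1)
        cx1, cy1 = max(x1, 0.0), max(y1, 0.0)
        cx2, cy2 = min(x2, float(w)), min(y2, float(h))
        if cx2 <= cx1 or cy2 <= cy1:
            continue
        if (cx2 - cx1) * (cy2 - cy1) < min_area_frac * area0:
            continue
        new_labels.append(YoloLabel(l.class_id, (cx1 + cx2) / 2 / w, (cy1 + cy2) / 2 / h,
                                    (cx2 - cx1) / w, (cy2 - cy1) / h))
    return ImageSample(img, new_labels, sample.id)


def add_gaussian_noise(image: np.ndarray, sigma: float, rng=None) -> np.ndarray:
    """Add i.i.d. normal(0, sigma^2) noise per pixel/channel (8-bit scale)."""
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    rng = rng or np.random.default_rng()
    noisy = image.astype(np.float32) + rng.normal(0, sigma, image.shape)
    return np.clip(noisy, 0, 255).astype(np.uint8)


def add_salt_pepper(image: np.ndarray, density: float, rng=None) -> np.ndarray:
    """Set a ``density`` fraction of pixels to 0 or 255 with equal probability."""
    if not 0 <= density <= 1:
        raise ValueError("density must lie in [0,1]")
    rng = rng or np.random.default_rng()
    out = image.copy()
    h, w = image.shape[:2]
    mask = rng.random((h, w)) < density
    salt = rng.random((h, w)) < 0.5
    out[mask & salt] = 255
    out[mask & ~salt] = 0
    return out


def adjust_brightness(image: np.ndarray, factor: float) -> np.ndarray:
    if factor < 0:
        raise ValueError("brightness factor must be non-negative")
    return np.clip(image.astype(np.float32) * factor, 0, 255).astype(np.uint8)


def augment_training_set(train: list[ImageSample], cfg: AugmentationConfig) -> list[ImageSample]:
    """Offline augmentation: originals + n_aug_per_image perturbed copies each.

    Each copy passes through rotation -> noise -> brightness with parameters
    drawn from the configured ranges; the noise family alternates between
    Gaussian and salt-and-pepper so the overall ratio is exactly 1:1 whenever
    the total number of generated copies is even.
    """
    rng = np.random.default_rng(cfg.seed)
    out = list(train)
    toggle = 0
    for s in train:
        for i in range(cfg.n_aug_per_image):
            angle = rng.uniform(*cfg.rotation_range)
            a = rotate_with_boxes(s, float(angle))
            if toggle % 2 == 0:
                sigma = rng.uniform(*cfg.gaussian_sigma_range)
                img = add_gaussian_noise(a.image, float(sigma), rng)
            else:
                dens = rng.uniform(*cfg.sp_density_range)
                img = add_salt_pepper(a.image, float(dens), rng)
            toggle += 1
            factor = rng.uniform(*cfg.brightness_range)
            img = adjust_brightness(img, float(factor))
            out.append(ImageSample(img, a.labels, f"{s.id}_aug{i + 1}"))
    return out


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------

def bbox_stats(labels: list[YoloLabel], small_area: float = 0.10) -> dict:
    """Distribution summary of normalised box widths/heights/areas."""
    if len(labels) == 0:
        raise ValueError("bbox_stats requires at least one label")
    w = np.array([l.w for l in labels])
    h = np.array([l.h for l in labels])
    a = w * h
    q = [0.05, 0.25, 0.5, 0.75, 0.95]
    return {
        "n": len(labels),
        "mean_w": float(w.mean()), "mean_h": float(h.mean()), "mean_area": float(a.mean()),
        "quantiles_w": {str(p): float(np.quantile(w, p)) for p in q},
        "quantiles_h": {str(p): float(np.quantile(h, p)) for p in q},
        "quantiles_area": {str(p): float(np.quantile(a, p)) for p in q},
        "small_box_fraction": float((a < small_area).mean()),
        "scatter": np.stack([w, h], axis=1),
    }


# ---------------------------------------------------------------------------
# Manifest I/O
# ---------------------------------------------------------------------------

def write_manifest(path, entries: dict):
    with open(path, "w") as fh:
        yaml.safe_dump(entries, fh, sort_keys=False)


def read_manifest(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
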