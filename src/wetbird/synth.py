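"""Synthetic wetland-like scene generator with exact box annotations.

Real wetland surveillance footage of small birds is hard to share and label;
this module emulates its difficulties — cluttered textured backgrounds (water
ripple, vegetation streaks, low sun gradients), dark elliptical targets that
each occupy well under 10% of the image area, variable target density,
partial occlusion by foreground streaks, and brightness variation — while
keeping the ground truth exact: every annotation is the tight bounding box of
the rendered target support, so the generator doubles as its own oracle.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .data import ImageSample, YoloLabel, save_image_sample, write_manifest

BACKGROUNDS = ("water_ripple", "vegetation", "sunset_gradient", "mixed")


@dataclass
class SceneConfig:
    image_size: int = 640
    n_birds_range: tuple = (3, 20)
    bird_area_fraction_range: tuple = (0.0004, 0.01)
    background: str = "mixed"
    occlusion_prob: float = 0.3
    contrast_delta_range: tuple = (25.0, 90.0)   # darkening of target vs background
    seed: int = 0

    def __post_init__(self):
        if self.background not in BACKGROUNDS:
            raise ValueError(f"background must be one of {BACKGROUNDS}")
        for r in (self.n_birds_range, self.bird_area_fraction_range, self.contrast_delta_range):
            if r[0] > r[1]:
                raise ValueError(f"interval {r} not ordered")
        if self.bird_area_fraction_range[1] > 0.10:
            raise ValueError("bird area fraction must stay below 10% of the image")
        if not 0 <= self.occlusion_prob <= 1:
            raise ValueError("occlusion_prob must lie in [0,1]")


class GenerationError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Backgrounds
# ---------------------------------------------------------------------------

def _smooth_noise(rng, size, sigma, amp):
    n = ndimage.gaussian_filter(rng.standard_normal((size, size)), sigma)
    sd = n.std() or 1.0
    return n / sd * amp


def _water_ripple(rng, size):
    base = rng.uniform(95, 150)
    yy, xx = np.mgrid[0:size, 0:size] / size
    img = np.full((size, size), base)
    for _ in range(rng.integers(2, 4)):
        f = rng.uniform(4, 18)
        th = rng.uniform(0, np.pi)
        amp = rng.uniform(6, 16)
        img += amp * np.sin(2 * np.pi * f * (np.cos(th) * xx + np.sin(th) * yy)
                            + rng.uniform(0, 2 * np.pi))
    img += _smooth_noise(rng, size, max(1.5, size / 80), rng.uniform(5, 10))
    img += rng.uniform(-20, 20) * (yy - 0.5)
    tint = np.array([0.88, 0.97, 1.06]) * rng.uniform(0.95, 1.05, 3)
    return img, tint


def _vegetation(rng, size):
    base = rng.uniform(80, 140)
    sig = (max(1.0, size / 160), max(4.0, size / 14))
    if rng.random() < 0.5:
        sig = sig[::-1]
    streaks = ndimage.gaussian_filter(rng.standard_normal((size, size)), sig)
    streaks = streaks / (streaks.std() or 1.0) * rng.uniform(14, 24)
    img = base + streaks + _smooth_noise(rng, size, 1.0, 6)
    tint = np.array([0.85, 1.05, 0.80]) * rng.uniform(0.95, 1.05, 3)
    return img, tint


def _sunset_gradient(rng, size):
    yy = np.mgrid[0:size, 0:size][0] / size
    top, bottom = rng.uniform(150, 210), rng.uniform(50, 110)
    img = top + (bottom - top) * yy + _smooth_noise(rng, size, 2.0, 5)
    tint = np.array([1.12, 0.95, 0.80]) * rng.uniform(0.95, 1.05, 3)
    return img, tint


def _background(rng, cfg: SceneConfig):
    kind = cfg.background
    if kind == "mixed":
        kind = BACKGROUNDS[rng.integers(0, 3)]
    gray, tint = {"water_ripple": _water_ripple, "vegetation": _vegetation,
                  "sunset_gradient": _sunset_gradient}[kind](rng, cfg.image_size)
    img = gray[..., None] * tint[None, None, :]
    return np.clip(img, 0, 255)


# ---------------------------------------------------------------------------
# Targets
# ---------------------------------------------------------------------------

def _ellipse_mask(h, w, cx, cy, a, b, phi):
    yy, xx = np.mgrid[0:h, 0:w]
    dx, dy = xx - cx, yy - cy
    u = dx * np.cos(phi) + dy * np.sin(phi)
    v = -dx * np.sin(phi) + dy * np.cos(phi)
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _bird_mask(size, cx, cy, a, b, phi):
    """Body ellipse plus a smaller head blob along the major axis."""
    body = _ellipse_mask(size, size, cx, cy, a, b, phi)
    hx = cx + 0.95 * a * np.cos(phi)
    hy = cy + 0.95 * a * np.sin(phi)
    r = max(1.0, 0.45 * b)
    head = _ellipse_mask(size, size, hx, hy, r, r, 0.0)
    return body | head


def generate_scene_with_meta(cfg: SceneConfig, rng=None, max_retries: int = 50):
    """Render one scene; returns (sample, per-target geometry metadata).

    Labels are the exact bounding boxes of the rendered target support.
    Placement rejects candidates whose center falls inside an already placed
    target's box (partial overlap remains possible); a scene too crowded for
    its size raises :class:`GenerationError` after bounded retries.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    S = cfg.image_size
    img = _background(rng, cfg)
    n_birds = int(rng.integers(cfg.n_birds_range[0], cfg.n_birds_range[1] + 1))
    labels = []
    meta = []
    boxes_px = []
    lo, hi = cfg.bird_area_fraction_range
    for _ in range(n_birds):
        placed = False
        for _attempt in range(max_retries):
            frac = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            area = frac * S * S
            q = rng.uniform(1.3, 2.8)
            a = float(np.sqrt(area * q / np.pi))
            b = a / q
            phi = rng.uniform(0, np.pi)
            ext = a + max(1.0, 0.45 * b) + 2
            if 2 * ext >= S:
                continue
            cx = rng.uniform(ext, S - ext)
            cy = rng.uniform(ext, S - ext)
            if any(x1 <= cx <= x2 and y1 <= cy <= y2 for x1, y1, x2, y2 in boxes_px):
                continue
            mask = _bird_mask(S, cx, cy, a, b, phi)
            if not mask.any():
                continue
            delta = rng.uniform(*cfg.contrast_delta_range)
            shade = rng.uniform(0.85, 1.15, 3)
            img[mask] = np.clip(img[mask] - delta * shade[None, :], 0, 255)
            if rng.random() < cfg.occlusion_prob:
                # vegetation streak drawn over the bird; label keeps full extent
                sl = rng.uniform(0.8, 1.6) * a
                sphi = rng.uniform(0, np.pi)
                streak = _ellipse_mask(S, S, cx + rng.uniform(-a / 2, a / 2),
                                       cy + rng.uniform(-b, b),
                                       sl, max(1.0, 0.25 * b), sphi)
                img[streak] = np.clip(img[streak] * 0.8 + np.array([20.0, 34.0, 16.0]), 0, 255)
            ys, xs = np.nonzero(mask)
            x1, x2 = xs.min(), xs.max() + 1
            y1, y2 = ys.min(), ys.max() + 1
            boxes_px.append((x1, y1, x2, y2))
            labels.append(YoloLabel(0, (x1 + x2) / 2 / S, (y1 + y2) / 2 / S,
                                    (x2 - x1) / S, (y2 - y1) / S))
            meta.append({"cx": cx, "cy": cy, "a": a, "b": b, "phi": phi})
            placed = True
            break
        if not placed:
            raise GenerationError("could not place a target within the retry budget")
    sid = f"scene_{rng.integers(0, 2**31):08x}"
    return ImageSample(np.clip(img, 0, 255).astype(np.uint8), labels, sid), meta


def generate_scene(cfg: SceneConfig, rng=None, max_retries: int = 50) -> ImageSample:
    """Render one scene; labels are exact boxes of the rendered support."""
    return generate_scene_with_meta(cfg, rng, max_retries)[0]


def scene_rng(seed: int, index: int):
    """Per-image random stream: any single scene is regenerable in isolation."""
    return np.random.default_rng([seed, index])


def generate_dataset(n_images: int, cfg: SceneConfig, out_dir) -> dict:
    """Write images + labels + a manifest; returns the manifest dict."""
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    out = Path(out_dir)
    try:
        (out / "images").mkdir(parents=True, exist_ok=True)
        (out / "labels").mkdir(parents=True, exist_ok=True)
    except OSError as e:
        raise IOError(f"cannot create output directory {out}: {e}") from e
    entries = []
    for i in range(n_images):
        s = generate_scene(cfg, scene_rng(cfg.seed, i))
        s.id = f"scene_{i:05d}"
        save_image_sample(s, out / "images", out / "labels")
        entries.append({"id": s.id, "image": f"images/{s.id}.png",
                        "label": f"labels/{s.id}.txt", "seed_index": i})
    manifest = {
        "image_size": cfg.image_size, "seed": cfg.seed, "n_images": n_images,
        "background": cfg.background, "class_names": ["bird"], "images": entries,
    }
    write_manifest(out / "manifest.yaml", manifest)
    return manifest


def generate_samples(n_images: int, cfg: SceneConfig) -> list[ImageSample]:
    """In-memory convenience wrapper around per-image seeded generation."""
    out = []
    for i in range(n_images):
        s = generate_scene(cfg, scene_rng(cfg.seed, i))
        s.id = f"scene_{i:05d}"
        out.append(s)
    return out
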