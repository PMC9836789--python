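"""Seeded synthetic dermoscopy image generator.

Emulates the features of dermoscopic lesion photographs that the rest of
the pipeline keys on, without any download: a skin-tone background with a
mild illumination gradient, a single elliptical lesion whose colour,
border irregularity and texture depend on the lesion class, and optional
thin dark hair strokes drawn as quadratic Bezier curves (the artifact the
hair-removal stage must detect and repair).

Every image is a pure function of (class, config, seed): the same inputs
give byte-identical pixels.  Ground truth (hair mask, hair-free image,
lesion bounding box) is returned alongside, so detection, inpainting and
localization can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.draw import disk as draw_disk
from skimage.draw import polygon as draw_polygon

from .constants import CLASS_INDEX, CLASS_NAMES

__all__ = [
    "ClassAppearance", "SynthConfig", "LabeledImage", "HairTruth",
    "generate_image", "generate_dataset", "scaled_counts", "default_palette",
]


@dataclass(frozen=True)
class ClassAppearance:
    """Visual signature of one lesion class.

    ``hue_range`` is in degrees on the HSV wheel; ``value_range`` and
    ``sat_range`` are HSV value/saturation in [0,1]; ``border_irregularity``
    scales the sinusoidal perturbation of the ellipse boundary;
    ``texture_amplitude`` scales the smooth value-noise mottling inside
    the lesion.
    """

    hue_range: tuple[float, float]
    sat_range: tuple[float, float]
    value_range: tuple[float, float]
    border_irregularity: float
    texture_amplitude: float

    def __post_init__(self):
        for lo, hi in (self.sat_range, self.value_range):
            if not (0 <= lo <= hi <= 1):
                raise ValueError("sat/value ranges must satisfy 0 <= lo <= hi <= 1")
        if not 0 <= self.border_irregularity <= 1:
            raise ValueError("border_irregularity must lie in [0,1]")
        if not 0 <= self.texture_amplitude <= 1:
            raise ValueError("texture_amplitude must lie in [0,1]")


def default_palette() -> dict[str, ClassAppearance]:
    """Distinct, dermatology-motivated appearance per class.

    Hue/value separations are deliberate: they are the signal a colour
    classifier (and the CNN) can learn, standing in for true pathology.
    """
    return {
        # actinic keratosis: pink-red, scaly (high texture)
        "Akiec": ClassAppearance((2, 14), (0.45, 0.6), (0.75, 0.9), 0.5, 0.6),
        # basal cell carcinoma: pearly pink, smooth
        "Bcc": ClassAppearance((340, 355), (0.25, 0.4), (0.8, 0.95), 0.4, 0.3),
        # benign keratosis: mid brown, waxy/verrucous (high texture)
        "Bkl": ClassAppearance((28, 40), (0.55, 0.7), (0.45, 0.6), 0.35, 0.7),
        # dermatofibroma: dusky grey-brown, small and regular
        "Df": ClassAppearance((18, 30), (0.3, 0.45), (0.3, 0.42), 0.2, 0.4),
        # melanoma: very dark brown-black, highly irregular border
        "Mel": ClassAppearance((20, 34), (0.6, 0.8), (0.08, 0.22), 0.85, 0.7),
        # melanocytic nevus: uniform tan-brown, regular border
        "Nv": ClassAppearance((22, 36), (0.5, 0.65), (0.55, 0.7), 0.15, 0.2),
        # vascular lesion: red-purple
        "Vasc": ClassAppearance((300, 330), (0.55, 0.75), (0.55, 0.75), 0.25, 0.3),
    }


@dataclass(frozen=True)
class SynthConfig:
    """Generator configuration; the defaults define the desk-scale study conditions."""

    image_size: int = 224
    class_palette: dict[str, ClassAppearance] = field(default_factory=default_palette)
    hair_probability: float = 0.5
    hair_count_range: tuple[int, int] = (2, 6)
    hair_width_range: tuple[int, int] = (1, 3)
    skin_tone_range: tuple[tuple[int, int, int], tuple[int, int, int]] = \
        ((185, 130, 105), (230, 185, 160))
    seed: int = 0

    def __post_init__(self):
        missing = set(CLASS_NAMES) - set(self.class_palette)
        if missing:
            raise ValueError(f"class_palette missing classes: {sorted(missing)}")
        if not 0 <= self.hair_probability <= 1:
            raise ValueError("hair_probability must lie in [0,1]")
        if self.hair_count_range[0] > self.hair_count_range[1] or self.hair_count_range[0] < 0:
            raise ValueError("invalid hair_count_range")
        if self.hair_width_range[0] < 1 or self.hair_width_range[0] > self.hair_width_range[1]:
            raise ValueError("invalid hair_width_range")
        if self.image_size < 8:
            raise ValueError("image_size too small")


@dataclass
class LabeledImage:
    """An RGB image with its lesion class and provenance."""

    pixels: np.ndarray  # (H, W, 3) uint8
    class_index: int
    class_name: str
    is_augmented: bool = False
    source_id: str = ""
    lesion_bbox: tuple[int, int, int, int] | None = None  # (r0, c0, r1, c1) inclusive

    def __post_init__(self):
        if self.class_name not in CLASS_INDEX:
            raise ValueError(f"unknown lesion class {self.class_name!r}")
        if CLASS_INDEX[self.class_name] != self.class_index:
            raise ValueError("class_index inconsistent with class_name")
        if self.pixels.dtype != np.uint8 or self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("pixels must be an (H,W,3) uint8 array")


@dataclass
class HairTruth:
    """Ground truth for hair removal: the exact stroke pixels and hair-free image."""

    mask: np.ndarray  # (H, W) bool, True on hair pixels
    stroke_count: int
    clean_image: np.ndarray | None = None  # the image before hair was drawn

    def __post_init__(self):
        if self.stroke_count < 0:
            raise ValueError("stroke_count must be non-negative")
        if (self.stroke_count == 0) != (not self.mask.any()):
            raise ValueError("mask must be empty exactly when stroke_count is 0")


def _hsv_to_rgb(h: float, s: float, v: float) -> np.ndarray:
    """Scalar HSV (h in degrees) to RGB in [0,1]."""
    h = (h % 360) / 60.0
    i = int(h) % 6
    f = h - int(h)
    p, q, t = v * (1 - s), v * (1 - s * f), v * (1 - s * (1 - f))
    rgb = [(v, t, p), (q, v, p), (p, v, t), (p, q, v), (t, p, v), (v, p, q)][i]
    return np.array(rgb)


def _smooth_noise(rng: np.random.Generator, size: int, scale: int) -> np.ndarray:
    """Value noise: coarse Gaussian grid bilinearly upsampled to size**2, in [-1,1]."""
    coarse = rng.normal(size=(scale, scale))
    # bilinear upsample by separable linear interpolation
    xi = np.linspace(0, scale - 1, size)
    i0 = np.floor(xi).astype(int)
    i1 = np.minimum(i0 + 1, scale - 1)
    frac = xi - i0
    rows = coarse[i0][:, i0] * np.outer(1 - frac, 1 - frac) \
        + coarse[i0][:, i1] * np.outer(1 - frac, frac) \
        + coarse[i1][:, i0] * np.outer(frac, 1 - frac) \
        + coarse[i1][:, i1] * np.outer(frac, frac)
    m = np.abs(rows).max() or 1.0
    return rows / m


def _lesion_mask(rng: np.random.Generator, size: int,
                 irregularity: float) -> tuple[np.ndarray, tuple[int, int, int, int]]:
    """Filled ellipse with sinusoidally perturbed boundary; returns mask and bbox."""
    cy = size / 2 + rng.uniform(-0.08, 0.08) * size
    cx = size / 2 + rng.uniform(-0.08, 0.08) * size
    ry = rng.uniform(0.20, 0.32) * size
    rx = rng.uniform(0.20, 0.32) * size
    tilt = rng.uniform(0, np.pi)
    theta = np.linspace(0, 2 * np.pi, 256, endpoint=False)
    wobble = np.zeros_like(theta)
    for k in (2, 3, 5, 7):
        wobble += rng.uniform(0.2, 1.0) * np.sin(k * theta + rng.uniform(0, 2 * np.pi))
    radius_mod = 1 + 0.22 * irregularity * wobble / np.abs(wobble).max()
    ey = ry * radius_mod * np.sin(theta)
    ex = rx * radius_mod * np.cos(theta)
    rr_b = cy + ey * np.cos(tilt) - ex * np.sin(tilt)
    cc_b = cx + ey * np.sin(tilt) + ex * np.cos(tilt)
    rr_b = np.clip(rr_b, 0, size - 1)
    cc_b = np.clip(cc_b, 0, size - 1)
    rr, cc = draw_polygon(rr_b, cc_b, shape=(size, size))
    mask = np.zeros((size, size), dtype=bool)
    mask[rr, cc] = True
    bbox = (int(rr.min()), int(cc.min()), int(rr.max()), int(cc.max()))
    return mask, bbox


def _draw_hairs(rng: np.random.Generator, img: np.ndarray,
                cfg: SynthConfig) -> tuple[np.ndarray, int]:
    """Draw dark Bezier hair strokes in place; returns (mask, stroke count)."""
    size = cfg.image_size
    mask = np.zeros((size, size), dtype=bool)
    count = 0
    if rng.uniform() < cfg.hair_probability:
        count = int(rng.integers(cfg.hair_count_range[0], cfg.hair_count_range[1] + 1))
    for _ in range(count):
        # endpoints near opposite borders; control point bends the curve
        p0 = rng.uniform(0, size, 2)
        p2 = rng.uniform(0, size, 2)
        while np.hypot(*(p2 - p0)) < 0.5 * size:
            p2 = rng.uniform(0, size, 2)
        p1 = (p0 + p2) / 2 + rng.uniform(-0.3, 0.3, 2) * size
        width = int(rng.integers(cfg.hair_width_range[0], cfg.hair_width_range[1] + 1))
        shade = rng.uniform(30, 80)
        t = np.linspace(0, 1, 3 * size)[:, None]
        pts = (1 - t) ** 2 * p0 + 2 * (1 - t) * t * p1 + t ** 2 * p2
        stroke = np.zeros((size, size), dtype=bool)
        radius = max(width / 2.0, 0.6)
        for y, x in pts:
            rr, cc = draw_disk((y, x), radius, shape=(size, size))
            stroke[rr, cc] = True
        tone = np.array([shade, shade * 0.85, shade * 0.7])
        img[stroke] = np.clip(tone, 0, 255).astype(np.uint8)
        mask |= stroke
    if count and not mask.any():
        count = 0  # all sampled strokes fell outside the frame
    return mask, count


def generate_image(cls: str, cfg: SynthConfig = SynthConfig(),
                   seed: int = 0) -> tuple[LabeledImage, HairTruth]:
    """Generate one labelled dermoscopy-like image plus its hair ground truth.

    Deterministic in (cls, cfg.seed, seed); unknown class names raise.
    """
    if cls not in CLASS_INDEX:
        raise ValueError(f"unknown lesion class {cls!r}; expected one of {CLASS_NAMES}")
    idx = CLASS_INDEX[cls]
    rng = np.random.default_rng([cfg.seed, idx, seed])
    size = cfg.image_size
    app = cfg.class_palette[cls]

    # --- skin background: sampled tone + soft illumination gradient + fine noise
    lo = np.array(cfg.skin_tone_range[0], dtype=float)
    hi = np.array(cfg.skin_tone_range[1], dtype=float)
    tone = lo + rng.uniform(size=3) * (hi - lo)
    yy, xx = np.mgrid[0:size, 0:size] / size
    grad_dir = rng.uniform(-1, 1, 2)
    gradient = (grad_dir[0] * (yy - 0.5) + grad_dir[1] * (xx - 0.5)) * 18.0
    img = tone[None, None, :] + gradient[..., None]
    img += rng.normal(0, 2.0, (size, size, 3))

    # --- lesion: perturbed ellipse, class colour, smooth mottled texture
    mask, bbox = _lesion_mask(rng, size, app.border_irregularity)
    hue = rng.uniform(*app.hue_range)
    sat = rng.uniform(*app.sat_range)
    val = rng.uniform(*app.value_range)
    base_rgb = _hsv_to_rgb(hue, sat, val) * 255.0
    texture = _smooth_noise(rng, size, scale=max(4, size // 20))
    shade = 1.0 + 0.18 * app.texture_amplitude * texture
    lesion = base_rgb[None, None, :] * shade[..., None]
    # soften the rim: blend over a 2-px feather ring using the mask's own edge
    img = np.where(mask[..., None], lesion, img)
    img = np.clip(img, 0, 255).astype(np.uint8)

    clean = img.copy()
    hair_mask, stroke_count = _draw_hairs(rng, img, cfg)

    labeled = LabeledImage(pixels=img, class_index=idx, class_name=cls,
                           is_augmented=False, source_id=f"{cls}_{seed:05d}",
                           lesion_bbox=bbox)
    truth = HairTruth(mask=hair_mask, stroke_count=stroke_count, clean_image=clean)
    return labeled, truth


def generate_dataset(counts: dict[str, int], cfg: SynthConfig = SynthConfig(),
                     out_dir=None) -> tuple[list[LabeledImage], pd.DataFrame]:
    """Generate ``counts[c]`` images per class; deterministic under ``cfg.seed``.

    Returns the images and a manifest with columns (path, class_name,
    class_index, split, is_augmented, seed).  When ``out_dir`` is given the
    images are written there as PNG and ``path`` points at the files.
    """
    for cls, n in counts.items():
        if cls not in CLASS_INDEX:
            raise ValueError(f"unknown lesion class {cls!r}")
        if n < 0:
            raise ValueError(f"negative count for class {cls}: {n}")
    images: list[LabeledImage] = []
    rows = []
    for cls in CLASS_NAMES:  # fixed class order keeps output deterministic
        for i in range(counts.get(cls, 0)):
            img, _ = generate_image(cls, cfg, seed=i)
            path = ""
            if out_dir is not None:
                from pathlib import Path

                from PIL import Image
                out = Path(out_dir)
                out.mkdir(parents=True, exist_ok=True)
                path = str(out / f"{img.source_id}.png")
                Image.fromarray(img.pixels).save(path)
            images.append(img)
            rows.append({"path": path or img.source_id, "class_name": cls,
                         "class_index": img.class_index, "split": "",
                         "is_augmented": False, "seed": i})
    manifest = pd.DataFrame(rows, columns=["path", "class_name", "class_index",
                                           "split", "is_augmented", "seed"])
    return images, manifest


def scaled_counts(totals: dict[str, int], factor: float) -> dict[str, int]:
    """Scale per-class counts by ``factor`` with round-half-up to integers."""
    return {cls: int(n * factor + 0.5) for cls, n in totals.items()}
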