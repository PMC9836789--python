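"""Dataset preprocessing: resize, hair removal, augmentation, split, balance.

Hair removal follows the classic dermoscopy pipeline: the image is
converted to luminance, a morphological black-hat transform (closing minus
image) highlights thin dark curvilinear structures, thresholding gives a
hair mask, and the masked pixels are repaired by inward propagation from
the mask boundary in distance order (fast-marching-style inpainting).

Augmentation applies, in fixed order, random rotation, shift, zoom, shear,
flips, then a resize — six operations, all seeded.  Balancing raises each
minority class to a target count by appending augmented copies round-robin
over the class's originals.  Splitting is stratified per class at a 7:2:1
ratio with largest-remainder rounding, with an optional per-class override
table for reproducing a published division verbatim.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.morphology import closing
from skimage.transform import AffineTransform, resize, warp

from .synth import LabeledImage

__all__ = [
    "HairRemovalConfig", "AugmentationConfig", "DegenerateMaskError",
    "resize_image", "detect_hair_mask", "inpaint_hair", "remove_hair",
    "augment_image", "split_dataset", "balance_training_set",
]


class DegenerateMaskError(ValueError):
    """Raised when an inpainting mask leaves no known pixels to propagate from."""


@dataclass(frozen=True)
class HairRemovalConfig:
    """Black-hat hair detection parameters.

    A 17 x 17 rectangular structuring element captures hairs thinner than
    ~8 px at 224 x 224 while leaving broad lesion structure alone; the
    threshold is on the 0-255 black-hat response.
    """

    element_shape: str = "rect"
    element_size: int = 17
    mask_threshold: float = 10.0
    inpaint_radius: int = 1

    def __post_init__(self):
        if self.element_shape not in ("rect", "square"):
            raise ValueError(f"unknown structuring element shape {self.element_shape!r}")
        if self.element_size < 3 or self.element_size % 2 == 0:
            raise ValueError("structuring element size must be odd and >= 3")
        if not 0 < self.mask_threshold < 255:
            raise ValueError("mask_threshold must lie in (0, 255)")
        if self.inpaint_radius < 1:
            raise ValueError("inpaint_radius must be >= 1")


@dataclass(frozen=True)
class AugmentationConfig:
    """Ranges of the six augmentation operations (all sampled uniformly)."""

    rotation_range: float = 180.0      # degrees, +/-
    shift_fraction: float = 0.1        # of image size, +/- both axes
    zoom_range: tuple[float, float] = (0.9, 1.1)
    shear_range: float = 10.0          # degrees, +/-
    flip_horizontal: float = 0.5       # probability
    flip_vertical: float = 0.5
    output_size: int = 224
    seed: int = 0

    def __post_init__(self):
        if self.zoom_range[0] <= 0 or self.zoom_range[0] > self.zoom_range[1]:
            raise ValueError("zoom_range must be a positive interval")
        for p in (self.flip_horizontal, self.flip_vertical):
            if not 0 <= p <= 1:
                raise ValueError("flip probabilities must lie in [0,1]")
        if self.shift_fraction < 0 or self.shift_fraction > 1:
            raise ValueError("shift_fraction must lie in [0,1]")
        if self.output_size < 1:
            raise ValueError("output_size must be positive")


def resize_image(img: np.ndarray, size: int) -> np.ndarray:
    """Bilinear resize of an (H,W,3) image to size x size x 3 (no padding)."""
    img = np.asarray(img)
    if img.size == 0:
        raise ValueError("cannot resize an empty image")
    if size < 1:
        raise ValueError("target size must be >= 1")
    if img.shape[:2] == (size, size):
        return img.copy()
    out = resize(img.astype(np.float64), (size, size, img.shape[2]) if img.ndim == 3
                 else (size, size), order=1, anti_aliasing=False, preserve_range=True)
    if np.issubdtype(np.asarray(img).dtype, np.integer):
        return np.clip(np.rint(out), 0, 255).astype(np.uint8)
    return out.astype(img.dtype)


def _luminance(img: np.ndarray) -> np.ndarray:
    """ITU-R 601 luma on the 0-255 scale."""
    rgb = img.astype(np.float64)
    return 0.299 * rgb[..., 0] + 0.587 * rgb[..., 1] + 0.114 * rgb[..., 2]


def detect_hair_mask(img: np.ndarray, cfg: HairRemovalConfig = HairRemovalConfig()) -> np.ndarray:
    """Black-hat hair mask: closing(luma) - luma thresholded at cfg.mask_threshold."""
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected an (H,W,3) RGB image")
    if cfg.element_size > min(img.shape[:2]):
        raise ValueError("structuring element larger than the image")
    gray = _luminance(img)
    footprint = np.ones((cfg.element_size, cfg.element_size), dtype=bool)
    blackhat = closing(gray, footprint) - gray
    return blackhat > cfg.mask_threshold


def inpaint_hair(img: np.ndarray, mask: np.ndarray, radius: int = 1) -> np.ndarray:
    """Fill masked pixels by inward propagation from the mask boundary.

    Unknown pixels are processed in increasing distance from the known
    region (the fast-marching front order) and each receives the
    inverse-distance weighted average of already-known pixels within a
    Chebyshev window of ``radius``+1.  Unmasked pixels are returned
    bit-identical.
    """
    img = np.asarray(img)
    mask = np.asarray(mask).astype(bool)
    if mask.shape != img.shape[:2]:
        raise ValueError(f"mask shape {mask.shape} does not match image {img.shape[:2]}")
    if radius < 1:
        raise ValueError("radius must be >= 1")
    if not mask.any():
        return img.copy()
    if mask.all():
        raise DegenerateMaskError("mask covers the whole image; nothing to propagate from")

    out = img.astype(np.float64).copy()
    known = ~mask
    dist = ndimage.distance_transform_edt(mask)
    order = np.argsort(dist[mask], kind="stable")
    ys, xs = np.nonzero(mask)
    ys, xs = ys[order], xs[order]
    h, w = mask.shape
    r = radius + 1
    offsets = [(dy, dx) for dy in range(-r, r + 1) for dx in range(-r, r + 1)
               if (dy, dx) != (0, 0)]
    weights = {o: 1.0 / np.hypot(*o) for o in offsets}
    for y, x in zip(ys, xs):
        acc = np.zeros(img.shape[2] if img.ndim == 3 else 1)
        wsum = 0.0
        for (dy, dx), wgt in weights.items():
            ny, nx = y + dy, x + dx
            if 0 <= ny < h and 0 <= nx < w and known[ny, nx]:
                acc = acc + wgt * out[ny, nx]
                wsum += wgt
        if wsum > 0:
            out[y, x] = acc / wsum
            known[y, x] = True
    if np.issubdtype(img.dtype, np.integer):
        return np.clip(np.rint(out), 0, 255).astype(img.dtype)
    return out.astype(img.dtype)


def remove_hair(img: np.ndarray, cfg: HairRemovalConfig = HairRemovalConfig()) -> np.ndarray:
    """Detect and inpaint hair in one call (the dehairing step of the pipeline)."""
    return inpaint_hair(img, detect_hair_mask(img, cfg), cfg.inpaint_radius)


def augment_image(img: LabeledImage, cfg: AugmentationConfig = AugmentationConfig(),
                  seed: int = 0) -> LabeledImage:
    """One random augmentation draw: rotate, shift, zoom, shear, flip, resize.

    The geometric transform is applied about the image centre with
    reflect padding; deterministic in (cfg.seed, seed); the label is
    preserved and the result is marked augmented.
    """
    rng = np.random.default_rng([cfg.seed, seed])
    angle = np.deg2rad(rng.uniform(-cfg.rotation_range, cfg.rotation_range))
    shift_y, shift_x = rng.uniform(-cfg.shift_fraction, cfg.shift_fraction, 2)
    zoom = rng.uniform(*cfg.zoom_range)
    shear = np.deg2rad(rng.uniform(-cfg.shear_range, cfg.shear_range))
    flip_h = rng.uniform() < cfg.flip_horizontal
    flip_v = rng.uniform() < cfg.flip_vertical

    pixels = img.pixels
    h, w = pixels.shape[:2]
    centre = np.array([w / 2 - 0.5, h / 2 - 0.5])
    core = AffineTransform(rotation=angle, shear=shear, scale=(zoom, zoom))
    tf = (AffineTransform(translation=-centre) + core
          + AffineTransform(translation=centre)
          + AffineTransform(translation=(shift_x * w, shift_y * h)))
    is_identity = np.allclose(tf.params, np.eye(3))
    if is_identity:
        warped = pixels.astype(np.float64)
    else:
        warped = warp(pixels.astype(np.float64), tf.inverse, order=1,
                      mode="reflect", preserve_range=True)
    if flip_h:
        warped = warped[:, ::-1]
    if flip_v:
        warped = warped[::-1, :]
    warped = np.clip(np.rint(warped), 0, 255).astype(np.uint8)
    out = resize_image(warped, cfg.output_size)
    return LabeledImage(pixels=out, class_index=img.class_index, class_name=img.class_name,
                        is_augmented=True, source_id=f"{img.source_id}#aug{seed}",
                        lesion_bbox=None)


def _largest_remainder(n: int, ratio: tuple[float, ...]) -> list[int]:
    total = sum(ratio)
    exact = [n * r / total for r in ratio]
    base = [int(np.floor(e)) for e in exact]
    rem = n - sum(base)
    order = np.argsort([b - e for b, e in zip(base, exact)], kind="stable")
    for i in range(rem):
        base[order[i]] += 1
    return base


def split_dataset(manifest: pd.DataFrame, ratio: tuple[float, float, float] = (7, 2, 1),
                  seed: int = 0,
                  per_class_counts: dict[str, tuple[int, int, int]] | None = None
                  ) -> pd.DataFrame:
    """Stratified train/test/val split (largest-remainder rounding per class).

    ``per_class_counts`` overrides the rounded counts class-by-class, for
    reproducing a published division whose rounding rule is unknown; the
    override must sum to the class size.  Rows are shuffled per class with
    a seeded generator, so the same seed reproduces the split exactly.
    """
    if any(r <= 0 for r in ratio):
        raise ValueError("split ratio entries must be positive")
    if len(manifest) == 0:
        raise ValueError("cannot stratify an empty manifest")
    present = set(manifest["class_name"].unique())
    if per_class_counts:
        absent = [c for c in per_class_counts if c not in present]
        if absent:
            raise ValueError(f"cannot stratify: no images for class(es) {absent}")
    out = manifest.copy()
    out["split"] = ""
    for cls, group in out.groupby("class_name", sort=False):
        n = len(group)
        if n == 0:
            continue
        if per_class_counts is not None and cls in per_class_counts:
            counts = list(per_class_counts[cls])
            if sum(counts) != n:
                raise ValueError(
                    f"override counts {counts} for class {cls} do not sum to {n}")
        else:
            counts = _largest_remainder(n, ratio)
        rng = np.random.default_rng([seed, hash(cls) % (2 ** 31)])
        perm = rng.permutation(n)
        idx = group.index.to_numpy()[perm]
        bounds = np.cumsum(counts)
        out.loc[idx[:bounds[0]], "split"] = "train"
        out.loc[idx[bounds[0]:bounds[1]], "split"] = "test"
        out.loc[idx[bounds[1]:bounds[2]], "split"] = "val"
    return out


def balance_training_set(manifest: pd.DataFrame,
                         targets: dict[str, int] | None = None,
                         aug_cfg: AugmentationConfig | None = None,
                         seed: int = 0,
                         images: dict[str, LabeledImage] | None = None
                         ) -> pd.DataFrame | tuple[pd.DataFrame, list[LabeledImage]]:
    """Raise each class's train count to its target by appending augmented rows.

    Originals are reused round-robin (most-used and least-used original
    differ by at most one augmentation).  By default every class is raised
    to the size of the largest class (the majority class is left
    unchanged).  Only the train split is touched.  When ``images`` maps
    path -> LabeledImage and ``aug_cfg`` is given, augmented images are
    materialised and returned alongside the manifest.
    """
    train = manifest[manifest["split"] == "train"]
    counts = train.groupby("class_name").size().to_dict()
    if targets is None:
        top = max(counts.values())
        targets = {cls: top for cls in counts}
    rows = []
    new_images: list[LabeledImage] = []
    aug_seed = seed
    for cls, target in targets.items():
        current = counts.get(cls, 0)
        if target < current:
            raise ValueError(f"target {target} for class {cls} below current count {current}")
        if current == 0 and target > 0:
            raise ValueError(f"cannot augment class {cls}: no originals in train split")
        need = target - current
        originals = train[train["class_name"] == cls].reset_index(drop=True)
        for k in range(need):
            src = originals.iloc[k % current]
            aug_seed += 1
            row = src.to_dict()
            row["path"] = f"{src['path']}#aug{aug_seed}"
            row["is_augmented"] = True
            row["seed"] = aug_seed
            rows.append(row)
            if images is not None and aug_cfg is not None:
                new_images.append(augment_image(images[src["path"]], aug_cfg, seed=aug_seed))
    balanced = pd.concat([manifest, pd.DataFrame(rows, columns=manifest.columns)],
                         ignore_index=True) if rows else manifest.copy()
    if images is not None and aug_cfg is not None:
        return balanced, new_images
    return balanced
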