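"""Stateless classification service: image in, thresholded decision out.

The flow mirrors a clinical upload service: read an RGB image, resize to
the model's 224 x 224 x 3 input, run the two-stream classifier, and apply
a confidence threshold (default 0.9) to the maximum softmax probability.
A prediction strictly below the threshold is returned with status
``reupload_requested`` instead of being presented as a diagnosis; at or
above the threshold it is ``accepted``.  The elapsed time covers the
forward pass only.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image, UnidentifiedImageError

from .constants import CLASS_NAMES, INPUT_SIZE, SERVICE_THRESHOLD
from .preprocess import resize_image

logger = logging.getLogger(__name__)

__all__ = ["ClassificationResult", "ImageFormatError", "classify", "batch_classify"]


class ImageFormatError(ValueError):
    """Raised for unreadable files or images that are not RGB."""


@dataclass
class ClassificationResult:
    status: str                      # "accepted" | "reupload_requested"
    class_name: str
    class_index: int
    probability: float
    elapsed_seconds: float
    probabilities: dict[str, float]
    threshold: float

    def __post_init__(self):
        if self.status not in ("accepted", "reupload_requested"):
            raise ValueError(f"invalid status {self.status!r}")
        total = sum(self.probabilities.values())
        if not np.isclose(total, 1.0, atol=1e-3):
            raise ValueError(f"class probabilities sum to {total}, expected ~1")

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2)


def _load_rgb(path) -> np.ndarray:
    try:
        with Image.open(path) as im:
            if im.mode != "RGB":
                raise ImageFormatError(
                    f"{path}: expected an RGB image, got mode {im.mode!r}")
            return np.asarray(im)
    except (UnidentifiedImageError, OSError) as exc:
        raise ImageFormatError(f"cannot read image {path}: {exc}") from exc


def _resolve_model(checkpoint):
    if hasattr(checkpoint, "predict_proba"):
        return checkpoint
    from .training import load_checkpoint
    return load_checkpoint(checkpoint)


def classify(image_path, checkpoint,
             threshold: float | dict[str, float] = SERVICE_THRESHOLD
             ) -> ClassificationResult:
    """Classify one image file with the thresholded decision rule.

    ``checkpoint`` may be a checkpoint path or an already-loaded model.
    Rejection is strict: status is ``reupload_requested`` iff the maximum
    probability is < threshold (a probability of exactly the threshold is
    accepted).  ``threshold`` may be a per-class mapping, e.g. a stricter
    bar for melanoma calls only; classes absent from the mapping fall back
    to the global default.
    """
    model = _resolve_model(checkpoint)
    pixels = _load_rgb(image_path)
    size = getattr(model, "input_size", INPUT_SIZE)
    pixels = resize_image(pixels, size)
    batch = pixels.astype(np.float32).transpose(2, 0, 1)[None] / 255.0
    t0 = time.perf_counter()
    probs = model.predict_proba(batch)[0]
    elapsed = time.perf_counter() - t0
    idx = int(np.argmax(probs))
    p = float(probs[idx])
    if isinstance(threshold, dict):
        bar = float(threshold.get(CLASS_NAMES[idx], SERVICE_THRESHOLD))
    else:
        bar = float(threshold)
    status = "accepted" if p >= bar else "reupload_requested"
    return ClassificationResult(
        status=status, class_name=CLASS_NAMES[idx], class_index=idx,
        probability=p, elapsed_seconds=elapsed,
        probabilities={c: float(v) for c, v in zip(CLASS_NAMES, probs)},
        threshold=bar)


def batch_classify(directory, checkpoint, truth: pd.DataFrame | None = None,
                   threshold: float = SERVICE_THRESHOLD) -> dict:
    """Classify every readable image in a directory; summarise against truth.

    ``truth`` is an optional manifest with columns path and class_name
    (and optionally group).  The summary reports per-group success rates
    and the most-confused lesion (off-diagonal argmax of the batch
    confusion tally) when truth is available; unreadable files are skipped
    with a logged warning.
    """
    directory = Path(directory)
    files = sorted(p for p in directory.iterdir()
                   if p.suffix.lower() in (".png", ".jpg", ".jpeg"))
    if not files:
        raise ValueError(f"no images found in {directory}")
    model = _resolve_model(checkpoint)
    truth_map = {}
    group_map = {}
    if truth is not None and len(truth):
        truth_map = dict(zip((Path(p).name for p in truth["path"]), truth["class_name"]))
        if "group" in truth.columns:
            group_map = dict(zip((Path(p).name for p in truth["path"]), truth["group"]))
    rows = []
    for f in files:
        try:
            res = classify(f, model, threshold)
        except ImageFormatError as exc:
            logger.warning("skipping %s: %s", f, exc)
            continue
        row = {"path": str(f), "predicted": res.class_name,
               "probability": res.probability, "status": res.status}
        if f.name in truth_map:
            row["actual"] = truth_map[f.name]
            row["correct"] = truth_map[f.name] == res.class_name
            row["group"] = group_map.get(f.name, 1)
        rows.append(row)
    results = pd.DataFrame(rows)
    summary: dict = {"results": results, "n_images": len(results)}
    if "correct" in results.columns and results["correct"].notna().any():
        scored = results.dropna(subset=["correct"])
        summary["success_rate"] = round(100.0 * scored["correct"].mean(), 2)
        per_group = scored.groupby("group").agg(
            correct=("correct", "sum"), wrong=("correct", lambda s: (~s).sum()))
        per_group["success_rate"] = (100.0 * per_group["correct"]
                                     / (per_group["correct"] + per_group["wrong"])).round(2)
        summary["per_group"] = per_group
        confusions = scored[~scored["correct"]]
        if len(confusions):
            tally = confusions.groupby(["actual", "predicted"]).size()
            summary["most_confused"] = tally.idxmax()[0]
        else:
            summary["most_confused"] = None
    return summary
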