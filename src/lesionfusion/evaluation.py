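"""Evaluation: confusion matrix, per-class / macro / micro metrics, ROC-AUC, Grad-CAM.

Per-class metrics are one-vs-rest on the percent scale:

    precision = TP / (TP + FP)      recall = TP / (TP + FN)
    F1 = 2 * precision * recall / (precision + recall)
    accuracy = (TP + TN) / (TP + TN + FP + FN)

Macro averages are unweighted means over classes; micro averages pool the
per-class counts (for single-label multiclass data micro-precision =
micro-recall = micro-F1 = overall accuracy).  Zero-denominator metrics are
reported as 0 and flagged rather than dropped, keeping macro averages
defined.  ROC curves and AUCs are one-vs-rest on softmax scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import auc as sk_auc
from sklearn.metrics import roc_curve

from .constants import CLASS_NAMES, NUM_CLASSES
from .nn import Tensor

__all__ = [
    "ConfusionMatrix", "ClassMetrics", "RocResult", "EvalReport",
    "confusion_matrix", "class_metrics", "f1_from_precision_recall",
    "roc_auc", "grad_cam", "report", "report_delta", "evaluate_predictions",
]


@dataclass
class ConfusionMatrix:
    """7x7 count grid; rows are actual classes, columns predicted classes."""

    counts: np.ndarray
    class_names: tuple[str, ...] = CLASS_NAMES

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.class_names)
        if self.counts.shape != (k, k):
            raise ValueError(f"expected a {k}x{k} grid, got {self.counts.shape}")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def supports(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def one_vs_rest(self, k: int) -> tuple[int, int, int, int]:
        """(TP, TN, FP, FN) for class k."""
        tp = int(self.counts[k, k])
        fp = int(self.counts[:, k].sum() - tp)
        fn = int(self.counts[k, :].sum() - tp)
        tn = self.total - tp - fp - fn
        return tp, tn, fp, fn


def confusion_matrix(y_true, y_pred, num_classes: int = NUM_CLASSES) -> ConfusionMatrix:
    """Tally counts[i][j] = #(actual i, predicted j)."""
    y_true = np.asarray(y_true, dtype=np.int64)
    y_pred = np.asarray(y_pred, dtype=np.int64)
    if y_true.shape != y_pred.shape:
        raise ValueError(f"length mismatch: {y_true.shape} vs {y_pred.shape}")
    if y_true.size and (y_true.min() < 0 or y_true.max() >= num_classes
                        or y_pred.min() < 0 or y_pred.max() >= num_classes):
        raise ValueError(f"labels must lie in 0..{num_classes - 1}")
    counts = np.zeros((num_classes, num_classes), dtype=np.int64)
    np.add.at(counts, (y_true, y_pred), 1)
    return ConfusionMatrix(counts, CLASS_NAMES[:num_classes])


def f1_from_precision_recall(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall (percent scale in, percent out)."""
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


@dataclass
class ClassMetrics:
    """Per-class table plus macro/micro aggregates, all on the percent scale."""

    per_class: pd.DataFrame  # columns precision, recall, f1, accuracy, support
    macro: dict[str, float]
    micro: dict[str, float]
    accuracy: float
    zero_division_flags: list[str] = field(default_factory=list)


def class_metrics(cm: ConfusionMatrix) -> ClassMetrics:
    """One-vs-rest metrics from a confusion matrix (percent scale)."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    rows, flags = [], []
    tp_sum = fp_sum = fn_sum = 0
    for k, name in enumerate(cm.class_names):
        tp, tn, fp, fn = cm.one_vs_rest(k)
        tp_sum, fp_sum, fn_sum = tp_sum + tp, fp_sum + fp, fn_sum + fn
        if tp + fp == 0:
            precision = 0.0
            flags.append(f"{name}: no predicted positives (precision set to 0)")
        else:
            precision = 100.0 * tp / (tp + fp)
        if tp + fn == 0:
            recall = 0.0
            flags.append(f"{name}: no actual positives (recall set to 0)")
        else:
            recall = 100.0 * tp / (tp + fn)
        rows.append({"class": name, "precision": precision, "recall": recall,
                     "f1": f1_from_precision_recall(precision, recall),
                     "accuracy": 100.0 * (tp + tn) / cm.total,
                     "support": tp + fn})
    per_class = pd.DataFrame(rows).set_index("class")
    macro = {m: float(per_class[m].mean()) for m in ("precision", "recall", "f1")}
    micro_p = 100.0 * tp_sum / (tp_sum + fp_sum) if tp_sum + fp_sum else 0.0
    micro_r = 100.0 * tp_sum / (tp_sum + fn_sum) if tp_sum + fn_sum else 0.0
    micro = {"precision": micro_p, "recall": micro_r,
             "f1": f1_from_precision_recall(micro_p, micro_r)}
    accuracy = 100.0 * np.trace(cm.counts) / cm.total
    return ClassMetrics(per_class, macro, micro, float(accuracy), flags)


@dataclass
class RocResult:
    """One-vs-rest ROC curves and AUCs plus micro/macro aggregates."""

    per_class: dict[str, tuple[np.ndarray, np.ndarray, float]]  # name -> (fpr, tpr, auc)
    micro: tuple[np.ndarray, np.ndarray, float]
    macro_auc: float
    skipped: list[str] = field(default_factory=list)


def roc_auc(y_true, scores) -> RocResult:
    """One-vs-rest ROC/AUC from per-class probability scores.

    ``scores`` is (N, K) with rows summing to ~1.  Classes absent from
    ``y_true`` have no defined AUC; they are excluded from the macro
    average with a warning.
    """
    y_true = np.asarray(y_true, dtype=np.int64)
    scores = np.asarray(scores, dtype=np.float64)
    if scores.ndim != 2 or scores.shape[0] != y_true.shape[0]:
        raise ValueError("scores must be (N, K) aligned with y_true")
    k = scores.shape[1]
    if not np.allclose(scores.sum(axis=1), 1.0, atol=1e-3):
        warnings.warn("score rows do not sum to 1; treating them as raw scores")
    per_class, aucs, skipped = {}, [], []
    onehot = np.zeros_like(scores)
    onehot[np.arange(len(y_true)), y_true] = 1.0
    for c in range(k):
        name = CLASS_NAMES[c] if c < len(CLASS_NAMES) else str(c)
        pos = onehot[:, c]
        if pos.sum() == 0 or pos.sum() == len(pos):
            skipped.append(name)
            warnings.warn(f"class {name} absent from y_true (or universal); AUC undefined")
            continue
        fpr, tpr, _ = roc_curve(pos, scores[:, c])
        a = float(sk_auc(fpr, tpr))
        per_class[name] = (fpr, tpr, a)
        aucs.append(a)
    fpr_mi, tpr_mi, _ = roc_curve(onehot.ravel(), scores.ravel())
    micro = (fpr_mi, tpr_mi, float(sk_auc(fpr_mi, tpr_mi)))
    macro = float(np.mean(aucs)) if aucs else float("nan")
    return RocResult(per_class, micro, macro, skipped)


def grad_cam(model, image: np.ndarray, target_class: int,
             layer: str = "fusion") -> np.ndarray:
    """Gradient-weighted class activation map, normalised to [0,1].

    ``image`` is (3,S,S) float in [0,1] (or (S,S,3) uint8, converted).
    The map is computed at the fused convolutional layer: channel weights
    are the spatial means of d score / d activation; the weighted sum is
    ReLU-rectified, bilinearly upsampled to the input size and max-normalised.
    """
    if layer != "fusion":
        raise ValueError(f"layer {layer!r} is not a convolutional feature map of this model")
    img = np.asarray(image)
    if img.ndim == 3 and img.shape[2] == 3 and img.dtype == np.uint8:
        img = img.astype(np.float32).transpose(2, 0, 1) / 255.0
    acts = Tensor(model.fusion_map(img[None].astype(np.float32)))
    acts.requires_grad = True  # leaf of a head-only graph
    logits = model.head_logits_from_fusion(acts)
    seed_grad = np.zeros_like(logits.data)
    seed_grad[0, target_class] = 1.0
    logits.backward(seed_grad)
    grads = acts.grad[0]          # (C, h, w)
    activ = acts.data[0]
    weights = grads.mean(axis=(1, 2))
    cam = np.maximum((weights[:, None, None] * activ).sum(axis=0), 0.0)
    from skimage.transform import resize as sk_resize
    size = img.shape[-1]
    cam = sk_resize(cam, (size, size), order=1, preserve_range=True,
                    anti_aliasing=False)
    peak = cam.max()
    return (cam / peak if peak > 0 else cam).astype(np.float64)


@dataclass
class EvalReport:
    """Bundled evaluation artefacts for one model on one dataset."""

    metrics: ClassMetrics
    cm: ConfusionMatrix
    roc: RocResult | None = None

    def summary(self) -> dict[str, float]:
        """Headline numbers, rounded to two decimals like published tables."""
        out = {
            "precision": round(self.metrics.macro["precision"], 2),
            "recall": round(self.metrics.macro["recall"], 2),
            "f1": round(self.metrics.macro["f1"], 2),
            "accuracy": round(self.metrics.accuracy, 2),
        }
        if self.roc is not None:
            out["micro_auc"] = round(self.roc.micro[2], 2)
            out["macro_auc"] = round(self.roc.macro_auc, 2)
        return out


def evaluate_predictions(y_true, y_pred, scores=None) -> EvalReport:
    """Full report from labels, hard predictions and optional probabilities."""
    cm = confusion_matrix(y_true, y_pred)
    metrics = class_metrics(cm)
    # micro identity check for single-label multiclass data
    assert abs(metrics.micro["precision"] - metrics.accuracy) < 1e-9
    roc = roc_auc(y_true, scores) if scores is not None else None
    return EvalReport(metrics, cm, roc)


def report(rep: EvalReport, out_dir=None, render_png: bool = False) -> dict[str, pd.DataFrame]:
    """Materialise a report as tables (and optionally CSV/PNG files)."""
    tables = {}
    per_class = rep.metrics.per_class.round(2)
    agg = pd.DataFrame([
        {"class": "macro", **{k: round(v, 2) for k, v in rep.metrics.macro.items()}},
        {"class": "micro", **{k: round(v, 2) for k, v in rep.metrics.micro.items()}},
    ]).set_index("class")
    tables["metrics"] = pd.concat([per_class, agg])
    tables["confusion"] = pd.DataFrame(rep.cm.counts, index=rep.cm.class_names,
                                       columns=rep.cm.class_names)
    if rep.roc is not None:
        rows = []
        for name, (fpr, tpr, a) in rep.roc.per_class.items():
            rows.extend({"class": name, "fpr": f, "tpr": t, "auc": a}
                        for f, t in zip(fpr, tpr))
        tables["roc_points"] = pd.DataFrame(rows)
    if out_dir is not None:
        from pathlib import Path
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in tables.items():
            df.to_csv(out / f"{name}.csv")
        if render_png:
            _render_png(rep, out)
    return tables


def _render_png(rep: EvalReport, out):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(rep.cm.counts, cmap="Blues")
    ax.set_xticks(range(len(rep.cm.class_names)), rep.cm.class_names, rotation=45)
    ax.set_yticks(range(len(rep.cm.class_names)), rep.cm.class_names)
    ax.set_xlabel("predicted label")
    ax.set_ylabel("actual label")
    fig.colorbar(im)
    fig.tight_layout()
    fig.savefig(out / "confusion.png", dpi=120)
    plt.close(fig)
    if rep.roc is not None:
        fig, ax = plt.subplots(figsize=(5, 4))
        for name, (fpr, tpr, a) in rep.roc.per_class.items():
            ax.plot(fpr, tpr, label=f"{name} (AUC {a:.2f})")
        ax.plot([0, 1], [0, 1], "k--", lw=0.5)
        ax.set_xlabel("false positive rate")
        ax.set_ylabel("true positive rate")
        ax.legend(fontsize=7)
        fig.tight_layout()
        fig.savefig(out / "roc.png", dpi=120)
        plt.close(fig)


def report_delta(a, b) -> dict[str, float]:
    """Headline metric differences a - b, rounded to two decimals.

    Used for ablation comparisons (the gain of an architectural variant
    over its baseline); accepts :class:`EvalReport` objects or plain
    summary dicts with precision/recall/f1/accuracy keys.
    """
    sa = a.summary() if isinstance(a, EvalReport) else a
    sb = b.summary() if isinstance(b, EvalReport) else b
    return {k: round(sa[k] - sb[k], 2) for k in sa if k in sb}
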