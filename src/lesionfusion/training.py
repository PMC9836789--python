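"""Training protocol: Adam + reduce-on-plateau, early stopping, best-weight restore.

The published protocol trains with batch size 16 at an initial learning
rate of 1e-4, multiplies the rate by 0.1 when the validation loss stops
improving, stops after five non-improving epochs, and caps training at 28
epochs.  All of that is configurable; the defaults are the protocol.

``run_ablation`` trains the architectural variants (plain VGG-16 stream,
residual VGG-16, DenseNet-121, two-stream; each with or without the
multireceptive-field block) and/or a grid of GeM exponents on the same
seeded data and tabulates precision/recall/F1/accuracy per variant.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import nn
from .backbones import DenseNet121Stream, ResidualVGG16Stream
from .constants import CLASS_NAMES, DEFAULT_GEM_P
from .evaluation import evaluate_predictions
from .fusion import GeMParams, TwoStreamClassifier
from .nn import Adam, Tensor, softmax_cross_entropy

__all__ = [
    "TrainConfig", "TrainLog", "DivergenceError", "train", "run_ablation",
    "build_variant", "save_checkpoint", "load_checkpoint", "images_to_batch",
]


class DivergenceError(RuntimeError):
    def __init__(self, epoch: int):
        super().__init__(f"loss became non-finite at epoch {epoch}")
        self.epoch = epoch


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 16
    initial_lr: float = 1e-4
    lr_decay_factor: float = 0.1
    lr_patience: int = 3
    early_stop_patience: int = 5
    max_epochs: int = 28
    seed: int = 0
    shuffle: bool = True
    stop_at_train_accuracy: float | None = None  # e.g. 1.0 for overfit smoke runs

    def __post_init__(self):
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if not 0 < self.lr_decay_factor < 1:
            raise ValueError("lr_decay_factor must lie in (0,1)")
        if self.lr_patience < 1 or self.early_stop_patience < 1:
            raise ValueError("patience values must be >= 1")
        if self.max_epochs < 0:
            raise ValueError("max_epochs must be >= 0")


@dataclass
class TrainLog:
    """Per-epoch record of the run plus the reason training stopped."""

    epochs: list[dict] = field(default_factory=list)
    stop_reason: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.epochs)

    @property
    def best_val_loss(self) -> float:
        if not self.epochs:
            return float("nan")
        return min(e["val_loss"] for e in self.epochs)


def images_to_batch(images) -> tuple[np.ndarray, np.ndarray]:
    """Stack LabeledImages into (X, y): float32 NCHW in [0,1] and int labels."""
    x = np.stack([im.pixels for im in images]).astype(np.float32) / 255.0
    x = x.transpose(0, 3, 1, 2)
    y = np.array([im.class_index for im in images], dtype=np.int64)
    return x, y


def _forward_dataset(model, x: np.ndarray, y: np.ndarray,
                     batch_size: int) -> tuple[float, float]:
    """Mean loss and accuracy over a dataset in eval mode."""
    model.eval()
    losses, correct = [], 0
    with nn.no_grad():
        for start in range(0, len(x), batch_size):
            xb = x[start:start + batch_size]
            yb = y[start:start + batch_size]
            logits = model(Tensor(xb))
            probs = nn.softmax(logits.data)
            losses.append(-np.log(probs[np.arange(len(yb)), yb] + 1e-12).sum())
            correct += int((logits.data.argmax(axis=1) == yb).sum())
    return float(np.sum(losses) / len(x)), correct / len(x)


def train(model, train_data, val_data, cfg: TrainConfig = TrainConfig()
          ) -> tuple[object, TrainLog]:
    """Train ``model``; returns (model with best-validation weights, log).

    ``train_data``/``val_data`` are (X, y) tuples of float32 NCHW images in
    [0,1] and integer class labels.  Fully deterministic under cfg.seed.
    """
    x_tr, y_tr = train_data
    x_va, y_va = val_data
    if len(x_tr) == 0 or len(x_va) == 0:
        raise ValueError("training and validation sets must be non-empty")
    n_classes = getattr(model, "num_classes", len(CLASS_NAMES))
    for arr in (y_tr, y_va):
        if len(arr) and (np.min(arr) < 0 or np.max(arr) >= n_classes):
            raise ValueError(f"class indices must lie in 0..{n_classes - 1}")

    log = TrainLog()
    if cfg.max_epochs == 0:
        log.stop_reason = "max_epochs reached"
        return model, log

    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.parameters(), lr=cfg.initial_lr)
    best_val = np.inf
    best_state = model.state_dict()
    since_best = 0
    since_lr_drop = 0
    lr = cfg.initial_lr

    for epoch in range(cfg.max_epochs):
        model.train()
        order = rng.permutation(len(x_tr)) if cfg.shuffle else np.arange(len(x_tr))
        epoch_loss, correct = 0.0, 0
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            logits = model(Tensor(x_tr[idx]))
            loss = softmax_cross_entropy(logits, y_tr[idx])
            if not np.isfinite(loss.data):
                raise DivergenceError(epoch)
            loss.backward()
            opt.step()
            opt.zero_grad()
            epoch_loss += float(loss.data) * len(idx)
            correct += int((logits.data.argmax(axis=1) == y_tr[idx]).sum())
            del logits, loss
        train_loss = epoch_loss / len(x_tr)
        train_acc = correct / len(x_tr)
        val_loss, val_acc = _forward_dataset(model, x_va, y_va, cfg.batch_size)
        log.epochs.append({"epoch": epoch, "train_loss": train_loss,
                           "train_acc": train_acc, "val_loss": val_loss,
                           "val_acc": val_acc, "lr": lr})

        if val_loss < best_val - 1e-9:
            best_val = val_loss
            best_state = model.state_dict()
            since_best = 0
            since_lr_drop = 0
        else:
            since_best += 1
            since_lr_drop += 1

        if cfg.stop_at_train_accuracy is not None and \
                train_acc >= cfg.stop_at_train_accuracy:
            log.stop_reason = "train accuracy target reached"
            break
        if since_best >= cfg.early_stop_patience:
            log.stop_reason = f"early stop: no improvement for {since_best} epochs"
            break
        if since_lr_drop >= cfg.lr_patience:
            lr *= cfg.lr_decay_factor
            opt.lr = lr
            since_lr_drop = 0
    else:
        log.stop_reason = "max_epochs reached"

    if cfg.stop_at_train_accuracy is None:
        model.load_state_dict(best_state)  # best-validation weights
    return model, log


# ---------------------------------------------------------------------------
# variants and ablation
# ---------------------------------------------------------------------------

_VARIANTS = ("vgg16", "improved_vgg16", "densenet121", "two_stream")


def build_variant(name: str, gem_p: float = DEFAULT_GEM_P, use_mrf: bool | None = None,
                  input_size: int = 224, seed: int = 0,
                  densenet_kwargs: dict | None = None,
                  vgg_kwargs: dict | None = None,
                  head_kwargs: dict | None = None) -> TwoStreamClassifier:
    """Build an architectural variant by name.

    ``vgg16`` is the plain (non-residual) VGG stream, ``improved_vgg16``
    the residual one; ``two_stream`` combines DenseNet-121 and the
    residual VGG.  ``use_mrf=False`` gives the "(-)" variants without the
    multireceptive-field block.  The kwargs dicts let tests build reduced
    desk-scale versions; defaults are the published architecture.
    """
    if name not in _VARIANTS:
        raise ValueError(f"unknown variant {name!r}; expected one of {_VARIANTS}")
    densenet_kwargs = dict(densenet_kwargs or {})
    vgg_kwargs = dict(vgg_kwargs or {})
    head_kwargs = dict(head_kwargs or {})
    if use_mrf is None:
        use_mrf = True
    streams = []
    if name in ("densenet121", "two_stream"):
        streams.append(DenseNet121Stream(input_size=input_size, seed=seed,
                                         **densenet_kwargs))
    if name in ("vgg16", "improved_vgg16", "two_stream"):
        use_residual = name != "vgg16"
        streams.append(ResidualVGG16Stream(input_size=input_size, seed=seed + 1,
                                           use_residual=use_residual, **vgg_kwargs))
    return TwoStreamClassifier(streams, gem=GeMParams(p=gem_p), use_mrf=use_mrf,
                               seed=seed + 2, **head_kwargs)


def run_ablation(grid, data, cfg: TrainConfig = TrainConfig(),
                 input_size: int = 224, build_kwargs: dict | None = None) -> pd.DataFrame:
    """Train every grid entry on the same seeded data; tabulate the metrics.

    ``grid`` is an iterable of dicts with keys among {"variant", "gem_p",
    "use_mrf"}; ``data`` is ((X_train, y_train), (X_val, y_val)).  Each row
    of the result carries the variant spec plus precision/recall/F1/accuracy
    (percent, macro-averaged) measured on the validation split.
    """
    grid = list(grid)
    if not grid:
        raise ValueError("ablation grid is empty")
    build_kwargs = dict(build_kwargs or {})
    train_data, val_data = data
    rows = []
    for entry in grid:
        variant = entry.get("variant", "two_stream")
        gem_p = entry.get("gem_p", DEFAULT_GEM_P)
        use_mrf = entry.get("use_mrf", True)
        model = build_variant(variant, gem_p=gem_p, use_mrf=use_mrf,
                              input_size=input_size, seed=cfg.seed, **build_kwargs)
        model, _ = train(model, train_data, val_data, cfg)
        probs = model.predict_proba(val_data[0])
        rep = evaluate_predictions(val_data[1], probs.argmax(axis=1), probs)
        rows.append({"variant": variant, "gem_p": gem_p, "use_mrf": use_mrf,
                     **rep.summary()})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(model, path, builder: dict | None = None):
    """Write weights plus the builder spec needed to reconstruct the model."""
    state = model.state_dict()
    meta = {"class_names": list(CLASS_NAMES),
            "builder": builder or {"name": "two_stream"}}
    np.savez_compressed(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **state)


def load_checkpoint(path):
    """Rebuild the model recorded in a checkpoint and load its weights."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        archive = np.load(path, allow_pickle=False)
        meta = json.loads(bytes(archive["__meta__"]).decode())
    except Exception as exc:  # corrupt archive or metadata
        raise ValueError(f"corrupt checkpoint {path}: {exc}") from exc
    builder = dict(meta["builder"])
    name = builder.pop("name", "two_stream")
    model = build_variant(name, **builder)
    state = {k: archive[k] for k in archive.files if k != "__meta__"}
    model.load_state_dict(state)
    return model
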