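"""Feature-fusion head: spatial pooling, multireceptive field, classifier.

The head concatenates the two 7 x 7 x 768 stream outputs into a
7 x 7 x 1536 map, passes it through three parallel same-padded
convolutions (3 x 3, 5 x 5, 7 x 7) whose outputs are concatenated and
integrated by a 1 x 1 convolution + ReLU, reduces the spatial extent with
generalized-mean (GeM) pooling into a length-1536 vector, and classifies
with a dense softmax layer.

GeM pooling is the per-channel power mean

    H_k = ( (1/|X_k|) * sum_{x in X_k} x**p )**(1/p)

over the spatial activation set ``X_k`` of channel k.  ``p = 1`` is average
pooling; ``p -> infinity`` approaches max pooling, so a single exponent
interpolates between the two.  The default ``p = 4`` is the value selected
by the study's hyperparameter sweep.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .constants import DEFAULT_GEM_P, NUM_CLASSES
from .nn import Tensor

__all__ = [
    "GeMParams", "PooledVector", "pool_max", "pool_avg", "pool_gem",
    "MultiReceptiveField", "GeMPool2d", "TwoStreamClassifier", "assemble_model",
]


@dataclass(frozen=True)
class GeMParams:
    """GeM pooling exponent and numerical guard.

    ``p`` is shared across channels; ``eps`` is added to the activations
    before exponentiation to keep gradients finite at exact zeros.
    """

    p: float = DEFAULT_GEM_P
    eps: float = 1e-6

    def __post_init__(self):
        if self.p < 1:
            raise ValueError(f"GeM exponent must satisfy p >= 1, got {self.p}")
        if self.eps <= 0:
            raise ValueError(f"eps must be positive, got {self.eps}")


@dataclass(frozen=True)
class PooledVector:
    """A per-channel pooled feature vector and the pooling variant that made it."""

    values: np.ndarray
    variant: str  # "max", "average" or "gem"

    def __post_init__(self):
        if self.variant not in ("max", "average", "gem"):
            raise ValueError(f"unknown pooling variant {self.variant!r}")


def _spatial_first(feature_map: np.ndarray) -> np.ndarray:
    """Normalise a channel-last feature map to (batch, H*W, K)."""
    fm = np.asarray(feature_map, dtype=np.float64)
    if fm.ndim == 3:
        fm = fm[None]
    if fm.ndim != 4:
        raise ValueError(f"feature map must be (H,W,K) or (N,H,W,K), got shape {fm.shape}")
    n, h, w, k = fm.shape
    if h == 0 or w == 0 or k == 0:
        raise ValueError("feature map has an empty extent")
    return fm.reshape(n, h * w, k)


def _maybe_squeeze(values: np.ndarray, feature_map: np.ndarray) -> np.ndarray:
    return values[0] if np.asarray(feature_map).ndim == 3 else values


def pool_max(feature_map: np.ndarray) -> PooledVector:
    """Per-channel maximum over spatial positions (channel-last layout)."""
    flat = _spatial_first(feature_map)
    return PooledVector(_maybe_squeeze(flat.max(axis=1), feature_map), "max")


def pool_avg(feature_map: np.ndarray) -> PooledVector:
    """Per-channel arithmetic mean over spatial positions."""
    flat = _spatial_first(feature_map)
    return PooledVector(_maybe_squeeze(flat.mean(axis=1), feature_map), "average")


def pool_gem(feature_map: np.ndarray, params: GeMParams = GeMParams()) -> PooledVector:
    """Per-channel generalized-mean (power-mean) pooling.

    Activations must be non-negative (the head applies it after a ReLU);
    negative inputs violate that contract and raise.
    """
    flat = _spatial_first(feature_map)
    if np.any(flat < 0):
        raise ValueError("GeM pooling requires non-negative activations (post-ReLU contract)")
    powered = (flat + params.eps) ** params.p
    values = powered.mean(axis=1) ** (1.0 / params.p)
    return PooledVector(_maybe_squeeze(values, feature_map), "gem")


class MultiReceptiveField(nn.Module):
    """Parallel 3x3 / 5x5 / 7x7 same-padded convolutions + 1x1 integration.

    Input and output channel counts are equal by default (1536 for the
    two-stream concatenation); each branch emits ``branch_channels`` maps
    and the concatenated branches are mixed by a 1 x 1 conv + ReLU.
    Spatial extent is preserved.  Maps smaller than the largest kernel are
    rejected unless ``allow_small`` is set (same-padding would still be
    well-defined, but a 7 x 7 kernel on a smaller map no longer spans
    distinct receptive fields).
    """

    def __init__(self, in_channels: int = 1536, branch_channels: int = 512,
                 out_channels: int | None = None,
                 kernels: tuple[int, ...] = (3, 5, 7),
                 allow_small: bool = False, seed: int = 2):
        super().__init__()
        rng = np.random.default_rng(seed)
        out_channels = in_channels if out_channels is None else out_channels
        self.in_channels, self.out_channels = in_channels, out_channels
        self.kernels = tuple(kernels)
        self.allow_small = allow_small
        branches = [nn.Conv2d(in_channels, branch_channels, k, padding=k // 2, rng=rng)
                    for k in self.kernels]
        self.branches = nn.Sequential(*branches)  # container only; applied in parallel
        self.integrate = nn.Conv2d(branch_channels * len(self.kernels), out_channels, 1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        n, c, h, w = x.data.shape
        if c != self.in_channels:
            raise ValueError(f"expected {self.in_channels} channels, got {c}")
        if not self.allow_small and min(h, w) < max(self.kernels):
            raise ValueError(
                f"spatial extent {h}x{w} smaller than the largest kernel {max(self.kernels)}")
        outs = [branch(x) for branch in self.branches]
        return nn.relu(self.integrate(nn.concat(outs, axis=1)))


class GeMPool2d(nn.Module):
    """Autograd GeM pooling layer: (N,C,H,W) -> (N,C)."""

    def __init__(self, params: GeMParams = GeMParams()):
        super().__init__()
        self.params = params

    def forward(self, x: Tensor) -> Tensor:
        return nn.gem_pool2d(x, self.params.p, self.params.eps)


class TwoStreamClassifier(nn.Module):
    """Streams -> concat -> multireceptive field -> GeM -> dense softmax head.

    ``streams`` may hold one stream (single-network ablations) or two.
    ``capture_fusion`` makes the forward pass keep the fused convolutional
    activation tensor on ``self.fusion_activations`` for Grad-CAM.
    """

    def __init__(self, streams, gem: GeMParams = GeMParams(), use_mrf: bool = True,
                 branch_channels: int = 512, mrf_kernels: tuple[int, ...] = (3, 5, 7),
                 num_classes: int = NUM_CLASSES, allow_small: bool = False, seed: int = 3):
        super().__init__()
        streams = list(streams)
        if not streams:
            raise ValueError("at least one stream is required")
        spatial = {s.output_spatial for s in streams}
        if len(spatial) != 1:
            raise ValueError(f"streams emit mismatched spatial sizes: {sorted(spatial)}")
        self.streams = nn.Sequential(*streams)  # container; applied in parallel
        self.fused_channels = sum(s.output_channels for s in streams)
        self.use_mrf = use_mrf
        if use_mrf:
            self.mrf = MultiReceptiveField(self.fused_channels, branch_channels,
                                           kernels=mrf_kernels, allow_small=allow_small,
                                           seed=seed)
        self.gem = GeMPool2d(gem)
        # small classifier init keeps initial logits near zero (loss ~ ln C)
        self.head = nn.Linear(self.fused_channels, num_classes,
                              rng=np.random.default_rng(seed + 1), init_std=0.01)
        self.num_classes = num_classes
        self.input_size = streams[0].input_size
        self.capture_fusion = False
        self.fusion_activations: Tensor | None = None

    def forward(self, x: Tensor) -> Tensor:
        feats = [s(x) for s in self.streams]
        fused = feats[0] if len(feats) == 1 else nn.concat(feats, axis=1)
        if self.use_mrf:
            fused = self.mrf(fused)
        if self.capture_fusion:
            fused.retain_grad()
            self.fusion_activations = fused
        pooled = self.gem(fused)
        return self.head(pooled)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Softmax class probabilities for a (N,3,S,S) float batch (eval mode)."""
        self.eval()
        with nn.no_grad():
            logits = self.forward(Tensor(x))
        return nn.softmax(logits.data)

    def fusion_map(self, x: np.ndarray) -> np.ndarray:
        """Fused convolutional activations in eval mode, without a graph."""
        self.eval()
        with nn.no_grad():
            feats = [s(Tensor(x)) for s in self.streams]
            fused = feats[0] if len(feats) == 1 else nn.concat(feats, axis=1)
            if self.use_mrf:
                fused = self.mrf(fused)
        return fused.data

    def head_logits_from_fusion(self, fused: Tensor) -> Tensor:
        """Apply GeM pooling + dense head to a fused activation tensor.

        Lets class-activation mapping differentiate the score w.r.t. the
        fused layer without back-propagating through the streams.
        """
        return self.head(self.gem(fused))


def assemble_model(streams, gem: GeMParams = GeMParams(), use_mrf: bool = True,
                   **kwargs) -> TwoStreamClassifier:
    """Assemble the classifier from built streams.

    Raises if the streams disagree on spatial extent, since concatenation
    along channels requires spatially aligned maps.
    """
    return TwoStreamClassifier(streams, gem=gem, use_mrf=use_mrf, **kwargs)
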