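"""The two feature streams: DenseNet-121 and a residual-augmented VGG-16.

Both streams take a 224 x 224 x 3 input and emit a spatially aligned
7 x 7 x 768 feature map with no fully-connected head, so that the fusion
module can concatenate them into a 7 x 7 x 1536 map.

DenseNet-121 follows the canonical 6/12/24/16 bottleneck layout with
growth rate 32 and 0.5 transition compression; because that trunk ends at
1024 channels, a 1 x 1 projection (+ReLU) brings it to the 768-channel
interface shared with the VGG stream.

The VGG stream keeps the five-block 3x3-conv layout (2,2,3,3,3 convs) but
widens the final block to 768 channels and wraps every block in a residual
skip: an identity path when channel counts match, otherwise a 1 x 1
projection, merged by elementwise addition followed by ReLU, then 2 x 2
max pooling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn import Tensor
from .nn.layers import count_parameters  # re-exported surface

__all__ = [
    "StreamSpec", "DenseNet121Stream", "ResidualVGG16Stream",
    "build_densenet121_stream", "build_residual_vgg16_stream",
    "count_parameters", "stream_summary",
]


@dataclass
class StreamSpec:
    """Stage table of a stream: (stage name, operator, output H x W x C)."""

    stages: list[tuple[str, str, tuple[int, int, int]]] = field(default_factory=list)
    output_channels: int = 768

    def add(self, name: str, operator: str, h: int, w: int, c: int):
        self.stages.append((name, operator, (h, w, c)))

    def assert_consistent(self):
        if not self.stages:
            raise ValueError("empty stream spec")
        h, w, c = self.stages[-1][2]
        if c != self.output_channels:
            raise ValueError(f"final stage channels {c} != declared output {self.output_channels}")


class _DenseLayer(nn.Module):
    """BN-ReLU-1x1(4g) -> BN-ReLU-3x3(g); output concatenated onto the input."""

    def __init__(self, in_channels: int, growth: int, rng):
        super().__init__()
        bottleneck = 4 * growth
        self.bn1 = nn.BatchNorm2d(in_channels)
        self.conv1 = nn.Conv2d(in_channels, bottleneck, 1, bias=False, rng=rng)
        self.bn2 = nn.BatchNorm2d(bottleneck)
        self.conv2 = nn.Conv2d(bottleneck, growth, 3, padding=1, bias=False, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        y = self.conv1(nn.relu(self.bn1(x)))
        y = self.conv2(nn.relu(self.bn2(y)))
        return nn.concat([x, y], axis=1)


class _DenseBlock(nn.Module):
    def __init__(self, in_channels: int, n_layers: int, growth: int, rng):
        super().__init__()
        self.out_channels = in_channels + n_layers * growth
        layers = [_DenseLayer(in_channels + i * growth, growth, rng) for i in range(n_layers)]
        self.layers = nn.Sequential(*layers)

    def forward(self, x: Tensor) -> Tensor:
        return self.layers(x)


class _Transition(nn.Module):
    """BN-ReLU-1x1 compression followed by 2x2 average pooling."""

    def __init__(self, in_channels: int, out_channels: int, rng):
        super().__init__()
        self.bn = nn.BatchNorm2d(in_channels)
        self.conv = nn.Conv2d(in_channels, out_channels, 1, bias=False, rng=rng)
        self.pool = nn.AvgPool2d(2)

    def forward(self, x: Tensor) -> Tensor:
        return self.pool(self.conv(nn.relu(self.bn(x))))


class DenseNet121Stream(nn.Module):
    """Densely connected stream; ``forward`` maps (N,3,S,S) -> (N,768,S/32,S/32).

    Parameters other than the defaults exist only to build reduced desk-scale
    models for tests; the defaults are the published configuration.
    """

    def __init__(self, input_size: int = 224, growth: int = 32,
                 block_layers: tuple[int, ...] = (6, 12, 24, 16),
                 stem_channels: int = 64, compression: float = 0.5,
                 output_channels: int = 768, seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.input_size = input_size
        self.output_channels = output_channels
        self.spec = StreamSpec(output_channels=output_channels)

        s = input_size
        self.stem_conv = nn.Conv2d(3, stem_channels, 7, stride=2, padding=3, bias=False, rng=rng)
        self.stem_bn = nn.BatchNorm2d(stem_channels)
        self.stem_pool = nn.MaxPool2d(3, stride=2, padding=1)
        s2 = (s + 1) // 2
        s4 = (s2 + 1) // 2
        self.spec.add("Convolution", "7 x 7 conv, stride 2", s2, s2, stem_channels)
        self.spec.add("Pooling", "3 x 3 max pool, stride 2", s4, s4, stem_channels)

        c, sz = stem_channels, s4
        blocks: list[nn.Module] = []
        for bi, n_layers in enumerate(block_layers, start=1):
            block = _DenseBlock(c, n_layers, growth, rng)
            blocks.append(block)
            c = block.out_channels
            self.spec.add(f"Dense block ({bi})",
                          f"(1 x 1 conv) x {n_layers}, (3 x 3 conv) x {n_layers}", sz, sz, c)
            if bi < len(block_layers):
                c_out = int(c * compression)
                blocks.append(_Transition(c, c_out, rng))
                self.spec.add(f"Transition layer ({bi})", "1 x 1 conv", sz, sz, c_out)
                sz //= 2
                self.spec.add(f"Transition layer ({bi})", "2 x 2 average pool, stride 2",
                              sz, sz, c_out)
                c = c_out
        self.blocks = nn.Sequential(*blocks)
        self.final_bn = nn.BatchNorm2d(c)
        self.project = nn.Conv2d(c, output_channels, 1, rng=rng)
        self.spec.add("Projection", "1 x 1 conv + ReLU", sz, sz, output_channels)
        self.output_spatial = sz
        self.spec.assert_consistent()
        if (input_size, growth, block_layers, stem_channels, compression, output_channels) == \
                (224, 32, (6, 12, 24, 16), 64, 0.5, 768):
            stages = {name: shape for name, _, shape in self.spec.stages}
            published = {
                "Convolution": (112, 112, 64),
                "Dense block (1)": (56, 56, 256),
                "Dense block (2)": (28, 28, 512),
                "Dense block (3)": (14, 14, 1024),
                "Projection": (7, 7, 768),
            }
            for stage, shape in published.items():
                if stages[stage] != shape:
                    raise AssertionError(f"stage {stage}: built {stages[stage]}, expected {shape}")

    def forward(self, x: Tensor) -> Tensor:
        if x.data.ndim != 4 or x.data.shape[1] != 3 or x.data.shape[2] != self.input_size:
            raise ValueError(
                f"expected (N,3,{self.input_size},{self.input_size}) input, got {x.data.shape}")
        y = self.stem_pool(nn.relu(self.stem_bn(self.stem_conv(x))))
        y = self.blocks(y)
        y = nn.relu(self.final_bn(y))
        return nn.relu(self.project(y))


class _ResidualVGGBlock(nn.Module):
    """n 3x3 conv layers wrapped by a skip path, merged by addition + ReLU."""

    def __init__(self, in_channels: int, out_channels: int, n_convs: int,
                 use_residual: bool, use_batchnorm: bool, rng):
        super().__init__()
        self.use_residual = use_residual
        layers: list[nn.Module] = []
        c = in_channels
        for i in range(n_convs):
            layers.append(nn.Conv2d(c, out_channels, 3, padding=1, rng=rng))
            if use_batchnorm:
                layers.append(nn.BatchNorm2d(out_channels))
            if i < n_convs - 1:
                layers.append(nn.ReLU())
            c = out_channels
        self.body = nn.Sequential(*layers)
        if use_residual:
            self.skip = (nn.Identity() if in_channels == out_channels
                         else nn.Conv2d(in_channels, out_channels, 1, rng=rng))
        self.pool = nn.MaxPool2d(2, stride=2)

    def forward(self, x: Tensor) -> Tensor:
        y = self.body(x)
        if self.use_residual:
            y = nn.add(y, self.skip(x))
        return self.pool(nn.relu(y))


class ResidualVGG16Stream(nn.Module):
    """VGG-16-style stream with per-block residual skips; (N,3,S,S) -> (N,768,S/32,S/32)."""

    def __init__(self, input_size: int = 224,
                 channels: tuple[int, ...] = (64, 128, 256, 512, 768),
                 convs_per_block: tuple[int, ...] = (2, 2, 3, 3, 3),
                 use_residual: bool = True, use_batchnorm: bool = False,
                 seed: int = 1):
        super().__init__()
        if len(channels) != len(convs_per_block):
            raise ValueError("channels and convs_per_block must have equal length")
        rng = np.random.default_rng(seed)
        self.input_size = input_size
        self.use_residual = use_residual
        self.output_channels = channels[-1]
        self.spec = StreamSpec(output_channels=channels[-1])
        c, sz = 3, input_size
        blocks = []
        for bi, (cout, ncv) in enumerate(zip(channels, convs_per_block), start=1):
            blocks.append(_ResidualVGGBlock(c, cout, ncv, use_residual, use_batchnorm, rng))
            op = f"(3 x 3 conv) x {ncv}" + (" + residual" if use_residual else "")
            self.spec.add(f"VGG block ({bi})", op, sz, sz, cout)
            sz //= 2
            self.spec.add("Pooling", "2 x 2 max pool, stride 2", sz, sz, cout)
            c = cout
        self.blocks = nn.Sequential(*blocks)
        self.output_spatial = sz
        self.spec.assert_consistent()
        if input_size == 224 and channels == (64, 128, 256, 512, 768):
            if (self.output_spatial, self.output_channels) != (7, 768):
                raise AssertionError("published VGG stream must end at 7 x 7 x 768")

    def forward(self, x: Tensor) -> Tensor:
        if x.data.ndim != 4 or x.data.shape[1] != 3 or x.data.shape[2] != self.input_size:
            raise ValueError(
                f"expected (N,3,{self.input_size},{self.input_size}) input, got {x.data.shape}")
        return self.blocks(x)


def build_densenet121_stream(input_size: int = 224, seed: int = 0, **kwargs) -> DenseNet121Stream:
    """The densely connected stream at the published configuration."""
    return DenseNet121Stream(input_size=input_size, seed=seed, **kwargs)


def build_residual_vgg16_stream(input_size: int = 224, seed: int = 1,
                                **kwargs) -> ResidualVGG16Stream:
    """The residual-augmented VGG-16 stream at the published configuration."""
    return ResidualVGG16Stream(input_size=input_size, seed=seed, **kwargs)


def stream_summary(stream) -> str:
    """Text table of (stage, operator, output size), mirroring the model tables."""
    rows = [("Layers", "Operator", "Output size")]
    for name, op, (h, w, c) in stream.spec.stages:
        rows.append((name, op, f"{h} x {w} x {c}"))
    widths = [max(len(r[i]) for r in rows) for i in range(3)]
    lines = ["  ".join(cell.ljust(w) for cell, w in zip(row, widths)).rstrip() for row in rows]
    lines.insert(1, "-" * (sum(widths) + 4))
    return "\n".join(lines)
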