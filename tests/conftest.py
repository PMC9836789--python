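"""Shared fixtures: tiny desk-scale models and small synthetic datasets."""

from dataclasses import replace

import numpy as np
import pytest

from lesionfusion import synth
from lesionfusion.backbones import DenseNet121Stream, ResidualVGG16Stream
from lesionfusion.fusion import GeMParams, TwoStreamClassifier

TINY_INPUT = 32

# downsampling bookkeeping: the dense stream halves 2 + (blocks-1) times,
# the VGG stream once per block, so 2 dense blocks pair with 3 VGG blocks
TINY_DENSENET = dict(growth=8, block_layers=(2, 2), stem_channels=8,
                     output_channels=24)
TINY_VGG = dict(channels=(8, 16, 24), convs_per_block=(1, 1, 1))


def tiny_model(seed: int = 0, gem_p: float = 4.0, use_mrf: bool = True,
               input_size: int = TINY_INPUT) -> TwoStreamClassifier:
    """A structurally faithful but slim two-stream model for fast tests.

    DenseNet stream: 32 -> 16 -> 8 (stem+pool) -> blocks/transition -> 4;
    VGG stream: two blocks, 32 -> 16 -> ... both end at matching spatial
    size with 24 channels, concatenating to 48.
    """
    dn = DenseNet121Stream(input_size=input_size, seed=seed, **TINY_DENSENET)
    vg = ResidualVGG16Stream(input_size=input_size, seed=seed + 1, **TINY_VGG)
    return TwoStreamClassifier([dn, vg], use_mrf=use_mrf, branch_channels=16,
                               allow_small=True, seed=seed + 2,
                               gem=GeMParams(p=gem_p))


@pytest.fixture(scope="session")
def synth_cfg():
    return synth.SynthConfig()

@pytest.fixture(scope="session")
def small_synth_cfg():
    """Small images keep geometry tests fast."""
    return replace(synth.SynthConfig(), image_size=64)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
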