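import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from msxfruit import MsxImage, RunConfig
from msxfruit.synth import SynthConfig, generate_scene


@pytest.fixture
def cfg() -> RunConfig:
    return RunConfig()


@pytest.fixture
def synth_cfg() -> SynthConfig:
    return SynthConfig()


@pytest.fixture
def scene(synth_cfg):
    """One default synthetic scene with a fixed seed."""
    return generate_scene(synth_cfg, seed=42)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_image(rng: np.random.Generator, h: int = 32, w: int = 32) -> MsxImage:
    return MsxImage(rng.integers(0, 256, size=(h, w, 3), dtype=np.uint8))
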