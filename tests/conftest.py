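import numpy as np
import pytest

import chromacontrast as cc


@pytest.fixture(scope="session")
def cs_cfg() -> cc.ColorSpaceConfig:
    return cc.ColorSpaceConfig()


@pytest.fixture(scope="session")
def fixtures() -> dict:
    return cc.fixture_images()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_dkl(rng: np.random.Generator, h: int = 16, w: int = 16, scale: float = 1.9) -> cc.DKLImage:
    """Random DKL image with coordinates roughly filling the histogram range."""
    return cc.DKLImage(
        ach=rng.uniform(-scale, scale, (h, w)),
        lm=rng.uniform(-scale, scale, (h, w)),
        s=rng.uniform(-scale, scale, (h, w)),
    )


def small_params(**overrides) -> cc.StillLifeParams:
    """64x64 generator parameters used throughout simulation tests."""
    defaults = dict(width=64, height=64)
    defaults.update(overrides)
    return cc.StillLifeParams(**defaults)
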