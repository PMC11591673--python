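import numpy as np
import pytest

from zframan.deconv import dho_profile
from zframan.io import SampleMeta, Spectrum


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_spectrum(
    bands,
    baseline=50.0,
    noise_sd=0.0,
    seed=0,
    grid=None,
    organ="iris",
    stage=96,
    animal="a1",
):
    """Render a synthetic spectrum from (F, W, peak_height) triplets."""
    if grid is None:
        grid = np.arange(100.0, 4000.0 + 0.5, 1.0)
    y = np.full_like(grid, float(baseline))
    for F, W, height in bands:
        y = y + dho_profile(grid, F, W, height * W / F)
    if noise_sd > 0:
        y = y + np.random.default_rng(seed).normal(0.0, noise_sd, grid.size)
    meta = SampleMeta(animal_id=animal, clutch_id="c1", organ=organ, stage_hpf=stage)
    return Spectrum(grid, y, sample=meta)


@pytest.fixture
def iris_like_bands():
    # six bands echoing an iris acquisition: strong CH/OH plus phosphate
    return [
        (980.0, 16.0, 120.0),
        (1002.0, 16.0, 140.0),
        (1409.0, 16.0, 130.0),
        (1603.0, 16.0, 150.0),
        (2929.0, 26.0, 180.0),
        (3431.0, 40.0, 130.0),
    ]
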