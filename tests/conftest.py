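import numpy as np
import pytest

from grassagb import (SceneConfig, render_scene, SpectralGrid, HyperspectralFeatures,
                      build_lut)


@pytest.fixture(scope="session")
def grid61():
    return SpectralGrid(np.linspace(400.0, 1000.0, 61))


@pytest.fixture(scope="session")
def tiny_config():
    """A fast, fully featured scene: 48x48 fine pixels, factor 8 (6x6
    coarse), 12 plots over the six treatment blocks."""
    return SceneConfig(shape=(48, 48), factor=8, n_plots=12,
                       correlation_length_px=4.0, block_grid=(2, 3),
                       spectral_bands=31, seed=7)


@pytest.fixture(scope="session")
def tiny_scene(tiny_config):
    return render_scene(tiny_config)


@pytest.fixture(scope="session")
def small_lut(grid61):
    spec = HyperspectralFeatures(grid61, (550.0, 670.0, 700.0, 740.0, 800.0))
    return build_lut(500, {"lai": (0.0, 6.0)}, spec, grid61, seed=11)
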