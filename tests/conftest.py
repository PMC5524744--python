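import numpy as np
import pytest

from hyperleaf.grid import SpectralGrid
from hyperleaf.synthetic import SceneParams, generate_scene, simulate_samples


@pytest.fixture(scope="session")
def grid() -> SpectralGrid:
    return SpectralGrid.default()


@pytest.fixture(scope="session")
def toy_grid() -> SpectralGrid:
    return SpectralGrid(np.array([500.0, 700.0]))


@pytest.fixture(scope="session")
def scene42():
    """One 3-leaf synthetic scene with default parameters."""
    return generate_scene(SceneParams(seed=42))


@pytest.fixture(scope="session")
def dataset150():
    """150 single-leaf synthetic scenes at the default noise level.

    Returns (spectra, pigments): leaf-mean spectra (150, 188) extracted
    with the ground-truth masks, and the per-leaf pigment table.
    """
    return simulate_samples(150, seed=2024, noise_sd=0.005, leaves_per_scene=1)
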