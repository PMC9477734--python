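import numpy as np
import pytest

import pavecell as pc


@pytest.fixture(scope="session")
def puzzle():
    """Six-lobed puzzle contour (R=10 um, a=0.3) with analytic curvature."""
    contour, kappa = pc.make_puzzle_cell(10.0, 6, 0.3)
    return contour, kappa


@pytest.fixture(scope="session")
def small_puzzle():
    """Smaller puzzle cell for image-painting tests."""
    contour, kappa = pc.make_puzzle_cell(5.0, 6, 0.3, vertex_spacing_um=0.2)
    return contour, kappa


@pytest.fixture(scope="session")
def sinusoid_scene():
    """256x256x40 sinusoidal-surface two-channel scene at SNR ~5."""
    spec = pc.SceneSpec(shape=(256, 256), n_z=40, read_noise_sd=200.0, seed=11)
    ref, tgt, truth = pc.make_surface_scene(
        spec,
        lambda x, y: 20 + 5 * np.sin(2 * np.pi * x / 64),
        blob_count=10,
        n_puncta=40,
    )
    return spec, ref, tgt, truth
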