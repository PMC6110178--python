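import numpy as np
import pytest
from shapely.geometry import Polygon

from opticell.recognition import CellBoundary
from opticell.synthetic import (
    CellGroundTruth,
    default_profiles,
    generate_image,
    generate_spectrum,
    noise_sd_for_snr,
)


@pytest.fixture(scope="session")
def profiles():
    return default_profiles()


@pytest.fixture(scope="session")
def euglena(profiles):
    return profiles["euglena"]


@pytest.fixture(scope="session")
def phacus(profiles):
    return profiles["phacus"]


@pytest.fixture
def square_cell():
    """100x100 µm axis-aligned square cell."""
    return CellBoundary(cell_id=0, polygon=Polygon([(0, 0), (100, 0), (100, 100), (0, 100)]))


@pytest.fixture
def circle_cell():
    """Regular 64-gon approximating a circle of radius 5 µm."""
    theta = np.linspace(0, 2 * np.pi, 65)[:-1]
    pts = list(zip(5 + 5 * np.cos(theta), 5 + 5 * np.sin(theta)))
    return CellBoundary(cell_id=1, polygon=Polygon(pts))


@pytest.fixture(scope="session")
def algae_scene_17():
    """17 non-overlapping in-range elliptical cells on a 300x300 µm slide."""
    rng = np.random.default_rng(17)
    cells = []
    # 5x4 grid with jitter, 17 cells used
    positions = [(40 + 55 * (i % 5), 40 + 65 * (i // 5)) for i in range(17)]
    for i, (x, y) in enumerate(positions):
        b = rng.uniform(4.0, 5.5)
        a = b * rng.uniform(1.0, 1.6)
        cells.append(
            CellGroundTruth(i, (x + rng.uniform(-6, 6), y + rng.uniform(-6, 6)),
                            (a, b), rng.uniform(0, np.pi), "euglena")
        )
    return cells


@pytest.fixture(scope="session")
def algae_image_17(algae_scene_17):
    """Low-noise rendering of the 17-cell scene (SNR 15 at contrast 1800)."""
    image, truth = generate_image(
        algae_scene_17, pixel_size=0.5, image_shape=(600, 600), noise_sd=120.0, seed=7
    )
    return image, truth


def make_class_spectra(profile, n, seed, snr=10.0, total=5e4, jitter=0.15):
    """n noisy single-cell spectra of one species at a given apex SNR."""
    rng = np.random.default_rng(seed)
    sd = noise_sd_for_snr(profile, total, snr)
    return [
        generate_spectrum(profile, total, sd, seed=int(rng.integers(2**31)),
                          abundance_jitter=jitter)
        for _ in range(n)
    ]
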