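import logging

import numpy as np
import pytest

import hilomfm as hm
from hilomfm.presets import tile_grid_from_plan

logging.getLogger("hilomfm").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def train256():
    """Reference optical train on a fast 256^2 computational grid."""
    return hm.default_train(256)


@pytest.fixture(scope="session")
def nine_plan(train256):
    """The standard nine-plane, 0.4 um, 3x3-tile multiplex plan."""
    return hm.nine_plane_plan(train256)


@pytest.fixture(scope="session")
def bead_phantom():
    """Seeded bead-plus-slab phantom spanning a 16 um deep volume.

    64x64 lateral voxels at 0.25 um, 40 axial slices at 0.4 um; twelve
    0.5 um beads over a uniform slab, with a bead-free corner reserved for
    background measurements and lateral bead separation enforced so each
    bead owns its axial profile.
    """
    return hm.make_phantom(
        (40, 64, 64),
        (0.4, 0.25, 0.25),
        n_beads=12,
        bead_radius=0.5,
        bead_intensity=100.0,
        slab_level=2.0,
        seed=3,
        keep_clear=(slice(0, 16), slice(0, 16)),
        min_separation=3.0,
        z_margin=1.2,
    )


@pytest.fixture(scope="session")
def small_grid(nine_plan):
    """3x3 camera tile grid with 64 px tiles for scaled-down simulations."""
    return tile_grid_from_plan(nine_plan, tile_px=64)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_field(rng, n=64, pitch=2.0, wavelength=0.55):
    arr = rng.normal(size=(n, n)) + 1j * rng.normal(size=(n, n))
    return hm.ComplexField(arr, pitch, wavelength)
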