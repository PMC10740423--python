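"""Shared fixtures: analytic sphere bundles and knee phantoms.

Expensive phantom generations are session-scoped so every test file reuses
one instance. Grids used for voxelization oracles carry a small irrational
origin offset so no voxel center lies exactly on a mesh surface (inside /
outside is then well defined everywhere).
"""

import numpy as np
import pytest

from kneeforge.core import CTVolume
from kneeforge.phantom import PhantomSpec, generate_phantom, sphere_fixture

#: sub-voxel origin shift putting oracle grids in general position
GENERAL_POSITION_OFFSET = (0.1317, 0.2173, 0.3391)


@pytest.fixture(scope="session")
def sphere_bundle():
    """Analytic sphere, radius 10 mm on a 1 mm grid."""
    return sphere_fixture(radius=10.0, spacing=1.0, mesh_refine=2)


@pytest.fixture(scope="session")
def phantom_default():
    """Default two-body knee phantom: 96 mm box, 1 mm voxels, 4 mm gap."""
    return generate_phantom(PhantomSpec(seed=0))


@pytest.fixture(scope="session")
def phantom_small():
    """Coarse phantom (2 mm voxels, 48 cube) for fast end-to-end tests."""
    return generate_phantom(
        PhantomSpec(shape=(48, 48, 48), spacing=(2.0, 2.0, 2.0), joint_gap=4.0, seed=1)
    )


@pytest.fixture
def offset_grid():
    """Factory for oracle grids in general position."""

    def make(shape, spacing=1.0):
        return CTVolume(
            np.zeros(shape),
            spacing=(spacing,) * 3,
            origin=GENERAL_POSITION_OFFSET,
        )

    return make


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
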