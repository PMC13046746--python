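import numpy as np
import pytest

from icplab.synthetic import HeadMeshSpec, gen_head_mesh


@pytest.fixture(scope="session")
def sphere_mesh_fine():
    """50 mm sphere at ~2 mm edges (volume within 0.06% of analytic)."""
    return gen_head_mesh(HeadMeshSpec(shape="sphere", semi_axes=(50.0,) * 3, mesh_resolution=2.0))


@pytest.fixture(scope="session")
def sphere_mesh_coarse():
    """50 mm sphere at ~5 mm edges, cheap enough for optimization loops."""
    return gen_head_mesh(HeadMeshSpec(shape="sphere", semi_axes=(50.0,) * 3, mesh_resolution=5.0))


@pytest.fixture(scope="session")
def ellipsoid_mesh():
    """Default 70 x 90 x 80 mm head stand-in at ~8 mm edges."""
    return gen_head_mesh(HeadMeshSpec(mesh_resolution=8.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
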