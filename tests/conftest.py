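import numpy as np
import pytest

import myofibrekit as mk


@pytest.fixture(scope="session")
def sphere_shell():
    """Full spherical shell (7..10 mm), moderate resolution."""
    spec = mk.SyntheticSpec(
        inner_radius=7.0, outer_radius=10.0, truncation_fraction=1.0,
        long_axis_ratio=1.0, target_edge_length=1.2, seed=1,
    )
    return mk.generate_ventricle_mesh(spec)


@pytest.fixture(scope="session")
def ventricle():
    """Truncated idealized ventricle with ebar and local frames."""
    spec = mk.SyntheticSpec(
        inner_radius=7.0, outer_radius=10.0, truncation_fraction=0.75,
        long_axis_ratio=1.0, target_edge_length=1.05, seed=3,
    )
    mesh = mk.generate_ventricle_mesh(spec)
    ebar = mk.solve_transmural_coordinate(mesh)
    frames = mk.build_local_frames(mesh, ebar, np.array([0.0, 0.0, -1.0]))
    return mesh, ebar, frames


@pytest.fixture(scope="session")
def slab():
    return mk.generate_slab_mesh((5, 4, 4))


@pytest.fixture
def rng():
    return np.random.default_rng(20231001)


@pytest.fixture(scope="session")
def material_triad():
    return (
        np.array([1.0, 0.0, 0.0]),
        np.array([0.0, 1.0, 0.0]),
        np.array([0.0, 0.0, 1.0]),
    )
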