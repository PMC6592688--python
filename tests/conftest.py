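import numpy as np
import pytest

from frillsim.geometry import GeometryParams, Kind, build_mesh


@pytest.fixture(scope="session")
def coarse_semicylinder():
    params = GeometryParams(
        kind=Kind.SEMICYLINDER,
        thickness_T=0.02,
        boundary_length_L=1.0,
        resolution=(8, 20),
        through_thickness_layers=2,
    )
    return params, build_mesh(params)


@pytest.fixture(scope="session")
def coarse_lobe():
    params = GeometryParams(
        kind=Kind.CURVED_LOBE,
        thickness_T=0.047,
        boundary_length_L=0.047 / 0.014,
        resolution=(8, 16),
        through_thickness_layers=2,
    )
    return params, build_mesh(params)


@pytest.fixture(scope="session")
def coarse_bilayer():
    params = GeometryParams(
        kind=Kind.BILAYER_FRILL,
        thickness_T=0.047,
        boundary_length_L=0.047 / 0.014,
        resolution=(8, 16),
        through_thickness_layers=2,
        substrate_depth_ratio=10.0,
        substrate_layers=3,
    )
    return params, build_mesh(params)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def two_tet_mesh():
    """Tiny two-tet mesh (shared face) for energy-gradient oracles."""
    from frillsim.geometry import TetMesh

    nodes = np.array(
        [
            [0.0, 0.0, 0.0],
            [1.0, 0.0, 0.0],
            [0.0, 1.0, 0.0],
            [0.0, 0.0, 1.0],
            [1.0, 1.0, 1.0],
        ]
    )
    tets = np.array([[0, 1, 2, 3], [1, 2, 3, 4]])
    x = nodes[tets]
    vol = np.linalg.det(x[:, 1:] - x[:, :1]) / 6.0
    assert (vol > 0).all()
    return TetMesh(
        node_positions=nodes,
        tets=tets,
        region_of_tet=np.zeros(2, dtype=np.int64),
        node_sets={
            "FIXED_INNER": np.array([], dtype=np.int64),
            "CREASE": np.array([], dtype=np.int64),
            "ANTERIOR_SURFACE": np.arange(5),
            "FREE_EDGE": np.array([], dtype=np.int64),
        },
        reference_normal_of_tet=np.tile([0.0, 0.0, 1.0], (2, 1)),
        crease_direction=np.array([0.0, 1.0, 0.0]),
        spacing_a=1.0,
        inner_boundary_length_L=1.0,
        thickness_T=0.1,
        band_fraction=np.zeros(5),
        arc_coord=nodes[:, 0].copy(),
    )
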