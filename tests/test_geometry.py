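"""Geometry construction: volumes, node sets, normals, depth fields."""

import numpy as np
import pytest

from frillsim.geometry import (
    GeometryParams,
    Kind,
    analytic_volume,
    boundary_faces,
    build_mesh,
    compute_depth_fields,
    validate_mesh,
)


@pytest.mark.parametrize(
    "kind,kw",
    [
        (Kind.SEMICYLINDER, dict(thickness_T=0.02, boundary_length_L=1.0, resolution=(10, 24))),
        (Kind.CURVED_LOBE, dict(thickness_T=0.047, boundary_length_L=0.047 / 0.014, resolution=(10, 20))),
        (
            Kind.BILAYER_FRILL,
            dict(
                thickness_T=0.047,
                boundary_length_L=0.047 / 0.014,
                resolution=(10, 20),
                substrate_depth_ratio=10.0,
                substrate_layers=3,
            ),
        ),
        (
            Kind.FLAT_STRIP,
            dict(
                thickness_T=0.047,
                boundary_length_L=1.0,
                resolution=(24, 2),
                substrate_depth_ratio=10.0,
                substrate_layers=3,
            ),
        ),
    ],
)
def test_construction_invariants(kind, kw):
    """Positive volumes, unit normals, in-range node sets, ~1% volume match
    against the closed-form parametric solid."""
    params = GeometryParams(kind=kind, through_thickness_layers=2, **kw)
    mesh = build_mesh(params)
    vols = mesh.tet_volumes()
    assert (vols > 0).all()
    assert abs(vols.sum() - analytic_volume(params)) / analytic_volume(params) < 0.01
    assert np.allclose(
        np.linalg.norm(mesh.reference_normal_of_tet, axis=1), 1.0, atol=1e-12
    )
    assert abs(np.linalg.norm(mesh.crease_direction) - 1.0) < 1e-12
    assert mesh.spacing_a > 0 and mesh.inner_boundary_length_L > 0
    n = mesh.n_nodes
    for name, nodes in mesh.node_sets.items():
        assert len(nodes) == 0 or (nodes.min() >= 0 and nodes.max() < n)
    assert not set(mesh.node_sets["FIXED_INNER"]) & set(mesh.node_sets["FREE_EDGE"])
    assert mesh.tets.min() >= 0 and mesh.tets.max() < n


def test_volume_converges_under_refinement():
    """Doubling resolution shrinks the volume error well below 0.5%."""
    kw = dict(
        kind=Kind.CURVED_LOBE,
        thickness_T=0.047,
        boundary_length_L=0.047 / 0.014,
        through_thickness_layers=2,
    )
    errs = []
    for res in [(6, 12), (12, 24)]:
        params = GeometryParams(resolution=res, **kw)
        mesh = build_mesh(params)
        va = analytic_volume(params)
        errs.append(abs(mesh.tet_volumes().sum() - va) / va)
    assert errs[1] < errs[0]
    assert errs[1] < 0.005


def test_semicylinder_thickness_uniform(coarse_semicylinder):
    """Measured max/min sheet thickness deviates < 2% from T."""
    params, mesh = coarse_semicylinder
    z = mesh.node_positions[:, 2]
    assert abs(z.max() - z.min() - params.thickness_T) < 0.02 * params.thickness_T


def test_pdms_scale_semicylinder():
    """The PDMS-analog sheet: L = 84.62, T/L = 0.01 gives T = 0.8462."""
    params = GeometryParams(
        kind=Kind.SEMICYLINDER,
        thickness_T=0.8462,
        boundary_length_L=84.62,
        resolution=(8, 20),
        through_thickness_layers=2,
    )
    mesh = build_mesh(params)
    z = mesh.node_positions[:, 2]
    assert np.isclose(z.max() - z.min(), 0.8462, rtol=1e-12)


def test_lobe_crease_nodes_coplanar(coarse_lobe):
    params, mesh = coarse_lobe
    crease = mesh.node_positions[mesh.node_sets["CREASE"]]
    assert np.abs(crease[:, 0]).max() < 1e-9 * params.boundary_length_L


def test_bilayer_skin_thickness_and_volume_ratio(coarse_bilayer):
    params, mesh = coarse_bilayer
    vols = mesh.tet_volumes()
    skin = vols[mesh.region_of_tet == 0].sum()
    sub = vols[mesh.region_of_tet == 1].sum()
    assert abs(sub / skin - params.substrate_depth_ratio) < 0.05 * params.substrate_depth_ratio
    # skin layer thickness
    cz = mesh.tet_centroids()[:, 2]
    assert (cz[mesh.region_of_tet == 0] > 0).all()
    z = mesh.node_positions[:, 2]
    assert abs(z.max() - params.thickness_T) < 0.02 * params.thickness_T


def test_bilayer_interface_conforms(coarse_bilayer):
    """Every interface node belongs to at least one skin and one substrate
    tet, and no duplicate nodes exist there."""
    _, mesh = coarse_bilayer
    interface = np.flatnonzero(np.abs(mesh.node_positions[:, 2]) < 1e-12)
    touch_skin = np.zeros(mesh.n_nodes, bool)
    touch_sub = np.zeros(mesh.n_nodes, bool)
    touch_skin[mesh.tets[mesh.region_of_tet == 0].ravel()] = True
    touch_sub[mesh.tets[mesh.region_of_tet == 1].ravel()] = True
    assert touch_skin[interface].all() and touch_sub[interface].all()
    uniq = np.unique(mesh.node_positions[interface].round(12), axis=0)
    assert len(uniq) == len(interface)


def test_crease_spans_both_layers(coarse_bilayer):
    _, mesh = coarse_bilayer
    z = mesh.node_positions[mesh.node_sets["CREASE"], 2]
    assert z.min() < 0 < z.max()


def test_mirror_symmetry():
    kw = dict(
        kind=Kind.CURVED_LOBE,
        thickness_T=0.047,
        boundary_length_L=0.047 / 0.014,
        resolution=(6, 10),
        through_thickness_layers=2,
    )
    plain = build_mesh(GeometryParams(**kw))
    mirrored = build_mesh(GeometryParams(mirror=True, **kw))
    ref = plain.node_positions.copy()
    ref[:, 0] *= -1
    a = np.array(sorted(map(tuple, np.round(ref, 12))))
    b = np.array(sorted(map(tuple, np.round(mirrored.node_positions, 12))))
    assert np.allclose(a, b, atol=1e-12)
    assert (mirrored.tet_volumes() > 0).all()


def test_rejects_degenerate_params():
    with pytest.raises(ValueError):
        GeometryParams(kind=Kind.SEMICYLINDER, thickness_T=0.02, boundary_length_L=1.0, resolution=(1, 8))
    with pytest.raises(ValueError):
        GeometryParams(kind=Kind.SEMICYLINDER, thickness_T=-0.02, boundary_length_L=1.0)
    with pytest.raises(ValueError):
        GeometryParams(kind=Kind.CURVED_LOBE, thickness_T=0.02, boundary_length_L=1.0, arc_angle_deg=200.0)
    with pytest.raises(ValueError):
        GeometryParams(kind=Kind.CURVED_LOBE, thickness_T=0.02, boundary_length_L=1.0, through_thickness_layers=1)
    with pytest.raises(ValueError):
        # T/L ratio above 0.1
        GeometryParams(kind=Kind.CURVED_LOBE, thickness_T=0.5, boundary_length_L=1.0)
    with pytest.raises(ValueError):
        GeometryParams(kind=Kind.BILAYER_FRILL, thickness_T=0.02, boundary_length_L=1.0, substrate_depth_ratio=2.0)


def test_depth_fields_slab_and_crease(coarse_lobe):
    """x_s spans (0, T); surface-adjacent tets have x_s <= a/2; crease-
    adjacent tets have x_c <= a/2."""
    params, mesh = coarse_lobe
    x_s, x_c = compute_depth_fields(mesh)
    assert (x_s >= 0).all() and (x_c >= 0).all()
    T, a = params.thickness_T, mesh.spacing_a
    assert x_s.max() <= T
    surface = np.zeros(mesh.n_nodes, bool)
    surface[mesh.node_sets["ANTERIOR_SURFACE"]] = True
    has_surface_face = surface[mesh.tets].sum(axis=1) >= 3
    assert (x_s[has_surface_face] <= a / 2).all()
    crease = np.zeros(mesh.n_nodes, bool)
    crease[mesh.node_sets["CREASE"]] = True
    crease[np.intersect1d(mesh.node_sets["FIXED_INNER"], np.flatnonzero(np.abs(mesh.node_positions[:,0])<1e-12))] = True
    touches_crease = crease[mesh.tets].sum(axis=1) >= 3
    assert (x_c[touches_crease] <= a / 2).all()


def test_depth_field_matches_independent_oracle(coarse_lobe):
    """x_s equals the exact point-to-surface distance computed by trimesh
    on the same anterior-surface triangle soup."""
    import trimesh
    from frillsim.geometry import surface_triangles

    _, mesh = coarse_lobe
    x_s, _ = compute_depth_fields(mesh)
    tris = surface_triangles(mesh, "ANTERIOR_SURFACE")
    tm = trimesh.Trimesh(vertices=mesh.node_positions, faces=tris, process=False)
    cent = mesh.tet_centroids()
    _, oracle, _ = trimesh.proximity.closest_point_naive(tm, cent)
    assert np.abs(x_s - oracle).max() < 1e-9


def test_validate_mesh_flags_constructed_defect(coarse_semicylinder):
    _, mesh = coarse_semicylinder
    assert validate_mesh(mesh)["n_inverted"] == 0
    import copy

    broken = copy.deepcopy(mesh)
    broken.tets[5] = broken.tets[5][[0, 2, 1, 3]]
    rep = validate_mesh(broken)
    assert rep["n_inverted"] == 1 and rep["inverted_tets"] == [5]


def test_boundary_faces_closed_surface(coarse_lobe):
    """Boundary triangles form a closed surface: total outward area vector
    sums to ~0 and the count matches Euler-consistent expectations."""
    _, mesh = coarse_lobe
    bf = boundary_faces(mesh)
    p = mesh.node_positions
    n = np.cross(p[bf[:, 1]] - p[bf[:, 0]], p[bf[:, 2]] - p[bf[:, 0]])
    assert np.linalg.norm(n.sum(axis=0)) < 1e-9 * np.linalg.norm(n, axis=1).sum()
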