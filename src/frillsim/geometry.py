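"""Parametric tetrahedral geometries for frill growth simulations.

All meshes are built from a structured curvilinear hexahedral lattice in
which every hexahedron is split into six consistently oriented tetrahedra.
This gives reproducible connectivity without an external mesher and
guarantees a conforming interface between the skin sheet and the substrate
in bilayer meshes.

Coordinate conventions: the crease plane is the y-z plane (x = 0), the
anterior surface normal points along +z, and all lengths are in mm.
Node indices are 0-based in memory.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

__all__ = [
    "Kind",
    "Region",
    "GeometryParams",
    "TetMesh",
    "build_semicylinder_sheet",
    "build_curved_lobe_sheet",
    "build_bilayer_frill",
    "build_flat_bilayer_strip",
    "build_mesh",
    "analytic_volume",
    "compute_depth_fields",
    "validate_mesh",
    "boundary_faces",
    "surface_triangles",
]


class Kind(str, Enum):
    SEMICYLINDER = "SEMICYLINDER"
    CURVED_LOBE = "CURVED_LOBE"
    BILAYER_FRILL = "BILAYER_FRILL"
    FLAT_STRIP = "FLAT_STRIP"


class Region(int, Enum):
    SKIN = 0
    SUBSTRATE = 1


# Split of the unit hexahedron (corner bits -> x,y,z) into six positively
# oriented tetrahedra sharing the 0-6 diagonal.
_HEX_TO_TETS = np.array(
    [
        [0, 1, 2, 6],
        [0, 2, 3, 6],
        [0, 3, 7, 6],
        [0, 7, 4, 6],
        [0, 4, 5, 6],
        [0, 5, 1, 6],
    ],
    dtype=np.int64,
)
# corner offsets (di, dj, dk) for hex corners 0..7
_HEX_CORNERS = np.array(
    [
        (0, 0, 0),
        (1, 0, 0),
        (1, 1, 0),
        (0, 1, 0),
        (0, 0, 1),
        (1, 0, 1),
        (1, 1, 1),
        (0, 1, 1),
    ],
    dtype=np.int64,
)


@dataclass
class GeometryParams:
    """Parameters of a parametric frill geometry.

    ``thickness_T`` is the skin-sheet thickness and ``boundary_length_L``
    the length of the fixed boundary (the diameter of the semicylindrical
    sheet, or the inner-arc length of a lobe).  ``resolution`` counts lattice
    cells along the two in-plane directions; ``through_thickness_layers``
    counts cells through the skin thickness.
    """

    kind: Kind = Kind.CURVED_LOBE
    thickness_T: float = 0.047
    boundary_length_L: float = 0.047 / 0.014
    resolution: tuple[int, int] = (24, 48)
    through_thickness_layers: int = 2
    # bilayer only
    substrate_depth_ratio: float = 10.0
    substrate_layers: int = 4
    substrate_grading: float = 1.8
    # lobe only
    arc_angle_deg: float = 120.0
    lobe_extent: float = 1.0
    # semicylinder only: relative radius of the tiny central hole that keeps
    # the polar lattice non-degenerate
    inner_hole_ratio: float = 0.04
    # flat strip only
    strip_length_factor: float = 60.0  # length in units of T
    strip_width_cells: int = 2
    mirror: bool = False

    def __post_init__(self) -> None:
        self.kind = Kind(self.kind)
        if self.thickness_T <= 0 or self.boundary_length_L <= 0:
            raise ValueError("thickness_T and boundary_length_L must be positive")
        ratio = self.thickness_T / self.boundary_length_L
        if self.kind is not Kind.FLAT_STRIP and not (0.0 < ratio <= 0.1):
            raise ValueError(
                f"thickness/boundary-length ratio {ratio:.4f} outside (0, 0.1]"
            )
        if self.through_thickness_layers < 2:
            raise ValueError("through_thickness_layers must be >= 2 for the skin")
        if min(self.resolution) < 2:
            raise ValueError("resolution must be >= 2 cells in each dimension")
        if self.kind is Kind.BILAYER_FRILL and self.substrate_depth_ratio < 5:
            raise ValueError("substrate_depth_ratio must be >= 5")
        if self.kind in (Kind.CURVED_LOBE, Kind.BILAYER_FRILL):
            if not (0.0 < self.arc_angle_deg <= 180.0):
                raise ValueError("arc angle must be in (0, 180] degrees")


@dataclass
class TetMesh:
    """Tetrahedral reference geometry with region labels and node sets.

    ``band_fraction`` and ``arc_coord`` are reference-parametrisation
    helpers used by the morphometrics sampling bands: the normalised
    in-plane distance from the fixed boundary towards the free edge, and
    the arc-length coordinate along a band, both evaluated in the
    undeformed configuration.
    """

    node_positions: np.ndarray  # (n, 3) mm
    tets: np.ndarray  # (m, 4) int
    region_of_tet: np.ndarray  # (m,) int  (Region values)
    node_sets: dict[str, np.ndarray]
    reference_normal_of_tet: np.ndarray  # (m, 3) unit
    crease_direction: np.ndarray  # (3,) unit
    spacing_a: float
    inner_boundary_length_L: float
    thickness_T: float
    band_fraction: np.ndarray = field(default=None, repr=False)
    arc_coord: np.ndarray = field(default=None, repr=False)
    kind: Kind = Kind.CURVED_LOBE
    #: parent hex of each tet (six tets per lattice cell); used for
    #: mean-dilatation volumetric averaging in the solver
    cluster_of_tet: np.ndarray = field(default=None, repr=False)

    @property
    def n_nodes(self) -> int:
        return len(self.node_positions)

    @property
    def n_tets(self) -> int:
        return len(self.tets)

    def tet_volumes(self) -> np.ndarray:
        """Signed volumes under the fixed node-ordering convention."""
        x = self.node_positions[self.tets]
        e = x[:, 1:] - x[:, :1]
        return np.linalg.det(e) / 6.0

    def tet_centroids(self) -> np.ndarray:
        return self.node_positions[self.tets].mean(axis=1)


def _structured_tets(n_u: int, n_v: int, n_w: int):
    """Connectivity of an (n_u, n_v, n_w)-cell structured lattice."""

    def nid(i, j, k):
        return (i * (n_v + 1) + j) * (n_w + 1) + k

    ii, jj, kk = np.meshgrid(
        np.arange(n_u), np.arange(n_v), np.arange(n_w), indexing="ij"
    )
    cells = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1)  # (ncell, 3)
    corners = cells[:, None, :] + _HEX_CORNERS[None, :, :]  # (ncell, 8, 3)
    corner_ids = nid(corners[..., 0], corners[..., 1], corners[..., 2])
    tets = corner_ids[:, _HEX_TO_TETS].reshape(-1, 4)
    return tets, nid


def _mean_edge_length(nodes: np.ndarray, tets: np.ndarray) -> float:
    pairs = tets[:, [[0, 1], [0, 2], [0, 3], [1, 2], [1, 3], [2, 3]]].reshape(-1, 2)
    pairs = np.unique(np.sort(pairs, axis=1), axis=0)
    d = np.linalg.norm(nodes[pairs[:, 0]] - nodes[pairs[:, 1]], axis=1)
    return float(d.mean())


def _fix_orientation(nodes: np.ndarray, tets: np.ndarray) -> np.ndarray:
    """Swap two vertices of any negatively oriented tet (curvilinear maps
    can flip the canonical split)."""
    x = nodes[tets]
    vol = np.linalg.det(x[:, 1:] - x[:, :1])
    flipped = vol < 0
    tets = tets.copy()
    tets[flipped] = tets[flipped][:, [0, 2, 1, 3]]
    return tets


def _finalize(
    nodes,
    tets,
    region,
    node_sets,
    normal,
    crease_dir,
    L,
    T,
    band_fraction,
    arc_coord,
    kind,
    mirror,
) -> TetMesh:
    if mirror:
        nodes = nodes.copy()
        nodes[:, 0] *= -1.0
        tets = tets[:, [0, 2, 1, 3]]  # keep positive orientation
    tets = _fix_orientation(nodes, tets)
    mesh = TetMesh(
        node_positions=nodes,
        tets=tets,
        region_of_tet=region,
        node_sets={k: np.asarray(sorted(v), dtype=np.int64) for k, v in node_sets.items()},
        reference_normal_of_tet=normal,
        crease_direction=crease_dir,
        spacing_a=_mean_edge_length(nodes, tets),
        inner_boundary_length_L=L,
        thickness_T=T,
        band_fraction=band_fraction,
        arc_coord=arc_coord,
        kind=kind,
        cluster_of_tet=np.arange(len(tets), dtype=np.int64) // 6,
    )
    vols = mesh.tet_volumes()
    if (vols <= 0).any():
        raise RuntimeError("mesh construction produced non-positive tet volumes")
    return mesh


def build_semicylinder_sheet(params: GeometryParams) -> TetMesh:
    """Thin semicylindrical (half-disc) sheet of diameter L and thickness T.

    The straight diameter edge is the fixed boundary; the curved rim is
    free.  A tiny central hole (radius ``inner_hole_ratio`` x L/2) keeps the
    polar lattice non-degenerate; its volume is accounted for in the
    analytic half-annulus volume.
    """
    if Kind(params.kind) is not Kind.SEMICYLINDER:
        raise ValueError("params.kind must be SEMICYLINDER")
    T, L = params.thickness_T, params.boundary_length_L
    R = L / 2.0
    r0 = params.inner_hole_ratio * R
    n_r, n_t = params.resolution
    n_z = params.through_thickness_layers

    r = np.linspace(r0, R, n_r + 1)
    th = np.linspace(0.0, math.pi, n_t + 1)
    z = np.linspace(0.0, T, n_z + 1)
    rr, tt, zz = np.meshgrid(r, th, z, indexing="ij")
    nodes = np.stack(
        [rr * np.cos(tt), rr * np.sin(tt), zz], axis=-1
    ).reshape(-1, 3)
    tets, nid = _structured_tets(n_r, n_t, n_z)

    iu, jv, kw = np.meshgrid(
        np.arange(n_r + 1), np.arange(n_t + 1), np.arange(n_z + 1), indexing="ij"
    )
    ids = nid(iu, jv, kw)
    fixed = set(ids[:, 0, :].ravel()) | set(ids[:, -1, :].ravel()) | set(
        ids[0, :, :].ravel()
    )
    free = set(ids[-1, :, :].ravel()) - fixed
    anterior = set(ids[:, :, -1].ravel())
    node_sets = {
        "FIXED_INNER": fixed,
        "FREE_EDGE": free,
        "ANTERIOR_SURFACE": anterior,
        "CREASE": set(),
    }
    region = np.zeros(len(tets), dtype=np.int64)
    normal = np.tile(np.array([0.0, 0.0, 1.0]), (len(tets), 1))
    rad = np.linalg.norm(nodes[:, :2], axis=1)
    band = (rad - r0) / (R - r0)
    arc = np.arctan2(nodes[:, 1], nodes[:, 0]) * rad
    return _finalize(
        nodes, tets, region, node_sets, normal, np.array([0.0, 1.0, 0.0]),
        L, T, band, arc, Kind.SEMICYLINDER, params.mirror,
    )


def _lobe_grid(params: GeometryParams, z_levels: np.ndarray):
    """Shared in-plane lattice of the curved-lobe geometries."""
    T, L = params.thickness_T, params.boundary_length_L
    theta_max = math.radians(params.arc_angle_deg)
    R_in = L / theta_max
    R_out = R_in + params.lobe_extent * L
    n_r, n_t = params.resolution
    n_z = len(z_levels) - 1

    r = np.linspace(R_in, R_out, n_r + 1)
    th = np.linspace(0.0, theta_max, n_t + 1)
    rr, tt, zz = np.meshgrid(r, th, z_levels, indexing="ij")
    # crease edge at theta = 0 lies along +y in the x=0 plane
    nodes = np.stack([rr * np.sin(tt), rr * np.cos(tt), zz], axis=-1).reshape(-1, 3)
    tets, nid = _structured_tets(n_r, n_t, n_z)
    iu, jv, kw = np.meshgrid(
        np.arange(n_r + 1), np.arange(n_t + 1), np.arange(n_z + 1), indexing="ij"
    )
    ids = nid(iu, jv, kw)
    rad = np.linalg.norm(nodes[:, :2], axis=1)
    band = (rad - R_in) / (R_out - R_in)
    arc = np.arctan2(nodes[:, 0], nodes[:, 1]) * rad  # theta * r
    return nodes, tets, ids, band, arc, R_in, R_out


def build_curved_lobe_sheet(params: GeometryParams) -> TetMesh:
    """Single frill lobe: thin sheet with a fixed circular inner arc and a
    straight sagittal crease edge lying in the y-z plane."""
    if Kind(params.kind) is not Kind.CURVED_LOBE:
        raise ValueError("params.kind must be CURVED_LOBE")
    T = params.thickness_T
    z_levels = np.linspace(0.0, T, params.through_thickness_layers + 1)
    nodes, tets, ids, band, arc, R_in, R_out = _lobe_grid(params, z_levels)
    fixed = set(ids[0, :, :].ravel())
    crease = set(ids[:, 0, :].ravel()) - fixed
    free = (set(ids[-1, :, :].ravel()) | set(ids[:, -1, :].ravel())) - fixed
    anterior = set(ids[:, :, -1].ravel())
    node_sets = {
        "FIXED_INNER": fixed,
        "CREASE": crease,
        "FREE_EDGE": free,
        "ANTERIOR_SURFACE": anterior,
    }
    region = np.zeros(len(tets), dtype=np.int64)
    normal = np.tile(np.array([0.0, 0.0, 1.0]), (len(tets), 1))
    return _finalize(
        nodes, tets, region, node_sets, normal, np.array([0.0, 1.0, 0.0]),
        params.boundary_length_L, T, band, arc, Kind.CURVED_LOBE, params.mirror,
    )


def _substrate_levels(params: GeometryParams) -> np.ndarray:
    """Geometrically graded substrate z-levels from -D to 0 (thin layers at
    the skin interface)."""
    T = params.thickness_T
    D = params.substrate_depth_ratio * T
    n = params.substrate_layers
    g = params.substrate_grading
    w = g ** np.arange(n)
    w = w / w.sum() * D
    levels = -np.concatenate([[0.0], np.cumsum(w)])[::-1]
    return levels


def build_bilayer_frill(params: GeometryParams) -> TetMesh:
    """Curved lobe skin sheet on a conforming soft-substrate block.

    The substrate extends ``substrate_depth_ratio * T`` beneath the skin,
    shares nodes on the interface plane z = 0, and uses geometrically
    graded layers (finer near the interface).  The crease spans both layers.
    """
    if Kind(params.kind) is not Kind.BILAYER_FRILL:
        raise ValueError("params.kind must be BILAYER_FRILL")
    T = params.thickness_T
    sub = _substrate_levels(params)
    skin = np.linspace(0.0, T, params.through_thickness_layers + 1)
    z_levels = np.concatenate([sub[:-1], skin])
    nodes, tets, ids, band, arc, R_in, R_out = _lobe_grid(params, z_levels)
    fixed = set(ids[0, :, :].ravel())
    crease = set(ids[:, 0, :].ravel()) - fixed
    free = (set(ids[-1, :, :].ravel()) | set(ids[:, -1, :].ravel())) - fixed
    anterior = set(ids[:, :, -1].ravel())
    node_sets = {
        "FIXED_INNER": fixed,
        "CREASE": crease,
        "FREE_EDGE": free,
        "ANTERIOR_SURFACE": anterior,
    }
    cz = nodes[tets].mean(axis=1)[:, 2]
    region = np.where(cz < 0.0, int(Region.SUBSTRATE), int(Region.SKIN)).astype(np.int64)
    normal = np.tile(np.array([0.0, 0.0, 1.0]), (len(tets), 1))
    return _finalize(
        nodes, tets, region, node_sets, normal, np.array([0.0, 1.0, 0.0]),
        params.boundary_length_L, T, band, arc, Kind.BILAYER_FRILL, params.mirror,
    )


def build_flat_bilayer_strip(params: GeometryParams) -> TetMesh:
    """Flat stiff-film-on-substrate strip for wavelength benchmarks.

    Skin occupies z in [0, T] over a graded substrate block; the strip runs
    along x with length ``strip_length_factor * T``.  The bottom face and
    both x-end faces are fixed.  Film growth along x (the crease direction
    of this mesh) drives periodic wrinkling.
    """
    if Kind(params.kind) is not Kind.FLAT_STRIP:
        raise ValueError("params.kind must be FLAT_STRIP")
    T = params.thickness_T
    length = params.strip_length_factor * T
    n_x, _ = params.resolution
    n_y = params.strip_width_cells
    width = n_y * (length / n_x)  # near-unit in-plane aspect cells
    sub = _substrate_levels(params)
    skin = np.linspace(0.0, T, params.through_thickness_layers + 1)
    z_levels = np.concatenate([sub[:-1], skin])
    n_z = len(z_levels) - 1

    x = np.linspace(0.0, length, n_x + 1)
    y = np.linspace(0.0, width, n_y + 1)
    xx, yy, zz = np.meshgrid(x, y, z_levels, indexing="ij")
    nodes = np.stack([xx, yy, zz], axis=-1).reshape(-1, 3)
    tets, nid = _structured_tets(n_x, n_y, n_z)
    iu, jv, kw = np.meshgrid(
        np.arange(n_x + 1), np.arange(n_y + 1), np.arange(n_z + 1), indexing="ij"
    )
    ids = nid(iu, jv, kw)
    fixed = (
        set(ids[:, :, 0].ravel())
        | set(ids[0, :, :].ravel())
        | set(ids[-1, :, :].ravel())
    )
    anterior = set(ids[:, :, -1].ravel())
    node_sets = {
        "FIXED_INNER": fixed,
        "CREASE": set(),
        "FREE_EDGE": set(),
        "ANTERIOR_SURFACE": anterior,
    }
    cz = nodes[tets].mean(axis=1)[:, 2]
    region = np.where(cz < 0.0, int(Region.SUBSTRATE), int(Region.SKIN)).astype(np.int64)
    normal = np.tile(np.array([0.0, 0.0, 1.0]), (len(tets), 1))
    band = nodes[:, 1] / max(width, 1e-30)
    arc = nodes[:, 0].copy()
    return _finalize(
        nodes, tets, region, node_sets, normal, np.array([1.0, 0.0, 0.0]),
        length, T, band, arc, Kind.FLAT_STRIP, params.mirror,
    )


_BUILDERS = {
    Kind.SEMICYLINDER: build_semicylinder_sheet,
    Kind.CURVED_LOBE: build_curved_lobe_sheet,
    Kind.BILAYER_FRILL: build_bilayer_frill,
    Kind.FLAT_STRIP: build_flat_bilayer_strip,
}


def build_mesh(params: GeometryParams) -> TetMesh:
    """Dispatch to the builder for ``params.kind``."""
    return _BUILDERS[Kind(params.kind)](params)


# ---------------------------------------------------------------------------
# derived fields and diagnostics

_FACE_OF_TET = np.array([[1, 2, 3], [0, 3, 2], [0, 1, 3], [0, 2, 1]], dtype=np.int64)


def boundary_faces(mesh: TetMesh) -> np.ndarray:
    """Outward-oriented boundary triangles (faces owned by exactly one tet)."""
    faces = mesh.tets[:, _FACE_OF_TET].reshape(-1, 3)
    key = np.sort(faces, axis=1)
    _, inv, counts = np.unique(key, axis=0, return_inverse=True, return_counts=True)
    return faces[counts[inv] == 1]


def surface_triangles(mesh: TetMesh, node_set: str = "ANTERIOR_SURFACE") -> np.ndarray:
    """Boundary triangles whose three vertices all belong to ``node_set``."""
    bf = boundary_faces(mesh)
    members = np.zeros(mesh.n_nodes, dtype=bool)
    members[mesh.node_sets[node_set]] = True
    return bf[members[bf].all(axis=1)]


def compute_depth_fields(mesh: TetMesh):
    """Per-tet centroid distances to the anterior surface (x_s) and to the
    crease plane (x_c), both in mm.

    Returns ``(x_s, x_c)``; ``x_c`` is +inf everywhere when the mesh has no
    crease (no crease-directed growth applies there).
    """
    if len(mesh.node_sets.get("ANTERIOR_SURFACE", ())) == 0:
        raise ValueError("ANTERIOR_SURFACE node set is empty")
    tris = surface_triangles(mesh, "ANTERIOR_SURFACE")
    if len(tris) == 0:
        raise ValueError("no boundary triangles on the anterior surface")
    centroids = mesh.tet_centroids()
    x_s = _point_triangle_distances(centroids, mesh.node_positions, tris)

    crease = mesh.node_sets.get("CREASE", np.empty(0, dtype=np.int64))
    if len(crease) == 0:
        x_c = np.full(mesh.n_tets, np.inf)
    else:
        pts = mesh.node_positions[crease]
        c0 = pts.mean(axis=0)
        # plane normal = direction of least variance of the crease nodes
        _, _, vt = np.linalg.svd(pts - c0)
        n = vt[-1]
        x_c = np.abs((centroids - c0) @ n)
    return x_s, x_c


def _point_triangle_distances(points, nodes, tris, chunk=2048):
    """Exact min distance from each point to a triangle soup (vectorised
    point-triangle projection)."""
    v0 = nodes[tris[:, 0]]
    v1 = nodes[tris[:, 1]]
    v2 = nodes[tris[:, 2]]
    out = np.empty(len(points))
    for s in range(0, len(points), chunk):
        p = points[s : s + chunk]
        d = _pt_tri_block(p, v0, v1, v2)
        out[s : s + chunk] = d
    return out


def _pt_tri_block(p, v0, v1, v2):
    # p: (np,3); v: (nt,3) -> (np,) min distance
    e0 = v1 - v0  # (nt,3)
    e1 = v2 - v0
    a = np.einsum("td,td->t", e0, e0)
    b = np.einsum("td,td->t", e0, e1)
    c = np.einsum("td,td->t", e1, e1)
    w = p[:, None, :] - v0[None, :, :]  # (np,nt,3)
    d = np.einsum("ptd,td->pt", w, e0)
    e = np.einsum("ptd,td->pt", w, e1)
    det = np.maximum(a * c - b * b, 1e-300)
    s = (c * d - b * e) / det
    t = (a * e - b * d) / det
    # clamp barycentric coordinates to the triangle
    s = np.clip(s, 0.0, 1.0)
    t = np.clip(t, 0.0, 1.0)
    over = s + t > 1.0
    if over.any():
        ssum = np.where(over, s + t, 1.0)
        s = np.where(over, s / ssum, s)
        t = np.where(over, t / ssum, t)
    # project edge-region cases properly: re-project onto each edge and take min
    proj = v0[None] + s[..., None] * e0[None] + t[..., None] * e1[None]
    d_face = np.linalg.norm(p[:, None, :] - proj, axis=2)
    d_min = d_face
    for q0, q1 in ((v0, v1), (v0, v2), (v1, v2)):
        eq = q1 - q0
        ln = np.einsum("td,td->t", eq, eq)
        tt = np.einsum("ptd,td->pt", p[:, None, :] - q0[None], eq) / np.maximum(ln, 1e-300)
        tt = np.clip(tt, 0.0, 1.0)
        pr = q0[None] + tt[..., None] * eq[None]
        d_min = np.minimum(d_min, np.linalg.norm(p[:, None, :] - pr, axis=2))
    return d_min.min(axis=1)


def validate_mesh(mesh: TetMesh) -> dict:
    """Diagnostic report: volumes, aspect ratios, node-set sizes, inverted
    tets.  Pure report; never raises."""
    vols = mesh.tet_volumes()
    inverted = np.flatnonzero(vols <= 0)
    x = mesh.node_positions[mesh.tets]
    edges = np.linalg.norm(
        x[:, [0, 0, 0, 1, 1, 2]] - x[:, [1, 2, 3, 2, 3, 3]], axis=2
    )
    lmax = edges.max(axis=1)
    # aspect ratio: longest edge / (inradius proxy 3V/avg-face-area)
    with np.errstate(divide="ignore", invalid="ignore"):
        aspect = lmax**3 / np.abs(vols) / 6.0
    return {
        "n_nodes": mesh.n_nodes,
        "n_tets": mesh.n_tets,
        "min_volume": float(vols.min()),
        "max_volume": float(vols.max()),
        "total_volume": float(np.abs(vols).sum()),
        "n_inverted": int(len(inverted)),
        "inverted_tets": inverted.tolist(),
        "aspect_ratio_median": float(np.median(aspect)),
        "aspect_ratio_max": float(aspect.max()),
        "spacing_a": mesh.spacing_a,
        "node_set_sizes": {k: int(len(v)) for k, v in mesh.node_sets.items()},
    }


def analytic_volume(params: GeometryParams) -> float:
    """Closed-form volume of the parametric solid (for construction checks)."""
    p = params
    T, L = p.thickness_T, p.boundary_length_L
    kind = Kind(p.kind)
    if kind is Kind.SEMICYLINDER:
        R = L / 2.0
        r0 = p.inner_hole_ratio * R
        return 0.5 * math.pi * (R**2 - r0**2) * T
    theta = math.radians(p.arc_angle_deg)
    if kind is Kind.CURVED_LOBE:
        R_in = L / theta
        R_out = R_in + p.lobe_extent * L
        return 0.5 * theta * (R_out**2 - R_in**2) * T
    if kind is Kind.BILAYER_FRILL:
        R_in = L / theta
        R_out = R_in + p.lobe_extent * L
        area = 0.5 * theta * (R_out**2 - R_in**2)
        return area * T * (1.0 + p.substrate_depth_ratio)
    if kind is Kind.FLAT_STRIP:
        length = p.strip_length_factor * T
        width = p.strip_width_cells * length / p.resolution[0]
        return length * width * T * (1.0 + p.substrate_depth_ratio)
    raise ValueError(kind)
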