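"""Neo-Hookean growth elasticity minimised by damped dynamic relaxation.

The body is a tetrahedral mesh in which each element carries a growth
tensor G.  The elastic deformation gradient F = A_def (G A_hat)^-1 maps the
stress-free grown element onto its deformed shape; frustrated growth makes
F != I even at equilibrium and stores the residual stress that drives the
ridge instability.  The strain energy density is

    W = (mu/2) [tr(F F^T) J^(-2/3) - 3] + (K/2)(J - 1)^2,  J = det F

with shear modulus mu and bulk modulus K = alpha mu,
alpha = (2 + 2 nu)/(3 - 6 nu).  Equilibria are found with damped
second-order dynamics on the nodes (explicit pseudo-time integration with
viscous damping reduced progressively), not with an implicit solver.

Internally stresses are normalised by the skin shear modulus and lengths
are mm; only stiffness ratios matter for the equilibrium shapes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import _kernels
from .geometry import Region, TetMesh
from .growth import ElementGrowth, GrowthSchedule, GrowthTargets, build_element_growth, evaluate_schedule

__all__ = [
    "Material",
    "SolverConfig",
    "SolverState",
    "NumericalError",
    "alpha_from_poisson",
    "strain_energy_density",
    "cauchy_stress",
    "assemble_nodal_forces",
    "apply_constraints",
    "relax_to_steady_state",
    "run_static_growth",
    "run_quasi_static",
    "materials_by_region",
]


class NumericalError(RuntimeError):
    """Inverted element or numerical blow-up during relaxation."""

    def __init__(self, message, tet_index=-1, iteration=-1):
        super().__init__(message)
        self.tet_index = tet_index
        self.iteration = iteration


def alpha_from_poisson(nu: float) -> float:
    """Bulk-to-shear factor alpha = (2 + 2 nu)/(3 - 6 nu)."""
    if not 0.0 <= nu < 0.5:
        raise ValueError("Poisson's ratio must lie in [0, 0.5)")
    return (2.0 + 2.0 * nu) / (3.0 - 6.0 * nu)


@dataclass(frozen=True)
class Material:
    """Isotropic neo-Hookean material (moduli in units of the skin shear
    modulus unless stated otherwise)."""

    mu: float = 1.0
    nu: float = 0.45

    @property
    def alpha(self) -> float:
        return alpha_from_poisson(self.nu)

    @property
    def K(self) -> float:
        return self.alpha * self.mu

    @property
    def young_E(self) -> float:
        return 2.0 * self.mu * (1.0 + self.nu)


def materials_by_region(
    mesh: TetMesh,
    skin: Material,
    substrate: Material | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-tet (mu, K) arrays from per-region materials."""
    mu = np.full(mesh.n_tets, skin.mu)
    K = np.full(mesh.n_tets, skin.K)
    if substrate is not None:
        sub = mesh.region_of_tet == int(Region.SUBSTRATE)
        mu[sub] = substrate.mu
        K[sub] = substrate.K
    elif (mesh.region_of_tet == int(Region.SUBSTRATE)).any():
        raise ValueError("mesh has a substrate region but no substrate material")
    return mu, K


def bilayer_materials(stiffness_ratio: float, nu: float = 0.45) -> tuple[Material, Material]:
    """Skin and substrate materials for a given skin-to-substrate stiffness
    ratio E_skin/E_substrate (equal Poisson ratios, so also mu_k/mu_s)."""
    if stiffness_ratio <= 0:
        raise ValueError("stiffness ratio must be positive")
    return Material(mu=1.0, nu=nu), Material(mu=1.0 / stiffness_ratio, nu=nu)


# ---------------------------------------------------------------------------
# pointwise constitutive functions (reference numpy implementations)


def strain_energy_density(F: np.ndarray, mu: float, K: float) -> float:
    """W(F); raises on det(F) <= 0."""
    F = np.asarray(F, dtype=float)
    J = np.linalg.det(F)
    if J <= 0.0:
        raise NumericalError(f"inverted deformation gradient (J={J:.3g})")
    trB = np.einsum("ij,ij->", F, F)
    return 0.5 * mu * (trB * J ** (-2.0 / 3.0) - 3.0) + 0.5 * K * (J - 1.0) ** 2


def cauchy_stress(F: np.ndarray, mu: float, K: float) -> np.ndarray:
    """sigma = (1/J) dW/dF F^T = mu J^(-5/3) dev(F F^T) + K (J - 1) I."""
    F = np.asarray(F, dtype=float)
    J = np.linalg.det(F)
    if J <= 0.0:
        raise NumericalError(f"inverted deformation gradient (J={J:.3g})")
    B = F @ F.T
    dev = B - np.trace(B) / 3.0 * np.eye(3)
    return mu * J ** (-5.0 / 3.0) * dev + K * (J - 1.0) * np.eye(3)


# ---------------------------------------------------------------------------
# element precomputation


def _reference_shape_inverses(mesh: TetMesh, growth: ElementGrowth):
    """(G A_hat)^-1 and grown reference volume per tet."""
    x = mesh.node_positions[mesh.tets]
    A_hat = np.swapaxes(x[:, 1:] - x[:, :1], 1, 2)  # columns x_i - x_0
    GA = np.einsum("mij,mjk->mik", growth.G_of_tet, A_hat)
    detGA = np.linalg.det(GA)
    if (detGA <= 0).any():
        raise NumericalError("growth tensor produced a degenerate element")
    invGA = np.linalg.inv(GA)
    vol_ref = np.linalg.det(A_hat) / 6.0
    volG = vol_ref * np.linalg.det(growth.G_of_tet)
    return np.ascontiguousarray(invGA), np.ascontiguousarray(volG)


# ---------------------------------------------------------------------------
# solver configuration and state

SINGLE_SHEET = "SINGLE_SHEET"
MULTI_LAYER = "MULTI_LAYER"


@dataclass
class SolverConfig:
    """Dynamic-relaxation settings.

    The time step is dt_factor * a / sqrt(K_max) (the stable explicit step
    scales as sqrt(mass/stiffness) with node mass a^3 and nodal stiffness
    ~ K a); the node mass is a^3 and the viscous damping gamma starts at
    gamma0_factor * mass, is halved whenever the energy decrease over the
    last window stalls, and is floored at gamma_min_factor * mass.
    Convergence requires the relative energy change over ``energy_window``
    iterations to fall below ``energy_rel_tol`` and the per-step node
    displacement below ``disp_tol * a``.
    """

    dt_factor: float = 0.01
    gamma0_factor: float = 10.0
    gamma_min_factor: float = 0.1
    mass_scaling: str = "uniform"  # "uniform" (m = a^3) or "stiffness"
    #: evaluate the volumetric term at the hex-cluster mean dilatation
    #: (mean-dilatation anti-locking); False = pointwise K(J-1) as printed
    volumetric_averaging: bool = False
    energy_window: int = 100_000
    energy_rel_tol: float = 0.001
    disp_tol: float = 1e-6
    max_iterations: int = 4_000_000
    check_every: int = 500
    perturbation_amplitude: float = 1e-3  # fraction of T
    rng_seed: int = 0
    sharpness: float = 100.0  # growth attenuation, mm^-1
    mode: str = SINGLE_SHEET

    def __post_init__(self) -> None:
        for name in ("dt_factor", "energy_rel_tol", "disp_tol"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def fast(cls, **overrides) -> "SolverConfig":
        """Desk-scale settings: near-stability time step and convergence
        windows sized for coarse meshes (a few thousand to a few tens of
        thousands of tets)."""
        defaults = dict(
            dt_factor=0.8,
            mass_scaling="uniform",
            volumetric_averaging=True,
            gamma0_factor=3.0,
            gamma_min_factor=1.0,
            energy_window=3000,
            energy_rel_tol=1e-3,
            disp_tol=2e-5,
            max_iterations=120_000,
            check_every=250,
        )
        defaults.update(overrides)
        return cls(**defaults)


@dataclass
class SolverState:
    """Nodal state of a relaxation run."""

    x: np.ndarray
    v: np.ndarray
    f: np.ndarray
    mesh: TetMesh = field(repr=False)
    energy_history: list = field(default_factory=list)  # (iteration, energy, max_disp)
    iterations: int = 0
    converged: bool = False
    total_energy: float = math.nan

    @classmethod
    def initial(cls, mesh: TetMesh) -> "SolverState":
        n = mesh.n_nodes
        return cls(
            x=mesh.node_positions.astype(np.float64).copy(),
            v=np.zeros((n, 3)),
            f=np.zeros((n, 3)),
            mesh=mesh,
        )

    def displacement(self) -> np.ndarray:
        return self.x - self.mesh.node_positions


def _constraint_arrays(mesh: TetMesh, mode: str):
    """Per-node constraint code and the constraint direction vector.

    Code 1: fixed (FIXED_INNER).  Code 2 (single sheet): crease nodes move
    only along the crease direction C.  Code 3 (multi layer): crease nodes
    lose the component normal to the crease plane.
    """
    if mode not in (SINGLE_SHEET, MULTI_LAYER):
        raise ValueError(f"unknown constraint mode {mode!r}")
    ctype = np.zeros(mesh.n_nodes, dtype=np.int8)
    crease = mesh.node_sets.get("CREASE", np.empty(0, dtype=np.int64))
    if len(crease):
        ctype[crease] = 2 if mode == SINGLE_SHEET else 3
    ctype[mesh.node_sets["FIXED_INNER"]] = 1
    if mode == SINGLE_SHEET:
        cdir = mesh.crease_direction.astype(np.float64)
    else:
        # blocked direction: the crease-plane normal (plane fitted to the
        # crease nodes; for the parametric lobes this is the x axis)
        if len(crease):
            pts = mesh.node_positions[crease]
            _, _, vt = np.linalg.svd(pts - pts.mean(axis=0))
            cdir = vt[-1].astype(np.float64)
        else:
            cdir = np.array([1.0, 0.0, 0.0])
    return ctype, np.ascontiguousarray(cdir)


def apply_constraints(state: SolverState, mesh: TetMesh, mode: str) -> None:
    """Project velocities and forces onto the admissible set in place."""
    ctype, cdir = _constraint_arrays(mesh, mode)
    for arr in (state.v, state.f):
        arr[ctype == 1] = 0.0
        sel = ctype == 2
        if sel.any():
            arr[sel] = np.outer(arr[sel] @ cdir, cdir)
        sel = ctype == 3
        if sel.any():
            arr[sel] -= np.outer(arr[sel] @ cdir, cdir)


def _cluster_array(mesh: TetMesh, config: SolverConfig | None) -> np.ndarray:
    """Volumetric-averaging clusters: parent hexes when enabled, one tet
    per cluster (pointwise J) otherwise."""
    if (
        config is not None
        and config.volumetric_averaging
        and mesh.cluster_of_tet is not None
    ):
        return np.ascontiguousarray(mesh.cluster_of_tet, dtype=np.int64)
    return np.arange(mesh.n_tets, dtype=np.int64)


def assemble_nodal_forces(
    state: SolverState,
    mesh: TetMesh,
    growth: ElementGrowth,
    materials: tuple[np.ndarray, np.ndarray],
    config: SolverConfig | None = None,
) -> np.ndarray:
    """Traction-based nodal forces at the current positions; also updates
    ``state.total_energy``.  Raises on inverted elements."""
    mu_el, K_el = materials
    invGA, volG = _reference_shape_inverses(mesh, growth)
    f = np.zeros_like(state.x)
    cluster = _cluster_array(mesh, config)
    nc = int(cluster.max()) + 1 if len(cluster) else 0
    energy, status, bad = _kernels.assemble_forces(
        state.x, mesh.tets, invGA, volG,
        np.ascontiguousarray(mu_el, dtype=np.float64),
        np.ascontiguousarray(K_el, dtype=np.float64),
        cluster, np.zeros(nc), np.zeros(nc),
        f,
    )
    if status == _kernels.STATUS_INVERTED:
        raise NumericalError("inverted element during assembly", tet_index=bad)
    if status == _kernels.STATUS_NAN:
        raise NumericalError("non-finite deformation during assembly", tet_index=bad)
    state.f = f
    state.total_energy = energy
    return f


def _mass_and_timestep(mesh: TetMesh, mu_el, K_el, config: SolverConfig):
    """Per-node inverse mass and pseudo-time step.

    ``uniform``: the node mass is a^3 (a = mean spacing) and the step is
    dt_factor * l_min / c with c the fastest wave speed -- l_min, the
    smallest edge (the through-thickness spacing on thin-sheet meshes),
    governs explicit stability.  ``stiffness``: each node's mass is its
    accumulated incident-element stiffness, which equalises nodal
    frequencies so dt becomes a dimensionless fraction of the uniform
    stability limit; equilibria are unaffected (mass only shapes the
    relaxation path).
    """
    x = mesh.node_positions[mesh.tets]
    edges = np.linalg.norm(
        x[:, [0, 0, 0, 1, 1, 2]] - x[:, [1, 2, 3, 2, 3, 3]], axis=2
    )
    stiff = K_el + (4.0 / 3.0) * mu_el
    if config.mass_scaling == "uniform":
        inv_m = np.full(mesh.n_nodes, 1.0 / mesh.spacing_a**3)
        c = math.sqrt(stiff.max())
        dt = config.dt_factor * float(edges.min()) / c
    elif config.mass_scaling == "stiffness":
        vols = np.abs(mesh.tet_volumes())
        s_e = stiff * vols / edges.min(axis=1) ** 2
        k_node = np.zeros(mesh.n_nodes)
        np.add.at(k_node, mesh.tets.ravel(), np.repeat(s_e / 4.0, 4))
        k_node = np.maximum(k_node, 1e-300)
        inv_m = 1.0 / k_node
        dt = config.dt_factor
    else:
        raise ValueError(f"unknown mass_scaling {config.mass_scaling!r}")
    return np.ascontiguousarray(inv_m), dt


def _perturb(state: SolverState, mesh: TetMesh, config: SolverConfig) -> None:
    from .synthetic_data import make_perturbation

    if config.perturbation_amplitude <= 0:
        return
    disp = make_perturbation(
        mesh, amplitude=config.perturbation_amplitude, seed=config.rng_seed
    )
    state.x += disp


def relax_to_steady_state(
    state: SolverState,
    mesh: TetMesh,
    growth: ElementGrowth,
    materials: tuple[np.ndarray, np.ndarray],
    config: SolverConfig,
    perturb: bool = True,
) -> SolverState:
    """Integrate damped second-order dynamics until the elastic energy
    stabilises.

    Convergence: relative energy change over ``energy_window`` iterations
    below ``energy_rel_tol`` and max per-step displacement below
    ``disp_tol * spacing_a``.  The damping factor starts at
    gamma0_factor * m and is halved whenever the window shows no further
    energy decrease.  A NaN or inverted element triggers a restart of the
    current chunk from the last checkpoint with a halved time step.
    """
    mu_el, K_el = materials
    mu_el = np.ascontiguousarray(mu_el, dtype=np.float64)
    K_el = np.ascontiguousarray(K_el, dtype=np.float64)
    invGA, volG = _reference_shape_inverses(mesh, growth)
    ctype, cdir = _constraint_arrays(mesh, config.mode)

    a = mesh.spacing_a
    inv_m, dt = _mass_and_timestep(mesh, mu_el, K_el, config)
    gamma_over_m = config.gamma0_factor
    gamma_min = config.gamma_min_factor

    if perturb and state.iterations == 0:
        _perturb(state, mesh, config)
        state.x[ctype == 1] = mesh.node_positions[ctype == 1]

    x = np.ascontiguousarray(state.x)
    v = np.ascontiguousarray(state.v)
    f = np.zeros_like(x)
    tets = np.ascontiguousarray(mesh.tets)

    cluster = _cluster_array(mesh, config)
    nc = int(cluster.max()) + 1
    jbar_num = np.zeros(nc)
    jbar_den = np.zeros(nc)

    chunk = int(config.check_every)
    window = max(int(config.energy_window), chunk)
    history = state.energy_history
    e0, status, bad = _kernels.assemble_forces(
        x, tets, invGA, volG, mu_el, K_el, cluster, jbar_num, jbar_den, f
    )
    if status != _kernels.STATUS_OK:
        raise NumericalError("invalid initial configuration", tet_index=bad)
    history.append((state.iterations, e0, math.nan))

    it = 0
    converged = False
    x_ck, v_ck = x.copy(), v.copy()
    dt_halvings = 0
    while it < config.max_iterations:
        energy, max_disp, status, bad = _kernels.relax_chunk(
            x, v, f, tets, invGA, volG, mu_el, K_el,
            cluster, jbar_num, jbar_den,
            ctype, cdir, inv_m, dt, gamma_over_m, chunk,
        )
        if status != _kernels.STATUS_OK:
            if dt_halvings >= 12:
                raise NumericalError(
                    "relaxation diverged despite repeated time-step halving",
                    tet_index=bad,
                    iteration=state.iterations + it,
                )
            dt *= 0.5
            dt_halvings += 1
            x[:] = x_ck
            v[:] = 0.0
            continue
        x_ck[:] = x
        v_ck[:] = v
        it += chunk
        history.append((state.iterations + it, energy, max_disp))

        # energy change over the last `window` iterations
        span = max(window // chunk, 1)
        if len(history) > span:
            e_then = history[-1 - span][1]
            scale = max(abs(energy), abs(e0), 1e-300)
            rel = abs(energy - e_then) / scale
            if rel < config.energy_rel_tol and max_disp < config.disp_tol * a:
                converged = True
                break
            # damping reduced progressively once the window stops making
            # significant progress at the current gamma
            if rel < 10.0 * config.energy_rel_tol and gamma_over_m > gamma_min:
                gamma_over_m = max(gamma_over_m * 0.5, gamma_min)

    state.x = x
    state.v = v
    state.f = f
    state.iterations += it
    state.converged = converged
    state.total_energy = history[-1][1]
    if not converged:
        tail = [h[1] for h in history[-5:]]
        raise NumericalError(
            f"no convergence after {it} iterations (energy tail {tail})",
            iteration=state.iterations,
        )
    return state


def element_fields(
    state: SolverState,
    mesh: TetMesh,
    growth: ElementGrowth,
    materials: tuple[np.ndarray, np.ndarray],
) -> dict:
    """Per-tet J = det(F) and strain energy density W at the current
    positions (for checkpoint export)."""
    mu_el, K_el = materials
    invGA, _ = _reference_shape_inverses(mesh, growth)
    x = state.x[mesh.tets]
    A_def = np.swapaxes(x[:, 1:] - x[:, :1], 1, 2)
    F = np.einsum("mij,mjk->mik", A_def, invGA)
    J = np.linalg.det(F)
    trB = np.einsum("mij,mij->m", F, F)
    with np.errstate(invalid="ignore"):
        W = 0.5 * mu_el * (trB * np.sign(J) * np.abs(J) ** (-2.0 / 3.0) - 3.0) + 0.5 * K_el * (J - 1.0) ** 2
    return {"J": J, "W": W}


def run_static_growth(
    mesh: TetMesh,
    targets: GrowthTargets,
    materials: tuple[np.ndarray, np.ndarray],
    config: SolverConfig,
    depth_fields=None,
):
    """Apply the full growth at once, relax, and measure the outcome.

    Returns (state, RidgeReport).
    """
    from .morphometrics import ridge_report

    growth = build_element_growth(
        mesh, targets, depth_fields=depth_fields, sharpness=config.sharpness
    )
    state = SolverState.initial(mesh)
    relax_to_steady_state(state, mesh, growth, materials, config)
    return state, ridge_report(state, mesh)


def run_quasi_static(
    mesh: TetMesh,
    schedule: GrowthSchedule,
    materials: tuple[np.ndarray, np.ndarray],
    config: SolverConfig,
    n_steps: int = 20,
    depth_fields=None,
    taus=None,
):
    """Grow incrementally along the developmental schedule, re-relaxing at
    every step from the previous equilibrium.

    ``taus`` overrides the default equally spaced grid on (0, 1].
    Returns a list of (tau, state_snapshot, RidgeReport); the state is the
    same object relaxed in place, snapshotted by position copy.
    """
    from .geometry import compute_depth_fields
    from .morphometrics import ridge_report

    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    if depth_fields is None and not schedule.uniform:
        depth_fields = compute_depth_fields(mesh)
    if taus is None:
        taus = np.linspace(0.0, 1.0, n_steps + 1)[1:]
    taus = np.asarray(taus, dtype=float)
    if np.any(taus <= 0) or np.any(taus > 1) or np.any(np.diff(taus) <= 0):
        raise ValueError("taus must be increasing within (0, 1]")
    state = SolverState.initial(mesh)
    _perturb(state, mesh, config)
    ctype, _ = _constraint_arrays(mesh, config.mode)
    state.x[ctype == 1] = mesh.node_positions[ctype == 1]
    trajectory = []
    for tau in taus:
        targets = evaluate_schedule(schedule, float(tau))
        growth = build_element_growth(
            mesh, targets, depth_fields=depth_fields, sharpness=config.sharpness
        )
        relax_to_steady_state(state, mesh, growth, materials, config, perturb=False)
        report = ridge_report(state, mesh)
        snap = replace(
            state,
            x=state.x.copy(),
            v=state.v.copy(),
            f=state.f.copy(),
            energy_history=list(state.energy_history),
        )
        trajectory.append((float(tau), snap, report))
    return trajectory
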