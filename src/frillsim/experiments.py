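"""Canonical desk-scale experiments.

Each function runs one of the package's standard study conditions end to
end at the default desk-scale resolution and returns plain dictionaries of
measured quantities.  Both the test suite and ``scripts/acceptance.py``
drive these; resolutions here are the package's reference problem sizes
(see docs/methods.md).
"""

from __future__ import annotations

import math

import numpy as np

from .fem_core import (
    Material,
    SolverConfig,
    SolverState,
    bilayer_materials,
    materials_by_region,
    relax_to_steady_state,
    run_quasi_static,
    run_static_growth,
)
from .geometry import GeometryParams, Kind, build_mesh, compute_depth_fields
from .growth import GrowthSchedule, GrowthTargets, build_element_growth
from .morphometrics import analytic_wavelength, measured_wavelength, ridge_report
from .synthetic_data import get_preset

__all__ = [
    "single_sheet_ramp",
    "pdms_pleats",
    "bilayer_static",
    "bilayer_ratio_sweep",
    "strip_wavelength",
    "semicylinder_growth_sweep",
    "semicylinder_thickness_sweep",
]


def _lobe_mesh(resolution=(22, 44)):
    preset = get_preset("lobe_single_sheet")
    return build_mesh(preset.geometry_params(resolution=resolution))


def single_sheet_ramp(
    seed: int = 0,
    resolution=(28, 56),
    g_final: float = 1.28,
    g_steps=(1.05, 1.10, 1.15, 1.20, 1.28),
    measure_at=(1.10, 1.20, 1.28),
):
    """Quasi-static homogeneous growth of the curved lobe (T/L = 0.014,
    nu = 0.45, crease growing with the surface).

    Returns ridge counts along the ramp and at the requested growth
    factors, picking the nearest visited step for each.
    """
    mesh = _lobe_mesh(resolution)
    materials = materials_by_region(mesh, Material(mu=1.0, nu=0.45))
    config = SolverConfig.fast(rng_seed=seed, mode="SINGLE_SHEET")
    schedule = GrowthSchedule(
        crease_equals_surface=True, uniform=True, final_g_surface=g_final
    )
    taus = [(g - 1.0) / (g_final - 1.0) for g in g_steps]
    trajectory = run_quasi_static(
        mesh, schedule, materials, config, taus=taus
    )
    gs = [1.0 + (g_final - 1.0) * tau for tau, _, _ in trajectory]
    counts = [rep.ridge_count for _, _, rep in trajectory]
    at = {}
    for g in measure_at:
        i = int(np.argmin([abs(gv - g) for gv in gs]))
        at[round(g, 3)] = counts[i]
    _, final_state, final_report = trajectory[-1]
    return {
        "g_values": gs,
        "ridge_counts": counts,
        "counts_at": at,
        "final_report": final_report,
        "final_state": final_state,
        "mesh": mesh,
    }


def pdms_pleats(seed: int = 0, resolution=(16, 40), n_steps: int = 4):
    """Swelling PDMS analog: semicylindrical sheet, T/L = 0.01, grown
    uniformly by 1.3 (30% linear swelling)."""
    preset = get_preset("pdms_analog")
    mesh = build_mesh(preset.geometry_params(resolution=resolution))
    materials = materials_by_region(mesh, Material(mu=1.0, nu=0.45))
    config = SolverConfig.fast(rng_seed=seed, mode="SINGLE_SHEET")
    schedule = GrowthSchedule(uniform=True, final_g_surface=1.3)
    trajectory = run_quasi_static(mesh, schedule, materials, config, n_steps=n_steps)
    _, state, report = trajectory[-1]
    return {"report": report, "state": state, "mesh": mesh}


def bilayer_static(
    stiffness_ratio: float = 100.0,
    seed: int = 0,
    resolution=(16, 32),
    g_surface: float = 1.3,
    g_crease: float = 2.2,
    substrate_depth_ratio: float = 10.0,
    n_steps: int = 4,
):
    """Bilayer frill lobe grown quasi-statically to the stage-E32 growth
    factors at a given skin-to-substrate stiffness ratio."""
    preset = get_preset("bilayer_ratio_sweep")
    mesh = build_mesh(
        preset.geometry_params(
            resolution=resolution, substrate_depth_ratio=substrate_depth_ratio
        )
    )
    skin, sub = bilayer_materials(stiffness_ratio, nu=0.45)
    materials = materials_by_region(mesh, skin, sub)
    config = SolverConfig.fast(rng_seed=seed, mode="MULTI_LAYER")
    schedule = GrowthSchedule(final_g_surface=g_surface)
    if g_crease != 2.2:
        # quadratic ramp rescaled to the requested endpoint
        schedule = GrowthSchedule(
            final_g_surface=g_surface,
            crease_coeffs=(1.0, (g_crease - 1.0) * 1.65 / 1.2, (g_crease - 1.0) * -0.45 / 1.2),
        )
    trajectory = run_quasi_static(mesh, schedule, materials, config, n_steps=n_steps)
    _, state, report = trajectory[-1]
    return {
        "report": report,
        "state": state,
        "mesh": mesh,
        "trajectory_counts": [r.ridge_count for _, _, r in trajectory],
    }


def bilayer_ratio_sweep(ratios=(20.0, 100.0, 2000.0), seed: int = 0, **kw):
    """Ridge counts across skin-to-substrate stiffness ratios."""
    out = {}
    for ratio in ratios:
        out[ratio] = bilayer_static(stiffness_ratio=ratio, seed=seed, **kw)
    return out


def strip_wavelength(
    stiffness_ratio: float,
    seed: int = 0,
    spacing_over_T: float = 0.5,
    wavelengths_long: float = 4.0,
    overstrains=(0.8, 1.5, 2.3),
    film_layers: int = 3,
):
    """Flat stiff-film-on-substrate strip: measured wrinkle wavelength vs
    the analytic lambda = 2 pi T (mu_k/(3 mu_s))^(1/3).

    Film growth along the strip axis is stepped across the onset strain
    eps_c = 0.25 (3 mu_s/mu_k)^(2/3) (``overstrains`` are multiples of
    eps_c), stopping shortly above onset where the wrinkle train still
    carries the onset-selected wavelength (deep post-buckling coarsens
    it).  The strip is sized to the analytic wavelength so the interior
    fits several wrinkles clear of the pinned ends.  The measured mean
    and SD come from the surface peak spacings.
    """
    T = 0.047
    lam = analytic_wavelength(T, stiffness_ratio, 1.0)
    eps_c = 0.25 * (3.0 / stiffness_ratio) ** (2.0 / 3.0)
    length_factor = max(50.0, wavelengths_long * lam / T)
    n_x = int(round(length_factor / spacing_over_T))
    params = GeometryParams(
        kind=Kind.FLAT_STRIP,
        thickness_T=T,
        boundary_length_L=length_factor * T,
        resolution=(n_x, 2),
        through_thickness_layers=film_layers,
        substrate_depth_ratio=max(8.0, 0.5 * lam / T),
        substrate_layers=5,
        strip_length_factor=length_factor,
        strip_width_cells=2,
    )
    mesh = build_mesh(params)
    skin, sub = bilayer_materials(stiffness_ratio, nu=0.45)
    materials = materials_by_region(mesh, skin, sub)
    config = SolverConfig.fast(
        rng_seed=seed, mode="MULTI_LAYER", disp_tol=6e-5, max_iterations=200_000
    )
    depth_fields = compute_depth_fields(mesh)
    state = SolverState.initial(mesh)
    from .fem_core import _constraint_arrays, _perturb

    _perturb(state, mesh, config)
    ctype, _ = _constraint_arrays(mesh, config.mode)
    state.x[ctype == 1] = mesh.node_positions[ctype == 1]
    from .growth import ElementGrowth, logistic_attenuation

    x_s, _ = depth_fields
    C = mesh.crease_direction
    for over in overstrains:
        g = 1.0 + over * eps_c
        # uniaxial film growth along the strip axis, attenuated with depth
        # below the film exactly like the tangential growth of the frill
        g_loc = logistic_attenuation(float(g), x_s, T)
        G = np.eye(3)[None] + (g_loc - 1.0)[:, None, None] * np.outer(C, C)[None]
        growth = ElementGrowth(
            G_of_tet=G, g_s_local=np.ones_like(g_loc), g_c_local=g_loc,
            targets=GrowthTargets(g_surface=float(g), uniform=False),
        )
        relax_to_steady_state(state, mesh, growth, materials, config, perturb=False)
    mean, sd, band_means = measured_wavelength(state, mesh)
    return {
        "measured_mean_mm": mean,
        "measured_sd_mm": sd,
        "band_means_mm": band_means,
        "analytic_mm": analytic_wavelength(T, stiffness_ratio, 1.0),
        "state": state,
        "mesh": mesh,
    }


def _semicylinder_run(thickness_T, g, seed, resolution=(12, 30), n_steps=3):
    params = GeometryParams(
        kind=Kind.SEMICYLINDER,
        thickness_T=thickness_T,
        boundary_length_L=1.0,
        resolution=resolution,
        through_thickness_layers=2,
    )
    mesh = build_mesh(params)
    materials = materials_by_region(mesh, Material(mu=1.0, nu=0.45))
    config = SolverConfig.fast(rng_seed=seed, mode="SINGLE_SHEET")
    schedule = GrowthSchedule(uniform=True, final_g_surface=g)
    trajectory = run_quasi_static(mesh, schedule, materials, config, n_steps=n_steps)
    _, state, report = trajectory[-1]
    return report


def semicylinder_growth_sweep(gs=(1.05, 1.1, 1.2, 1.3), seed: int = 0, **kw):
    """Ridge counts of the T/L = 0.02 semicylindrical sheet across uniform
    growth factors."""
    return {g: _semicylinder_run(0.02, g, seed, **kw) for g in gs}


def semicylinder_thickness_sweep(ratios=(0.01, 0.02, 0.04), g=1.2, seed: int = 0, **kw):
    """Ridge counts at fixed growth g = 1.2 across relative thickness."""
    return {t: _semicylinder_run(t, g, seed, **kw) for t in ratios}
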