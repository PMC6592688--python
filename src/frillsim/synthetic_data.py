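"""Synthetic inputs: perturbations, fixture surfaces, indentation
profiles, and named scenario presets.

Everything the analysis consumes is generated here or by the geometry
module; no external data files are needed.  All randomness flows through
explicit integer seeds.
"""

from __future__ import annotations

import math
import tomllib
from dataclasses import dataclass
from importlib import resources

import numpy as np

from .geometry import GeometryParams, Kind, TetMesh, build_mesh
from .indentation import DepthProfile, TwoLayerFit, two_layer_modulus

__all__ = [
    "ScenarioPreset",
    "make_perturbation",
    "make_fixture_surface",
    "make_scaled_state",
    "make_indentation_profile",
    "list_presets",
    "get_preset",
]


@dataclass
class ScenarioPreset:
    """Self-contained description of one simulation scenario."""

    name: str
    description: str
    expected: str
    geometry: dict
    growth: dict
    material: dict
    solver: dict
    sweep: dict | None = None
    schedule: dict | None = None

    def geometry_params(self, **overrides) -> GeometryParams:
        kw = dict(self.geometry)
        kw.update(overrides)
        if "resolution" in kw:
            kw["resolution"] = tuple(kw["resolution"])
        return GeometryParams(**kw)


def make_perturbation(mesh: TetMesh, amplitude: float, seed: int) -> np.ndarray:
    """Seeded symmetry-breaking nodal displacement field.

    Uniform random surface-normal (z) offsets scaled so the largest
    magnitude equals ``amplitude * T``; exactly zero on FIXED_INNER and
    CREASE nodes.  Without it the discretised symmetric problem can stall
    on an unstable unbuckled branch.
    """
    if not 0.0 < amplitude <= 0.01:
        raise ValueError("perturbation amplitude must be in (0, 0.01]")
    rng = np.random.default_rng(seed)
    disp = np.zeros((mesh.n_nodes, 3))
    disp[:, 2] = rng.uniform(-1.0, 1.0, mesh.n_nodes)
    for name in ("FIXED_INNER", "CREASE"):
        nodes = mesh.node_sets.get(name)
        if nodes is not None and len(nodes):
            disp[nodes] = 0.0
    peak = np.abs(disp[:, 2]).max()
    if peak > 0:
        disp *= amplitude * mesh.thickness_T / peak
    return disp


class _FixtureState:
    """Minimal stand-in for a converged solver state (synthetic surface)."""

    def __init__(self, x: np.ndarray):
        self.x = x
        self.converged = True


def make_fixture_surface(
    n_ridges: int,
    amplitude: float,
    wavelength: float | None = None,
    params: GeometryParams | None = None,
):
    """Lobe mesh carrying ``n_ridges`` synthetic radial sinusoidal ridges.

    The normal displacement is A cos(2 pi n theta/Theta - pi), which has
    exactly ``n_ridges`` interior maxima of equal amplitude along every
    band; peak-to-trough amplitude is 2A.  When ``wavelength`` is given it
    sets the angular period via the mid-band radius instead of
    ``n_ridges``.  Returns (state, mesh).
    """
    if n_ridges < 0:
        raise ValueError("n_ridges must be >= 0")
    if params is None:
        params = GeometryParams(
            kind=Kind.CURVED_LOBE,
            thickness_T=0.047,
            boundary_length_L=0.047 / 0.014,
            resolution=(20, 60),
            through_thickness_layers=2,
        )
    mesh = build_mesh(params)
    theta_max = math.radians(params.arc_angle_deg)
    rad = np.linalg.norm(mesh.node_positions[:, :2], axis=1)
    r_mid = 0.5 * (rad.min() + rad.max())
    if wavelength is not None:
        if wavelength < 4.0 * mesh.spacing_a:
            raise ValueError("wavelength below 4 node spacings is unresolvable")
        n_eff = theta_max * r_mid / wavelength
    else:
        n_eff = float(n_ridges)
    x = mesh.node_positions.copy()
    if n_eff > 0:
        theta = np.arctan2(x[:, 0], x[:, 1])
        x[:, 2] += amplitude * np.cos(2.0 * math.pi * n_eff * theta / theta_max - math.pi)
    return _FixtureState(x), mesh


def make_scaled_state(mesh: TetMesh, s: float) -> "_FixtureState":
    """State with the in-plane coordinates uniformly scaled by ``s``
    (fixture for the realized-growth measure)."""
    x = mesh.node_positions.copy()
    x[:, 0] *= s
    x[:, 1] *= s
    return _FixtureState(x)


def make_indentation_profile(
    fit: TwoLayerFit,
    depths,
    noise_cv: float = 0.05,
    seed: int = 0,
    skin_thickness_um: float = 47.0,
) -> DepthProfile:
    """Noisy synthetic depth profile from the two-layer modulus model.

    Noise is multiplicative lognormal with unit mean and coefficient of
    variation ``noise_cv`` (moduli are positive and span decades).
    """
    if not 0.0 <= noise_cv <= 0.5:
        raise ValueError("noise_cv must be in [0, 0.5]")
    depths = np.asarray(depths, dtype=float)
    E = two_layer_modulus(depths, skin_thickness_um, fit)
    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        sigma = math.sqrt(math.log(1.0 + noise_cv**2))
        noise = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=len(depths))
        E = E * noise
    return DepthProfile(
        depths_um=depths, moduli_pa=E, skin_thickness_um=skin_thickness_um
    )


# ---------------------------------------------------------------------------
# scenario presets

_PRESETS_CACHE: dict | None = None


def _load_presets() -> dict:
    global _PRESETS_CACHE
    if _PRESETS_CACHE is None:
        text = resources.files("frillsim").joinpath("presets/presets.toml").read_text()
        raw = tomllib.loads(text)
        _PRESETS_CACHE = {
            name: ScenarioPreset(
                name=name,
                description=entry.get("description", ""),
                expected=entry.get("expected", ""),
                geometry=entry.get("geometry", {}),
                growth=entry.get("growth", {}),
                material=entry.get("material", {}),
                solver=entry.get("solver", {}),
                sweep=entry.get("sweep"),
                schedule=entry.get("schedule"),
            )
            for name, entry in raw.items()
        }
    return _PRESETS_CACHE


def list_presets() -> list[ScenarioPreset]:
    """All shipped scenario presets."""
    return list(_load_presets().values())


def get_preset(name: str) -> ScenarioPreset:
    presets = _load_presets()
    if name not in presets:
        raise KeyError(
            f"unknown preset {name!r}; available: {', '.join(sorted(presets))}"
        )
    return presets[name]
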