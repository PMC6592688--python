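"""Per-element growth tensors and the quasi-static growth schedule.

Growth is prescribed, not mechanosensitive: each tetrahedron carries a
growth tensor G = Gs . Gc where

    Gs = g_s I + (1 - g_s) N N^T      (isotropic expansion g_s in the plane
                                       perpendicular to the surface normal N)
    Gc = I + (g_c - 1) C C^T          (expansion g_c along the crease
                                       direction C)

The local factors g_s, g_c attenuate with depth below the anterior surface
(g_s) and distance from the crease plane (g_c) through a generalised
logistic, so that the skin sheet grows at the target rate while the
substrate stays near 1.  Incompatible ("frustrated") growth of this kind
generates the residual stress that buckles the sheet.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import TetMesh, compute_depth_fields

__all__ = [
    "GrowthTargets",
    "GrowthSchedule",
    "ElementGrowth",
    "logistic_attenuation",
    "element_growth_tensor",
    "build_element_growth",
    "evaluate_schedule",
    "default_frill_schedule",
]

#: steepness of the skin-substrate growth transition, mm^-1, with all
#: lengths in mm; the transition half-width around depth T is ~10 um.
DEFAULT_SHARPNESS = 100.0


@dataclass
class GrowthTargets:
    """Target growth factors, relative to the fixed neck-boundary length.

    ``g_surface`` is the tangential (in-plane) expansion of the skin sheet,
    ``g_crease`` the expansion of the central crease along C, and
    ``g_outer`` the free-edge growth (1.0: the rim does not grow more than
    the sheet).  ``uniform`` marks single-sheet runs in which the whole
    sheet grows homogeneously at ``g_surface`` with no depth attenuation
    and no separate crease term.
    """

    g_surface: float = 1.3
    g_crease: float = 2.2
    g_outer: float = 1.0
    crease_equals_surface: bool = False
    uniform: bool = False

    def __post_init__(self) -> None:
        if self.crease_equals_surface:
            self.g_crease = self.g_surface
        if self.g_surface < 1.0 or self.g_crease < 1.0:
            raise ValueError("growth factors below 1 (resorption) are not modelled")


@dataclass
class GrowthSchedule:
    """Developmental growth ramps on normalised time tau in [0, 1].

    tau = 0 corresponds to the smooth-frill stage (E23) and tau = 1 to the
    three-ridge stage (E32).  The surface ramp is linear and the crease
    ramp quadratic, each pinned to the measured anchors.
    """

    surface_coeffs: tuple = (1.0, 0.3)  # g_s(tau) = 1 + 0.3 tau
    crease_coeffs: tuple = (1.0, 1.65, -0.45)  # g_c(tau) = 1 + 1.65 tau - 0.45 tau^2
    anchors: tuple = (((0.0, 1.0), (1.0, 1.3)), ((0.0, 1.0), (1 / 3, 1.5), (1.0, 2.2)))
    crease_equals_surface: bool = False
    uniform: bool = False
    final_g_surface: float | None = None  # rescale the linear ramp endpoint

    def g_surface_of_t(self, tau: float) -> float:
        a, b = self.surface_coeffs
        if self.final_g_surface is not None:
            b = self.final_g_surface - a
        return a + b * tau

    def g_crease_of_t(self, tau: float) -> float:
        a, b, c = self.crease_coeffs
        return a + b * tau + c * tau * tau


def default_frill_schedule(**kw) -> GrowthSchedule:
    return GrowthSchedule(**kw)


def evaluate_schedule(schedule: GrowthSchedule, tau: float) -> GrowthTargets:
    """Growth targets at normalised developmental time ``tau``."""
    if not 0.0 <= tau <= 1.0:
        raise ValueError(f"tau={tau} outside [0, 1]")
    g_s = schedule.g_surface_of_t(tau)
    if schedule.crease_equals_surface:
        g_c = g_s
    else:
        g_c = schedule.g_crease_of_t(tau)
    return GrowthTargets(
        g_surface=g_s,
        g_crease=g_c,
        crease_equals_surface=schedule.crease_equals_surface,
        uniform=schedule.uniform,
    )


def logistic_attenuation(g_target, x_i, T, sharpness=DEFAULT_SHARPNESS):
    """Depth-attenuated local growth factor.

    g_i = 1 + (g_target - 1) / (1 + 0.25 exp(-sharpness (T - x_i)))

    At the surface (x_i = 0, deep transition T >> 1/sharpness) g_i is
    essentially g_target; one thickness below the transition it has decayed
    to 1.  Monotone nonincreasing in x_i, bounded in [1, g_target].
    """
    g_target = np.asarray(g_target, dtype=float)
    x_i = np.asarray(x_i, dtype=float)
    if np.any(g_target < 1.0):
        raise ValueError("g_target < 1 (resorption) is not modelled")
    if np.any(x_i < 0):
        raise ValueError("distances must be nonnegative")
    if T <= 0 or sharpness <= 0:
        raise ValueError("T and sharpness must be positive")
    # exp argument is clipped only on the overflow side; underflow -> g = 1
    arg = np.clip(-sharpness * (T - x_i), -745.0, 745.0)
    g = 1.0 + (g_target - 1.0) / (1.0 + 0.25 * np.exp(arg))
    return g if g.ndim else float(g)


def element_growth_tensor(g_s_local: float, g_c_local: float, N, C) -> np.ndarray:
    """G = Gs . Gc for one element; identity when both factors are 1."""
    N = np.asarray(N, dtype=float)
    C = np.asarray(C, dtype=float)
    if abs(np.linalg.norm(N) - 1.0) > 1e-9 or abs(np.linalg.norm(C) - 1.0) > 1e-9:
        raise ValueError("N and C must be unit vectors")
    I = np.eye(3)
    Gs = g_s_local * I + (1.0 - g_s_local) * np.outer(N, N)
    Gc = I + (g_c_local - 1.0) * np.outer(C, C)
    return Gs @ Gc


@dataclass
class ElementGrowth:
    """Per-tet growth tensors with the attenuated local factors."""

    G_of_tet: np.ndarray  # (m, 3, 3)
    g_s_local: np.ndarray  # (m,)
    g_c_local: np.ndarray  # (m,)
    targets: GrowthTargets = None

    def det(self) -> np.ndarray:
        return np.linalg.det(self.G_of_tet)


def build_element_growth(
    mesh: TetMesh,
    targets: GrowthTargets,
    depth_fields=None,
    sharpness: float = DEFAULT_SHARPNESS,
) -> ElementGrowth:
    """Assemble per-tet growth tensors for a mesh.

    In ``uniform`` mode (single homogeneous sheet) every element receives
    the full tangential expansion ``g_surface`` and no crease term; the
    crease, being part of the sheet, then grows at the same rate as the
    surface.  Otherwise both factors attenuate with the element's depth
    below the anterior surface (x_s) and its distance from the crease
    plane (x_c).
    """
    m = mesh.n_tets
    T = mesh.thickness_T
    if targets.uniform:
        g_s = np.full(m, targets.g_surface)
        g_c = np.ones(m)
    else:
        if depth_fields is None:
            depth_fields = compute_depth_fields(mesh)
        x_s, x_c = depth_fields
        g_s = logistic_attenuation(targets.g_surface, x_s, T, sharpness)
        with np.errstate(over="ignore"):
            finite = np.isfinite(x_c)
            g_c = np.ones(m)
            if finite.any() and targets.g_crease > 1.0:
                g_c[finite] = logistic_attenuation(
                    targets.g_crease, x_c[finite], T, sharpness
                )

    N = mesh.reference_normal_of_tet
    C = mesh.crease_direction
    I = np.eye(3)
    NN = np.einsum("mi,mj->mij", N, N)
    Gs = g_s[:, None, None] * I + (1.0 - g_s)[:, None, None] * NN
    Gc = I[None] + (g_c - 1.0)[:, None, None] * np.outer(C, C)[None]
    G = np.einsum("mij,mjk->mik", Gs, Gc)
    return ElementGrowth(G_of_tet=G, g_s_local=g_s, g_c_local=g_c, targets=targets)
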