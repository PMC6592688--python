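"""Two-layer depth-dependent Young's modulus model for nanoindentation.

An indenter probing a stiff skin sheet of thickness T on a much softer
substrate reads an apparent modulus that decays from E_skin at vanishing
depth to E_substrate at depths well beyond T:

    E(d) = E_substrate (E_skin / E_substrate)^M,
    M    = 1 / (1 + A (d/T)^B)

with positive mixing coefficients A, B.  The mixing exponent is usually
written L in the indentation literature; it is called ``mixing_exponent``
here to avoid colliding with the boundary length L of the mechanics
modules.  Fits are performed in log-modulus
space (the moduli span ~2 decades) independently at each skin thickness of
a plausible range; reported parameters are means across the range with the
spread as uncertainty.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "DepthProfile",
    "TwoLayerFit",
    "two_layer_modulus",
    "mixing_exponent",
    "fit_two_layer",
    "stiffness_ratio",
    "DEFAULT_THICKNESS_RANGE",
]

#: skin-thickness range (um) spanned by the depth-profile fits
DEFAULT_THICKNESS_RANGE = (27.0, 72.0)


@dataclass
class DepthProfile:
    """Depth-dependent apparent Young's modulus measurements."""

    depths_um: np.ndarray
    moduli_pa: np.ndarray
    skin_thickness_um: float = 47.0

    def __post_init__(self) -> None:
        self.depths_um = np.asarray(self.depths_um, dtype=float)
        self.moduli_pa = np.asarray(self.moduli_pa, dtype=float)
        if self.depths_um.ndim != 1 or self.depths_um.shape != self.moduli_pa.shape:
            raise ValueError("depths and moduli must be 1-d arrays of equal length")
        if np.any(np.diff(self.depths_um) <= 0) or np.any(self.depths_um <= 0):
            raise ValueError("depths must be strictly increasing and positive")
        if np.any(self.moduli_pa <= 0):
            raise ValueError("moduli must be positive")


@dataclass
class TwoLayerFit:
    """Fitted two-layer modulus parameters with across-thickness spread."""

    E_skin: float
    E_substrate: float
    coeff_A: float
    coeff_B: float
    uncertainty: dict = field(default_factory=dict)  # parameter -> spread (SD)
    thickness_range_um: tuple = DEFAULT_THICKNESS_RANGE
    per_thickness: list = field(default_factory=list)

    @property
    def stiffness_ratio(self) -> float:
        return self.E_skin / self.E_substrate

    def to_dict(self) -> dict:
        return {
            "E_skin_pa": self.E_skin,
            "E_substrate_pa": self.E_substrate,
            "coeff_A": self.coeff_A,
            "coeff_B": self.coeff_B,
            "stiffness_ratio": self.stiffness_ratio,
            "stiffness_ratio_rounded": round(self.stiffness_ratio),
            "uncertainty": self.uncertainty,
            "thickness_range_um": list(self.thickness_range_um),
        }


def mixing_exponent(d, T, A, B):
    """M = 1 / (1 + A (d/T)^B); 1 at the surface, -> 0 at great depth."""
    d = np.asarray(d, dtype=float)
    if T <= 0:
        raise ValueError("T must be positive")
    if A <= 0 or B <= 0:
        raise ValueError("A and B must be positive")
    return 1.0 / (1.0 + A * (d / T) ** B)


def two_layer_modulus(d, T, fit: TwoLayerFit):
    """Apparent modulus E(d) of the skin-on-substrate system (Pa)."""
    if fit.E_skin <= 0 or fit.E_substrate <= 0:
        raise ValueError("moduli must be positive")
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("depths must be nonnegative")
    M = mixing_exponent(d, T, fit.coeff_A, fit.coeff_B)
    E = fit.E_substrate * (fit.E_skin / fit.E_substrate) ** M
    return E if E.ndim else float(E)


_MULTISTART_AB = [(a, b) for a in (0.5, 1.0, 2.0) for b in (0.5, 1.0, 2.0)]


def _fit_at_thickness(d, logE, T):
    """Least squares on log E at one skin thickness, multi-started over
    (A, B).  Parameters are log-transformed to enforce positivity."""
    lo = logE.min()
    hi = logE.max()

    def residual(q):
        lEs, lEsub, lA, lB = q
        with np.errstate(over="ignore"):
            M = 1.0 / (1.0 + math.exp(min(lA, 500.0)) * (d / T) ** math.exp(min(lB, 6.0)))
        return lEsub + (lEs - lEsub) * M - logE

    best = None
    for A0, B0 in _MULTISTART_AB:
        q0 = np.array([hi, lo, math.log(A0), math.log(B0)])
        try:
            res = least_squares(residual, q0, method="lm", max_nfev=4000)
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise RuntimeError("two-layer fit failed at every start")
    lEs, lEsub, lA, lB = best.x
    return {
        "T_um": T,
        "E_skin": math.exp(lEs),
        "E_substrate": math.exp(lEsub),
        "coeff_A": math.exp(lA),
        "coeff_B": math.exp(lB),
        "cost": float(best.cost),
    }


def fit_two_layer(
    profile: DepthProfile,
    thickness_range=DEFAULT_THICKNESS_RANGE,
    n_thickness: int = 10,
) -> TwoLayerFit:
    """Fit the two-layer model over a range of plausible skin thicknesses.

    The skin thickness is not identifiable from a depth profile alone
    (A and T trade off), so the model is fitted independently at each T of
    a grid across ``thickness_range``; the reported parameters are the
    means across the grid and the uncertainties their standard deviations.
    """
    d = profile.depths_um
    if len(d) < 6:
        raise ValueError("need at least 6 depth points")
    logE = np.log(profile.moduli_pa)
    t_lo, t_hi = thickness_range
    if not (0 < t_lo <= t_hi):
        raise ValueError("invalid thickness range")
    if not (d.min() < t_hi and d.max() > 3.0 * t_lo):
        import warnings

        warnings.warn(
            "depth profile does not span both asymptotic regimes; "
            "expect wide uncertainties",
            stacklevel=2,
        )
    ts = np.linspace(t_lo, t_hi, n_thickness) if n_thickness > 1 else [0.5 * (t_lo + t_hi)]
    fits = [_fit_at_thickness(d, logE, float(T)) for T in ts]
    keys = ("E_skin", "E_substrate", "coeff_A", "coeff_B")
    mean = {k: float(np.mean([f[k] for f in fits])) for k in keys}
    spread = {k: float(np.std([f[k] for f in fits], ddof=1)) if len(fits) > 1 else 0.0 for k in keys}
    return TwoLayerFit(
        E_skin=mean["E_skin"],
        E_substrate=mean["E_substrate"],
        coeff_A=mean["coeff_A"],
        coeff_B=mean["coeff_B"],
        uncertainty=spread,
        thickness_range_um=tuple(thickness_range),
        per_thickness=fits,
    )


def stiffness_ratio(fit: TwoLayerFit) -> tuple[float, int]:
    """E_skin / E_substrate, raw and rounded to the nearest integer."""
    r = fit.stiffness_ratio
    return r, round(r)
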