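"""Hill-type contractile machinery: individual force-length curves,
force-velocity constants, and force potentials.

The force-length relation is an individual concave quadratic fitted to MVC
data; its vertex defines the optimal fascicle length L_0 and the maximum
force F_max. The force-velocity relation is the classic Hill hyperbola with
normalized constants a_rel and b_rel, where

    a_rel = 0.1 + 0.4 * FT        (FT = fast-twitch fiber fraction)
    b_rel = a_rel * V_max         (V_max in optimal lengths per second)

A *potential* is the fraction of maximal force available at the current
fascicle length (force-length potential) or shortening velocity
(force-velocity potential); their product is the overall
force-length-velocity potential.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import FitError, ValidationError
from .traces import LeverArm

__all__ = [
    "ForceLengthCurve",
    "MuscleParameters",
    "fit_force_length",
    "tendon_force",
    "a_rel_from_ft",
    "b_rel_from",
    "derive_vmax",
    "fl_potential",
    "fv_potential",
    "flv_potential",
    "SOLEUS_VMAX_NORM",
    "VL_VMAX_NORM",
    "SOLEUS_FT",
    "VL_FT",
    "SOLEUS_A_REL",
    "VL_A_REL",
    "SOLEUS_B_REL",
    "VL_B_REL",
]

# Published reference constants for the two muscles studied. V_max values
# are in vitro fiber velocities adjusted to 37 degC and the average fiber
# type distribution (soleus: 19 % fast-twitch, vastus lateralis: 63 %).
# The printed a_rel/b_rel are shipped verbatim so results can be reproduced
# exactly despite rounding in the source (the formula path gives 0.176 /
# 0.352 and products 1.185 / 4.040).
SOLEUS_VMAX_NORM = 6.77  # L_0/s
VL_VMAX_NORM = 11.51  # L_0/s
SOLEUS_FT = 0.19
VL_FT = 0.63
SOLEUS_A_REL = 0.175
VL_A_REL = 0.351
SOLEUS_B_REL = 1.182  # L_0/s
VL_B_REL = 4.042  # L_0/s


def a_rel_from_ft(ft: float) -> float:
    """Hill constant a_rel from the fast-twitch fiber fraction: 0.1 + 0.4 FT."""
    if not (0.0 <= ft <= 1.0):
        raise ValidationError("fast-twitch fraction must lie in [0, 1]")
    return 0.1 + 0.4 * ft


def b_rel_from(a_rel: float, vmax_norm: float) -> float:
    """Hill constant b_rel (L_0/s) as the product a_rel * V_max."""
    if a_rel < 0 or vmax_norm <= 0:
        raise ValidationError("a_rel must be >= 0 and V_max positive")
    return a_rel * vmax_norm


def derive_vmax(
    type1_v: float, type2_v: float, type1_frac: float, temp_factor: float = 1.0
) -> float:
    """Representative V_max from fiber-type velocities.

    Weighted mean of slow (type 1) and fast (type 2) fiber maximal
    shortening velocities, scaled by a temperature adjustment factor to
    physiological conditions. The packaged defaults produced by this route
    are ``SOLEUS_VMAX_NORM`` and ``VL_VMAX_NORM``.
    """
    if not (0.0 <= type1_frac <= 1.0):
        raise ValidationError("type-1 fraction must lie in [0, 1]")
    if type1_v <= 0 or type2_v <= 0 or temp_factor <= 0:
        raise ValidationError("velocities and temperature factor must be positive")
    return temp_factor * (type1_frac * type1_v + (1.0 - type1_frac) * type2_v)


@dataclass(frozen=True)
class ForceLengthCurve:
    """Concave quadratic force-fascicle length relation.

    force(L) = c2*L^2 + c1*L + c0 with c2 < 0; the vertex is (L_0, F_max).
    ``extrapolated_vertex`` flags fits whose vertex falls outside the fitted
    length range extended by 20 % on each side (suspect but not rejected).
    """

    c2: float
    c1: float
    c0: float
    fit_range_mm: tuple[float, float]
    extrapolated_vertex: bool = False

    @property
    def L0_mm(self) -> float:
        return -self.c1 / (2.0 * self.c2)

    @property
    def Fmax_N(self) -> float:
        return self.c0 - self.c1**2 / (4.0 * self.c2)

    def force(self, length_mm):
        """Force in N at the given fascicle length(s) in mm (unclipped)."""
        L = np.asarray(length_mm, dtype=float)
        out = self.c2 * L**2 + self.c1 * L + self.c0
        return float(out) if np.ndim(length_mm) == 0 else out


def fit_force_length(lengths_mm, forces_N) -> ForceLengthCurve:
    """Least-squares quadratic fit of tendon force against fascicle length.

    Raises :class:`FitError` when the fit is not concave (c2 >= 0), which
    admits no force optimum. A vertex outside the fitted length range
    (extended by +/-20 % of its span) sets ``extrapolated_vertex``.
    """
    L = np.asarray(lengths_mm, dtype=float)
    F = np.asarray(forces_N, dtype=float)
    if L.shape != F.shape or L.ndim != 1:
        raise ValidationError("lengths and forces must be 1-D and equal length")
    if np.unique(L).size < 3:
        raise ValidationError("force-length fit needs >= 3 distinct lengths")
    c2, c1, c0 = np.polyfit(L, F, 2)
    lo, hi = float(L.min()), float(L.max())
    span = hi - lo
    # numerically flat curvature (e.g. collinear samples) is as unusable as
    # a convex one: no force optimum exists
    c2_floor = 1e-9 * (np.max(np.abs(F)) + 1.0) / span**2
    if c2 >= -c2_floor:
        raise FitError("force-length fit is not concave (c2 >= 0)")
    vertex = -c1 / (2 * c2)
    extrap = not (lo - 0.2 * span <= vertex <= hi + 0.2 * span)
    return ForceLengthCurve(float(c2), float(c1), float(c0), (lo, hi), extrap)


def tendon_force(moment_Nm: float, lever: LeverArm, angle_deg: float = 0.0) -> float:
    """Tendon force (N) as joint moment divided by the tendon lever arm."""
    r_mm = lever(angle_deg)
    if not (r_mm > 0):
        raise ValidationError("lever arm must be positive")
    return moment_Nm / (r_mm / 1000.0)


@dataclass(frozen=True)
class MuscleParameters:
    """Parameter set of one muscle for the Hill-type model.

    ``a_rel`` and ``b_rel`` default to the formula values 0.1 + 0.4 FT and
    a_rel * V_max; pass explicit values to use published rounded constants.
    """

    name: str
    L0_mm: float
    Fmax_N: float
    ft: float
    vmax_norm: float  # L_0/s
    a_rel: float = field(default=None)  # type: ignore[assignment]
    b_rel: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.L0_mm <= 0 or self.Fmax_N <= 0 or self.vmax_norm <= 0:
            raise ValidationError("L0, Fmax and V_max must be positive")
        if self.a_rel is None:
            object.__setattr__(self, "a_rel", a_rel_from_ft(self.ft))
        if self.b_rel is None:
            object.__setattr__(self, "b_rel", b_rel_from(self.a_rel, self.vmax_norm))
        if self.a_rel <= 0 or self.b_rel <= 0:
            raise ValidationError("a_rel and b_rel must be positive")

    @property
    def vmax_abs_mm_s(self) -> float:
        """Absolute maximal shortening velocity in mm/s (V_max * L_0)."""
        return self.vmax_norm * self.L0_mm

    @classmethod
    def soleus(cls, L0_mm: float = 41.3, Fmax_N: float = 2887.0) -> "MuscleParameters":
        """Soleus defaults with the published rounded Hill constants."""
        return cls("soleus", L0_mm, Fmax_N, SOLEUS_FT, SOLEUS_VMAX_NORM,
                   a_rel=SOLEUS_A_REL, b_rel=SOLEUS_B_REL)

    @classmethod
    def vastus_lateralis(cls, L0_mm: float = 94.0, Fmax_N: float = 4990.0) -> "MuscleParameters":
        """Vastus lateralis defaults with the published rounded Hill constants."""
        return cls("vastus_lateralis", L0_mm, Fmax_N, VL_FT, VL_VMAX_NORM,
                   a_rel=VL_A_REL, b_rel=VL_B_REL)

    def with_vmax_factor(self, factor: float) -> "MuscleParameters":
        """Scaled-V_max copy for sensitivity analysis.

        a_rel is unchanged; b_rel is re-derived as a_rel * (factor * V_max).
        """
        if factor <= 0:
            raise ValidationError("V_max factor must be positive")
        return MuscleParameters(
            self.name, self.L0_mm, self.Fmax_N, self.ft,
            self.vmax_norm * factor, a_rel=self.a_rel,
            b_rel=self.b_rel * factor,
        )


def fl_potential(length_mm, curve: ForceLengthCurve):
    """Force-length potential F(L)/F_max, clipped to [0, 1]."""
    f = curve.force(length_mm)
    return np.clip(np.asarray(f) / curve.Fmax_N, 0.0, 1.0) if np.ndim(length_mm) else float(
        min(max(f / curve.Fmax_N, 0.0), 1.0)
    )


def fv_potential(v_norm, params: MuscleParameters, eccentric: str = "clamp"):
    """Force-velocity potential from the Hill hyperbola.

    Parameters
    ----------
    v_norm
        Fascicle velocity in L_0/s, *shortening positive*.
    eccentric
        Policy for lengthening (v < 0): ``"clamp"`` returns 1.0 (no
        eccentric force enhancement assumed); ``"hyperbola"`` uses a
        mirrored eccentric branch 1.3 - 0.3 * (b - a*w)/(b + w) with
        w = -v, which is 1 at v = 0 and saturates at 1.3 + 0.3 a_rel.

    For 0 <= v <= V_max the value is (b_rel - a_rel*v)/(b_rel + v), which is
    1 at v = 0 and 0 at v = V_max (b_rel = a_rel * V_max); beyond V_max the
    potential is floored at 0.
    """
    v = np.asarray(v_norm, dtype=float)
    a, b = params.a_rel, params.b_rel
    conc = np.clip((b - a * v) / (b + v), 0.0, None)
    conc = np.where(v >= params.vmax_norm, 0.0, conc)
    if eccentric == "clamp":
        ecc = np.ones_like(v)
    elif eccentric == "hyperbola":
        w = -v
        ecc = 1.3 - 0.3 * (b - a * w) / (b + w)
    else:
        raise ValidationError(f"unknown eccentric policy: {eccentric!r}")
    out = np.where(v >= 0, conc, ecc)
    return float(out) if np.ndim(v_norm) == 0 else out


def flv_potential(fl, fv):
    """Overall force-length-velocity potential: the product of the two."""
    fl = np.asarray(fl, dtype=float)
    fv = np.asarray(fv, dtype=float)
    if np.any(fl < 0) or np.any(fl > 1) or np.any(fv < 0):
        raise ValidationError("potentials must be non-negative (fl in [0, 1])")
    out = fl * fv
    return float(out) if out.ndim == 0 else out
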