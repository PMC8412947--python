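"""Enthalpy efficiency as a function of normalized shortening velocity.

Enthalpy efficiency (eta) is the fraction of liberated chemical energy
converted into mechanical work. Classic whole-muscle experiments report it
against the *relative load* p = P/P_0; to use it with measured fascicle
velocities the table is transposed to normalized shortening velocity via
the Hill force-velocity relation,

    v/V_max = (1 - p) / (1 + p / (a/P_0)),

and interpolated with a natural cubic spline anchored at eta(0) = 0 (no
load, no work) and eta(1) = 0 (no shortening at V_max... more precisely
zero work at zero *force*), giving the familiar right-skewed curve with a
single interior maximum near 0.18 V/V_max.

The packaged reference table (``data/load_efficiency_a025_synthetic.csv``)
is a synthetic reconstruction of the classic a/P_0 = 0.25 load-efficiency
experiment, regenerated by :func:`synthesize_load_efficiency_table`; see
that function for the underlying energetics model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .contractile import MuscleParameters
from .errors import ValidationError

__all__ = [
    "LoadEfficiencyTable",
    "EfficiencyCurve",
    "load_to_velocity",
    "build_efficiency_curve",
    "evaluate_efficiency",
    "synthesize_load_efficiency_table",
    "reference_load_efficiency_table",
    "reference_efficiency_curve",
]

_FIXTURE = "load_efficiency_a025_synthetic.csv"


@dataclass(frozen=True)
class LoadEfficiencyTable:
    """Rows of (relative load p = P/P_0, enthalpy efficiency eta)."""

    relative_load: np.ndarray
    efficiency: np.ndarray
    a_over_p0: float

    def __post_init__(self) -> None:
        p = np.asarray(self.relative_load, dtype=float)
        e = np.asarray(self.efficiency, dtype=float)
        if p.shape != e.shape or p.ndim != 1:
            raise ValidationError("load and efficiency columns must match")
        if not np.all(np.diff(p) > 0):
            raise ValidationError("relative loads must be strictly increasing")
        if np.any(p < 0) or np.any(p > 1) or np.any(e < 0):
            raise ValidationError("loads must lie in [0, 1] and efficiencies be >= 0")
        if not (self.a_over_p0 > 0):
            raise ValidationError("a/P_0 must be positive")
        object.__setattr__(self, "relative_load", p)
        object.__setattr__(self, "efficiency", e)


def load_to_velocity(p, a_over_p0: float):
    """Transpose relative load to normalized shortening velocity.

    From the Hill relation (P + a)(v + b) = (P_0 + a) b with
    V_max = b P_0 / a:  v/V_max = (1 - p) / (1 + p / (a/P_0)).
    """
    if not (a_over_p0 > 0):
        raise ValidationError("a/P_0 must be positive")
    p_arr = np.asarray(p, dtype=float)
    if np.any(p_arr < 0) or np.any(p_arr > 1):
        raise ValidationError("relative load must lie in [0, 1]")
    out = (1.0 - p_arr) / (1.0 + p_arr / a_over_p0)
    return float(out) if np.ndim(p) == 0 else out


@dataclass(frozen=True)
class EfficiencyCurve:
    """Spline of enthalpy efficiency over normalized shortening velocity.

    Evaluation clamps negative spline excursions to 0 and returns 0 outside
    [0, 1]. ``peak_velocity``/``peak_efficiency`` locate the single interior
    maximum, found on a 0.001-resolution grid.
    """

    v_knots: np.ndarray
    eta_knots: np.ndarray
    peak_velocity: float
    peak_efficiency: float
    _spline: CubicSpline = field(repr=False, compare=False)

    def __call__(self, v_norm):
        v = np.asarray(v_norm, dtype=float)
        out = np.clip(self._spline(v), 0.0, None)
        # exact zeros at and beyond the anchors (v <= 0: no shortening, no
        # work; v >= 1: no force, no work)
        out = np.where((v <= 0.0) | (v >= 1.0), 0.0, out)
        return float(out) if np.ndim(v_norm) == 0 else out

    def sample(self, n: int = 1001) -> pd.DataFrame:
        """The curve sampled on a uniform velocity grid, for export/plots."""
        v = np.linspace(0.0, 1.0, n)
        return pd.DataFrame({"v_norm": v, "efficiency": self(v)})


def build_efficiency_curve(table: LoadEfficiencyTable) -> EfficiencyCurve:
    """Transpose a load-efficiency table to velocity and fit a cubic spline.

    Anchor points (0, 0) and (1, 0) are appended before fitting so the
    curve vanishes at zero velocity (no work) and at V_max (no force).
    """
    if table.relative_load.size < 4:
        raise ValidationError("need at least 4 table rows to build the curve")
    v = load_to_velocity(table.relative_load, table.a_over_p0)
    order = np.argsort(v)
    v_all = np.concatenate(([0.0], v[order], [1.0]))
    e_all = np.concatenate(([0.0], table.efficiency[order], [0.0]))
    v_knots, idx = np.unique(np.round(v_all, 12), return_index=True)
    eta_knots = e_all[idx]
    spline = CubicSpline(v_knots, eta_knots, bc_type="natural")
    grid = np.arange(0.0, 1.0 + 1e-12, 0.001)
    vals = np.clip(spline(grid), 0.0, None)
    k = int(np.argmax(vals))
    return EfficiencyCurve(v_knots, eta_knots, float(grid[k]), float(vals[k]), spline)


def evaluate_efficiency(
    v_l0s, params: MuscleParameters, curve: EfficiencyCurve
):
    """Enthalpy efficiency at a fascicle velocity in L_0/s (shortening positive).

    Isometric or lengthening states (v <= 0) and velocities at/above V_max
    produce no positive mechanical work, hence efficiency 0.
    """
    v = np.asarray(v_l0s, dtype=float)
    out = np.where(v <= 0.0, 0.0, curve(v / params.vmax_norm))
    return float(out) if np.ndim(v_l0s) == 0 else out


def synthesize_load_efficiency_table(
    a_over_p0: float = 0.25,
    loads: np.ndarray | None = None,
) -> LoadEfficiencyTable:
    """Synthetic reconstruction of the classic load-efficiency experiment.

    Models steady shortening against relative load p with Hill energetics:
    velocity from the force-velocity hyperbola (constant a/P_0, V_max
    normalized to 1 so b = a/P_0), and

        eta(p) = work rate / (work + shortening heat + maintenance heat)
               = p v / (p v + (0.16 + 0.18 p) v + a b)

    using the load-dependent shortening-heat coefficient 0.16 + 0.18 p and
    a maintenance-heat rate of a*b. This stands in for the historical
    whole-muscle measurements (not printed in modern sources) and
    reproduces their published summary: peak efficiency about 0.45 near
    0.18 V/V_max once splined.
    """
    if loads is None:
        loads = np.arange(0.0, 1.0 + 1e-12, 0.05)
    p = np.asarray(loads, dtype=float)
    a = a_over_p0
    b = a  # V_max = 1
    v = a * (1.0 - p) / (p + a)
    work = p * v
    heat = (0.16 + 0.18 * p) * v + a * b
    eta = work / (work + heat)
    return LoadEfficiencyTable(p, np.round(eta, 6), a_over_p0)


def _parse_fixture(text: str) -> LoadEfficiencyTable:
    a_over_p0 = None
    for line in text.splitlines():
        if line.startswith("#") and "a_over_P0" in line:
            a_over_p0 = float(line.split("=")[1])
    if a_over_p0 is None:
        raise ValidationError("fixture is missing the a_over_P0 metadata line")
    from io import StringIO

    df = pd.read_csv(StringIO(text), comment="#")
    return LoadEfficiencyTable(df["p"].to_numpy(), df["eta"].to_numpy(), a_over_p0)


def reference_load_efficiency_table() -> LoadEfficiencyTable:
    """The packaged synthetic a/P_0 = 0.25 load-efficiency table."""
    text = resources.files("mtulab.data").joinpath(_FIXTURE).read_text()
    return _parse_fixture(text)


def reference_efficiency_curve() -> EfficiencyCurve:
    """Efficiency-velocity curve built from the packaged reference table."""
    return build_efficiency_curve(reference_load_efficiency_table())
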