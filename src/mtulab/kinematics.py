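"""Stance-event detection, MTU/belly length reconstruction, differentiation,
and time normalization onto the stance grid.

Conventions
-----------
* Joint angles are in degrees; increasing angle is the direction that
  lengthens the MTU (ankle dorsiflexion for the plantar flexors, knee
  flexion for the knee extensors).
* Length traces are in mm; derivatives keep the raw sign (d length / dt),
  so shortening gives negative velocity. The Hill-model and efficiency
  layers negate at their boundary (shortening-positive convention there).
* The stance grid has 101 points, 0..100 % stance inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import EventDetectionError, ValidationError
from .traces import LeverArm, TimeSeriesTrace

__all__ = [
    "StanceWindow",
    "STANCE_GRID",
    "stance_average",
    "detect_stance",
    "mtu_length",
    "belly_length",
    "differentiate",
    "time_normalize",
]

#: Percent-of-stance abscissa shared by all normalized curves.
STANCE_GRID = np.linspace(0.0, 100.0, 101)


def stance_average(grid_values) -> float:
    """Stance average of a 101-point grid curve.

    Composite trapezoid over the inclusive 0..100 % grid, i.e. the uniform
    grid mean with the two endpoint samples half-weighted. This is the
    discrete time average of the underlying signal (second-order accurate);
    a plain arithmetic mean over-weights the endpoints by O(1/n).
    """
    y = np.asarray(grid_values, dtype=float)
    if y.size < 2:
        raise ValidationError("need at least two grid points to average")
    return float(np.trapezoid(y, dx=1.0) / (y.size - 1))


@dataclass(frozen=True)
class StanceWindow:
    """Sample indices of foot touchdown and toe-off within a trace."""

    touchdown_index: int
    toeoff_index: int

    def __post_init__(self) -> None:
        if not (0 <= self.touchdown_index < self.toeoff_index):
            raise ValidationError("touchdown index must precede toe-off index")

    def duration(self, sample_rate: float) -> float:
        """Stance duration in seconds."""
        return (self.toeoff_index - self.touchdown_index) / sample_rate


def _local_minima(x: np.ndarray) -> list[int]:
    # Strict on the left, non-strict on the right: the first sample of a
    # flat valley is the minimum.
    return [
        i
        for i in range(1, len(x) - 1)
        if x[i] < x[i - 1] and x[i] <= x[i + 1]
    ]


def detect_stance(knee_angle: TimeSeriesTrace) -> StanceWindow:
    """Identify touchdown and toe-off as consecutive knee-angle minima.

    Among all pairs of consecutive local minima, the pair bracketing the
    largest intervening knee-flexion excursion (peak angle above the higher
    of the two minima) is returned; during stance the knee flexes and
    re-extends, producing exactly this signature.
    """
    x = knee_angle.values
    if len(x) < 3:
        raise EventDetectionError("trace too short for event detection")
    minima = _local_minima(x)
    if len(minima) < 2:
        raise EventDetectionError("fewer than two knee-angle minima found")
    best, best_exc = None, -np.inf
    for i, j in zip(minima[:-1], minima[1:]):
        exc = float(np.max(x[i : j + 1]) - max(x[i], x[j]))
        if exc > best_exc:
            best, best_exc = (i, j), exc
    return StanceWindow(*best)


def mtu_length(
    joint_angle: TimeSeriesTrace, lever: LeverArm, initial_length_mm: float
) -> TimeSeriesTrace:
    """Reconstruct MTU length from joint-angle changes and the tendon lever arm.

    Each angle increment (converted to radians) is multiplied by the lever
    arm — evaluated at the interval midpoint angle when angle-dependent —
    and accumulated onto the initial length:

        L_MTU(t) = L_init + sum r(phi_mid) * dphi

    Only the length *changes* are physically meaningful; the offset is the
    caller-supplied initial length.
    """
    if not (initial_length_mm > 0):
        raise ValidationError("initial MTU length must be positive")
    phi = joint_angle.values
    lever(phi)  # range check against an angle-dependent table
    dphi = np.diff(phi) * np.pi / 180.0
    mid = 0.5 * (phi[:-1] + phi[1:])
    r = lever(mid)
    dL = np.atleast_1d(r) * dphi if np.ndim(r) else r * dphi
    out = initial_length_mm + np.concatenate(([0.0], np.cumsum(dL)))
    return joint_angle.with_values(out, units="mm")


def belly_length(
    fascicle: TimeSeriesTrace, pennation: TimeSeriesTrace, initial_length_mm: float
) -> TimeSeriesTrace:
    """Belly length changes from the fascicle projection onto the MTU line.

    Accumulates differences of consecutive products L_fascicle * cos(beta).
    This tracks belly length *changes* (the projection of the fascicle onto
    the MTU plane), not the anatomical length of the whole belly; the
    absolute offset is the caller-supplied initial length.
    """
    if not fascicle.same_time_base(pennation):
        raise ValidationError("fascicle and pennation traces must share a time base")
    beta = pennation.values
    if np.any(beta < 0) or np.any(beta >= 90):
        raise ValidationError("pennation angle must lie in [0, 90) degrees")
    proj = fascicle.values * np.cos(np.deg2rad(beta))
    out = initial_length_mm + (proj - proj[0])
    return fascicle.with_values(out, units="mm")


def differentiate(trace: TimeSeriesTrace) -> TimeSeriesTrace:
    """First time derivative: central differences inside, one-sided at the ends.

    Units become input-units per second. The sign is kept raw (shortening
    of a length trace is negative); downstream muscle-model code negates
    where a shortening-positive velocity is required.
    """
    if len(trace) < 3:
        raise ValidationError("need at least 3 samples to differentiate")
    v = np.gradient(trace.values, trace.dt, edge_order=1)
    units = f"{trace.units}/s" if trace.units else "1/s"
    return trace.with_values(v, units=units)


def time_normalize(trace: TimeSeriesTrace, window: StanceWindow) -> np.ndarray:
    """Resample the stance window onto the 101-point percent-stance grid.

    Linear interpolation in sample-index space; the touchdown and toe-off
    samples map exactly onto 0 % and 100 %.
    """
    i, j = window.touchdown_index, window.toeoff_index
    if j >= len(trace):
        raise ValidationError("stance window exceeds trace length")
    xp = np.arange(i, j + 1, dtype=float)
    xq = np.linspace(i, j, 101)
    return np.interp(xq, xp, trace.values[i : j + 1])
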