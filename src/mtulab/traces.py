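"""Core containers: uniformly sampled time series and tendon lever arms."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import LeverRangeError, ValidationError

__all__ = ["TimeSeriesTrace", "LeverArm"]


@dataclass
class TimeSeriesTrace:
    """A uniformly sampled scalar signal.

    Parameters
    ----------
    values
        Sample values. Stored as a float64 array; must be finite.
    sample_rate
        Sampling frequency in Hz (> 0).
    units
        Physical units of the samples (informational, propagated by
        operations where meaningful).
    t0
        Time of the first sample in seconds.
    """

    values: np.ndarray
    sample_rate: float
    units: str = ""
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size == 0:
            raise ValidationError("trace values must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("trace values must be finite")
        if not (self.sample_rate > 0):
            raise ValidationError("sample_rate must be positive")

    def __len__(self) -> int:
        return self.values.size

    @property
    def dt(self) -> float:
        return 1.0 / self.sample_rate

    @property
    def time(self) -> np.ndarray:
        """Sample times in seconds."""
        return self.t0 + np.arange(self.values.size) / self.sample_rate

    def with_values(self, values: np.ndarray, units: str | None = None) -> "TimeSeriesTrace":
        """A new trace on the same time base with different values."""
        return TimeSeriesTrace(values, self.sample_rate, self.units if units is None else units, self.t0)

    def same_time_base(self, other: "TimeSeriesTrace") -> bool:
        return (
            len(self) == len(other)
            and np.isclose(self.sample_rate, other.sample_rate)
            and np.isclose(self.t0, other.t0)
        )


@dataclass
class LeverArm:
    """A tendon lever arm, either constant or a function of joint angle.

    Angle-dependent arms are supplied as a strictly increasing table of
    (joint angle in degrees, lever arm in mm) and interpolated linearly;
    evaluation outside the tabulated range raises :class:`LeverRangeError`.
    """

    kind: str  # "constant" | "angle_dependent"
    value_mm: float | None = None
    angles_deg: np.ndarray | None = field(default=None, repr=False)
    values_mm: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.kind == "constant":
            if self.value_mm is None or not (self.value_mm > 0):
                raise ValidationError("constant lever arm must be positive")
        elif self.kind == "angle_dependent":
            a = np.asarray(self.angles_deg, dtype=float)
            v = np.asarray(self.values_mm, dtype=float)
            if a.ndim != 1 or a.size < 2 or a.shape != v.shape:
                raise ValidationError("lever table needs >= 2 (angle, mm) pairs")
            if not np.all(np.diff(a) > 0):
                raise ValidationError("lever table angles must be strictly increasing")
            if not np.all(v > 0):
                raise ValidationError("lever arm values must be positive")
            self.angles_deg, self.values_mm = a, v
        else:
            raise ValidationError(f"unknown lever arm kind: {self.kind!r}")

    @classmethod
    def constant(cls, value_mm: float) -> "LeverArm":
        return cls(kind="constant", value_mm=float(value_mm))

    @classmethod
    def from_table(cls, angles_deg: Sequence[float], values_mm: Sequence[float]) -> "LeverArm":
        return cls(kind="angle_dependent", angles_deg=np.asarray(angles_deg), values_mm=np.asarray(values_mm))

    def __call__(self, angle_deg):
        """Lever arm in mm at the given joint angle(s) in degrees."""
        if self.kind == "constant":
            return self.value_mm * np.ones_like(np.asarray(angle_deg, dtype=float)) if np.ndim(angle_deg) else self.value_mm
        a = np.asarray(angle_deg, dtype=float)
        lo, hi = self.angles_deg[0], self.angles_deg[-1]
        if np.any(a < lo) or np.any(a > hi):
            raise LeverRangeError(
                f"joint angle outside lever-arm table range [{lo}, {hi}] deg"
            )
        out = np.interp(a, self.angles_deg, self.values_mm)
        return float(out) if np.ndim(angle_deg) == 0 else out
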