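"""Velocity-decoupling coefficients between MTU, muscle belly, and fascicles.

At each percent of stance the decoupling coefficients are absolute velocity
differences normalized by the muscle's absolute maximal shortening velocity:

    DC_Tendon(t) = |V_MTU(t) - V_Belly(t)|    / V_max   (tendon compliance)
    DC_Belly(t)  = |V_Belly(t) - V_Fascicle(t)| / V_max (fascicle rotation)
    DC_MTU(t)    = |V_MTU(t) - V_Fascicle(t)|  / V_max  (overall decoupling)

They replace classic gearing ratios (V_MTU/V_Belly etc.), which blow up
when the denominator velocity passes through zero during walking/running;
:func:`gearing_ratios` is provided for comparison with such samples masked.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .kinematics import stance_average

__all__ = [
    "DecouplingProfile",
    "decoupling_profile",
    "gearing_ratios",
    "write_profile",
    "read_profile",
    "stance_averaged_dc",
]


@dataclass(frozen=True)
class DecouplingProfile:
    """DC curves on the stance grid plus their stance averages.

    Averages are trapezoidal grid means (endpoints half-weighted), i.e.
    discrete time averages over stance.
    """

    dc_tendon: np.ndarray
    dc_belly: np.ndarray
    dc_mtu: np.ndarray

    @property
    def mean_tendon(self) -> float:
        return stance_average(self.dc_tendon)

    @property
    def mean_belly(self) -> float:
        return stance_average(self.dc_belly)

    @property
    def mean_mtu(self) -> float:
        return stance_average(self.dc_mtu)


def decoupling_profile(
    v_mtu, v_belly, v_fascicle, vmax_abs_mm_s: float
) -> DecouplingProfile:
    """Decoupling coefficients from same-grid velocity sequences in mm/s.

    All three sequences must share a length (normally the 101-point stance
    grid) and ``vmax_abs_mm_s`` must be the *absolute* maximal shortening
    velocity (V_max in L_0/s times L_0 in mm) so units cancel.
    """
    vm = np.asarray(v_mtu, dtype=float)
    vb = np.asarray(v_belly, dtype=float)
    vf = np.asarray(v_fascicle, dtype=float)
    if not (vm.shape == vb.shape == vf.shape) or vm.ndim != 1:
        raise ValidationError("velocity sequences must be 1-D and equal length")
    if not (vmax_abs_mm_s > 0):
        raise ValidationError("V_max must be positive")
    return DecouplingProfile(
        np.abs(vm - vb) / vmax_abs_mm_s,
        np.abs(vb - vf) / vmax_abs_mm_s,
        np.abs(vm - vf) / vmax_abs_mm_s,
    )


def gearing_ratios(v_mtu, v_belly, v_fascicle, epsilon: float = 1.0):
    """Classic gearing ratios with near-zero denominators masked.

    Returns masked arrays (tendon gearing V_MTU/V_Belly, belly gearing —
    the architectural gear ratio — V_Belly/V_Fascicle, and MTU gearing
    V_MTU/V_Fascicle); samples with |denominator| < epsilon (mm/s) are
    masked as undefined rather than propagated as non-physiological spikes.
    """
    if not (epsilon > 0):
        raise ValidationError("epsilon must be positive")
    vm = np.asarray(v_mtu, dtype=float)
    vb = np.asarray(v_belly, dtype=float)
    vf = np.asarray(v_fascicle, dtype=float)

    def ratio(num, den):
        mask = np.abs(den) < epsilon
        safe = np.where(mask, 1.0, den)
        return np.ma.masked_array(num / safe, mask=mask)

    return ratio(vm, vb), ratio(vb, vf), ratio(vm, vf)


def write_profile(profile: DecouplingProfile, path) -> None:
    """Export a profile as delimited text (percent_stance, dc_tendon, dc_belly, dc_mtu)."""
    import pandas as pd

    from .kinematics import STANCE_GRID

    pd.DataFrame({
        "percent_stance": STANCE_GRID,
        "dc_tendon": profile.dc_tendon,
        "dc_belly": profile.dc_belly,
        "dc_mtu": profile.dc_mtu,
    }).to_csv(path, index=False)


def read_profile(path) -> DecouplingProfile:
    """Read a profile exported by :func:`write_profile` (or equivalent
    percent-stance DC curves, e.g. published figure source data)."""
    import pandas as pd

    df = pd.read_csv(path)
    missing = {"dc_tendon", "dc_belly", "dc_mtu"} - set(df.columns)
    if missing:
        raise ValidationError(f"profile file is missing columns: {sorted(missing)}")
    return DecouplingProfile(
        df["dc_tendon"].to_numpy(float),
        df["dc_belly"].to_numpy(float),
        df["dc_mtu"].to_numpy(float),
    )


def stance_averaged_dc(profile: DecouplingProfile) -> dict[str, float]:
    """Stance averages of the three DC curves, as reported in summary tables."""
    return {
        "dc_tendon": profile.mean_tendon,
        "dc_belly": profile.mean_belly,
        "dc_mtu": profile.mean_mtu,
    }
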