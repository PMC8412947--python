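"""Synthetic stance-phase trials and MVC datasets with analytic ground truth.

Every downstream stage (event detection, geometry, differentiation,
potentials, efficiency, decoupling, EMG) is testable without motion-capture
or ultrasound data: trajectories are *prescribed* smooth functions of
normalized stance time, so their velocities — and hence every
stance-averaged target — exist in closed form or as accurate quadrature of
known analytic functions.

Trajectory family
-----------------
Fascicle length, pennation angle, and the MTU lengthening-shortening
profile are cubic smoothstep interpolants S(u) = 3u^2 - 2u^3 between
endpoint values (C1, zero end-velocity). The MTU profile rises by the
configured excursion until ``mtu_shortening_onset`` of stance, then falls
to ``-mtu_rebound * excursion`` at toe-off (lengthening-shortening). The
joint angle that drives the MTU in the analysis (ankle for the plantar
flexors, knee for the knee extensors) is constructed by inverting the
lever-arm relation, so the analysis pipeline can reconstruct the prescribed
MTU length exactly. Knee-angle minima are placed exactly at touchdown and
toe-off, with monotone padding outside stance, so stance detection recovers
the prescribed window sample-exactly. EMG is a sinusoidal carrier under a
Gaussian burst envelope.

Presets
-------
``soleus_like``: continuous fascicle shortening 0.994 -> 0.752 L/L_0 over a
304 ms stance (mean velocity ~0.8 L_0/s), increasing pennation, large MTU
excursion (high tendon decoupling). ``vl_like``: near-isometric fascicles
(~1.05 L/L_0), flat pennation, 290 ms stance. Preset endpoint values mirror
published stance-averaged operating conditions of the human soleus and
vastus lateralis during running at moderate speed.

Noise is additive i.i.d. Gaussian per channel from a single seeded
generator stream; channels are drawn in the fixed order knee, ankle,
fascicle, pennation, EMG, moment, so a given seed is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Mapping

import numpy as np
import pandas as pd
from scipy.integrate import quad, simpson
from scipy.optimize import brentq

from .contractile import ForceLengthCurve, MuscleParameters, fl_potential, fv_potential
from .efficiency import evaluate_efficiency, reference_efficiency_curve
from .errors import ValidationError
from .kinematics import StanceWindow
from .traces import TimeSeriesTrace

__all__ = [
    "CHANNELS",
    "SyntheticTrialConfig",
    "SyntheticTrial",
    "generate_trial",
    "generate_mvc_dataset",
    "generate_mvc_emg",
    "compute_ground_truth",
]

#: Channel (column) order, also the noise-draw order.
CHANNELS = ("knee_deg", "ankle_deg", "fascicle_mm", "pennation_deg", "emg_V", "moment_Nm")

_PRESET_NOISE = {
    "knee_deg": 0.1,
    "ankle_deg": 0.1,
    "fascicle_mm": 0.3,
    "pennation_deg": 0.2,
    "emg_V": 0.02,
    "moment_Nm": 1.0,
}


def _smoothstep(u):
    u = np.clip(u, 0.0, 1.0)
    return 3.0 * u**2 - 2.0 * u**3


def _dsmoothstep(u):
    u = np.asarray(u, dtype=float)
    inside = (u >= 0.0) & (u <= 1.0)
    return np.where(inside, 6.0 * u * (1.0 - u), 0.0)


@dataclass(frozen=True)
class SyntheticTrialConfig:
    """Full parameterization of one synthetic stance trial.

    Lengths in mm, angles in degrees, times in seconds, EMG in volts,
    moments in N*m. ``noise_sd`` maps channel name to the SD of additive
    Gaussian noise in that channel's units (a bare number applies to all
    channels — mainly useful as 0 for noiseless trials).
    """

    preset: str = "custom"
    stance_duration: float = 0.3
    sample_rate: float = 1000.0
    # muscle / contractile
    L0_mm: float = 45.0
    Fmax_N: float = 3000.0
    fl_curvature: float = -3.0  # c2 of the quadratic force-length curve, N/mm^2
    ft: float = 0.4
    vmax_norm: float = 8.0  # L_0/s
    a_rel: float | None = None
    b_rel: float | None = None
    # fascicle / pennation trajectories (relative to L0 / degrees)
    fascicle_start_rel: float = 1.0
    fascicle_end_rel: float = 0.9
    pennation_start_deg: float = 15.0
    pennation_end_deg: float = 20.0
    # MTU profile and joint geometry
    mtu_excursion_mm: float = 15.0
    mtu_shortening_onset: float = 0.55  # fraction of stance at peak MTU length
    mtu_rebound: float = 0.5  # toe-off MTU offset = -rebound * excursion
    initial_mtu_length_mm: float = 400.0
    lever_arm_mm: float = 50.0
    mtu_joint: str = "ankle_deg"  # which joint column encodes the MTU profile
    knee_flexion_amplitude_deg: float = 25.0  # stance flexion hump (ankle-driven presets)
    # EMG
    emg_burst_center: float = 0.4  # fraction of stance
    emg_burst_width: float = 0.12
    emg_mvc_ratio: float = 0.5  # burst amplitude relative to MVC amplitude
    emg_carrier_hz: float = 150.0
    # joint moment
    moment_peak_Nm: float | None = None
    # bookkeeping
    pad_fraction: float = 0.15
    noise_sd: Mapping[str, float] | float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.preset not in ("soleus_like", "vl_like", "custom"):
            raise ValidationError(f"invalid preset: {self.preset!r}")
        if not (self.stance_duration > 0):
            raise ValidationError("stance_duration must be positive")
        if self.sample_rate < 100:
            raise ValidationError("sample_rate must be >= 100 Hz")
        if self.L0_mm <= 0:
            raise ValidationError("L0 must be positive")
        for b in (self.pennation_start_deg, self.pennation_end_deg):
            if not (0 <= b < 90):
                raise ValidationError("pennation must lie in [0, 90) degrees")
        if not (0 < self.mtu_shortening_onset < 1):
            raise ValidationError("mtu_shortening_onset must lie in (0, 1)")
        if self.mtu_joint not in ("ankle_deg", "knee_deg"):
            raise ValidationError("mtu_joint must be 'ankle_deg' or 'knee_deg'")
        for sd in self.noise_map().values():
            if sd < 0:
                raise ValidationError("noise_sd must be >= 0")

    def noise_map(self) -> dict[str, float]:
        if isinstance(self.noise_sd, Mapping):
            unknown = set(self.noise_sd) - set(CHANNELS)
            if unknown:
                raise ValidationError(f"unknown noise channels: {sorted(unknown)}")
            return {ch: float(self.noise_sd.get(ch, 0.0)) for ch in CHANNELS}
        return {ch: float(self.noise_sd) for ch in CHANNELS}

    def muscle_parameters(self) -> MuscleParameters:
        return MuscleParameters(
            self.preset, self.L0_mm, self.Fmax_N, self.ft, self.vmax_norm,
            a_rel=self.a_rel, b_rel=self.b_rel,
        )

    def force_length_curve(self) -> ForceLengthCurve:
        c2 = self.fl_curvature
        if c2 >= 0:
            raise ValidationError("fl_curvature must be negative (concave)")
        lo = self.L0_mm * min(self.fascicle_start_rel, self.fascicle_end_rel)
        hi = self.L0_mm * max(self.fascicle_start_rel, self.fascicle_end_rel)
        return ForceLengthCurve(
            c2, -2.0 * c2 * self.L0_mm, self.Fmax_N + c2 * self.L0_mm**2, (lo, hi)
        )

    @classmethod
    def from_preset(cls, preset: str, seed: int = 0, **overrides) -> "SyntheticTrialConfig":
        """Build a preset configuration; keyword overrides are applied last."""
        if preset == "soleus_like":
            base = cls(
                preset="soleus_like", stance_duration=0.304, L0_mm=41.3,
                Fmax_N=2887.0, fl_curvature=-3.0, ft=0.19, vmax_norm=6.77,
                a_rel=0.175, b_rel=1.182,
                fascicle_start_rel=0.994, fascicle_end_rel=0.752,
                pennation_start_deg=19.4, pennation_end_deg=28.4,
                mtu_excursion_mm=18.0, mtu_shortening_onset=0.59,
                initial_mtu_length_mm=400.0, lever_arm_mm=50.0,
                mtu_joint="ankle_deg", emg_burst_center=0.41,
                noise_sd=dict(_PRESET_NOISE), seed=seed,
            )
        elif preset == "vl_like":
            base = cls(
                preset="vl_like", stance_duration=0.290, L0_mm=94.0,
                Fmax_N=4990.0, fl_curvature=-1.0, ft=0.63, vmax_norm=11.51,
                a_rel=0.351, b_rel=4.042,
                fascicle_start_rel=1.066, fascicle_end_rel=1.042,
                pennation_start_deg=13.2, pennation_end_deg=13.4,
                mtu_excursion_mm=22.6, mtu_shortening_onset=0.50,
                initial_mtu_length_mm=450.0, lever_arm_mm=40.0,
                mtu_joint="knee_deg", emg_burst_center=0.35,
                noise_sd=dict(_PRESET_NOISE), seed=seed,
            )
        elif preset == "custom":
            base = cls(preset="custom", seed=seed)
        else:
            raise ValidationError(f"invalid preset: {preset!r}")
        return replace(base, **overrides) if overrides else base


@dataclass(frozen=True)
class SyntheticTrial:
    """Generated traces plus the analytically computed ground truth."""

    config: SyntheticTrialConfig
    traces: dict[str, TimeSeriesTrace]
    window: StanceWindow
    ground_truth: dict[str, float]

    def to_dataframe(self) -> pd.DataFrame:
        first = next(iter(self.traces.values()))
        data = {"time_s": first.time}
        data.update({ch: self.traces[ch].values for ch in CHANNELS})
        return pd.DataFrame(data)

    def save(self, path) -> None:
        """Write the trial as comma-separated text with a header row."""
        self.to_dataframe().to_csv(path, index=False)


class _AnalyticModel:
    """Prescribed trajectories as callables of normalized stance time u."""

    def __init__(self, cfg: SyntheticTrialConfig, stance_T: float):
        self.cfg = cfg
        self.T = stance_T

    def fascicle_mm(self, u):
        c = self.cfg
        return c.L0_mm * (c.fascicle_start_rel
                          + (c.fascicle_end_rel - c.fascicle_start_rel) * _smoothstep(u))

    def fascicle_vel(self, u):
        c = self.cfg
        return c.L0_mm * (c.fascicle_end_rel - c.fascicle_start_rel) * _dsmoothstep(u) / self.T

    def pennation_deg(self, u):
        c = self.cfg
        return c.pennation_start_deg + (c.pennation_end_deg - c.pennation_start_deg) * _smoothstep(u)

    def pennation_vel_rad(self, u):
        c = self.cfg
        return np.deg2rad(c.pennation_end_deg - c.pennation_start_deg) * _dsmoothstep(u) / self.T

    def belly_vel(self, u):
        beta = np.deg2rad(self.pennation_deg(u))
        return (self.fascicle_vel(u) * np.cos(beta)
                - self.fascicle_mm(u) * np.sin(beta) * self.pennation_vel_rad(u))

    def mtu_delta_mm(self, u):
        c = self.cfg
        onset, k, E = c.mtu_shortening_onset, c.mtu_rebound, c.mtu_excursion_mm
        u = np.asarray(u, dtype=float)
        rise = E * _smoothstep(u / onset)
        fall = E * (1.0 - (1.0 + k) * _smoothstep((u - onset) / (1.0 - onset)))
        return np.where(u <= onset, rise, fall)

    def mtu_vel(self, u):
        c = self.cfg
        onset, k, E = c.mtu_shortening_onset, c.mtu_rebound, c.mtu_excursion_mm
        u = np.asarray(u, dtype=float)
        rise = E * _dsmoothstep(u / onset) / (onset * self.T)
        fall = -E * (1.0 + k) * _dsmoothstep((u - onset) / (1.0 - onset)) / ((1.0 - onset) * self.T)
        return np.where(u <= onset, rise, fall)

    def emg_envelope(self, u):
        c = self.cfg
        return c.emg_mvc_ratio * np.exp(-0.5 * ((np.asarray(u, float) - c.emg_burst_center)
                                                / c.emg_burst_width) ** 2)


def _mean_abs(f: Callable, n_scan: int = 4001) -> float:
    """Time average of |f(u)| over [0, 1], splitting at sign changes."""
    u = np.linspace(0.0, 1.0, n_scan)
    y = f(u)
    cuts = [0.0]
    for i in np.nonzero(np.sign(y[:-1]) * np.sign(y[1:]) < 0)[0]:
        cuts.append(brentq(lambda x: float(f(x)), u[i], u[i + 1]))
    cuts.append(1.0)
    total = 0.0
    for a, b in zip(cuts[:-1], cuts[1:]):
        val, _ = quad(lambda x: abs(float(f(x))), a, b, limit=200)
        total += val
    return total


def compute_ground_truth(config: SyntheticTrialConfig, n_grid: int = 20001) -> dict[str, float]:
    """Stance-averaged targets from the prescribed analytic trajectories.

    Smooth integrands use composite Simpson quadrature on ``n_grid`` points;
    the absolute-value decoupling integrands are split at the sign changes
    of the underlying velocity differences and integrated piecewise with
    adaptive quadrature. Independent of the sampling/differentiation path
    the analysis pipeline uses.
    """
    cfg = config
    n_st = int(round(cfg.stance_duration * cfg.sample_rate))
    T = n_st / cfg.sample_rate
    model = _AnalyticModel(cfg, T)
    params = cfg.muscle_parameters()
    curve = cfg.force_length_curve()
    eff_curve = reference_efficiency_curve()

    u = np.linspace(0.0, 1.0, n_grid)
    v_short_norm = -model.fascicle_vel(u) / cfg.L0_mm  # L_0/s, shortening +
    fl = fl_potential(model.fascicle_mm(u), curve)
    fv = fv_potential(v_short_norm, params)

    def avg(y):
        return float(simpson(y, x=u))

    vmax_abs = params.vmax_abs_mm_s
    mean_v_norm = (cfg.fascicle_start_rel - cfg.fascicle_end_rel) / T
    gt = {
        "stance_duration_s": T,
        "mean_fascicle_velocity_norm": mean_v_norm,
        "mean_pennation_deg": 0.5 * (cfg.pennation_start_deg + cfg.pennation_end_deg),
        "fl_potential": avg(fl),
        "fv_potential": avg(fv),
        "flv_potential": avg(fl * fv),
        "efficiency": float(evaluate_efficiency(mean_v_norm, params, eff_curve)),
        "dc_tendon": _mean_abs(lambda x: model.mtu_vel(x) - model.belly_vel(x)) / vmax_abs,
        "dc_belly": _mean_abs(lambda x: model.belly_vel(x) - model.fascicle_vel(x)) / vmax_abs,
        "dc_mtu": _mean_abs(lambda x: model.mtu_vel(x) - model.fascicle_vel(x)) / vmax_abs,
        "peak_emg_pct": 100.0 * cfg.emg_burst_center,
        "emg_normalized_peak": cfg.emg_mvc_ratio,
    }
    return gt


def generate_trial(config: SyntheticTrialConfig) -> SyntheticTrial:
    """Generate one stance trial; identical config and seed give identical bits."""
    cfg = config
    rate = cfg.sample_rate
    n_st = int(round(cfg.stance_duration * rate))
    if n_st < 10:
        raise ValidationError("stance window too short for the sample rate")
    T = n_st / rate
    n_pad = max(3, int(round(cfg.pad_fraction * n_st)))
    td, to = n_pad, n_pad + n_st
    n = to + n_pad + 1
    t = np.arange(n) / rate
    u_ext = (np.arange(n) - td) / n_st  # < 0 before touchdown, > 1 after toe-off
    u = np.clip(u_ext, 0.0, 1.0)
    model = _AnalyticModel(cfg, T)

    fascicle = model.fascicle_mm(u)
    pennation = model.pennation_deg(u)
    mtu_delta = model.mtu_delta_mm(u)
    lever_rad = np.deg2rad(cfg.lever_arm_mm)  # mm per deg equivalent: r * pi/180

    # Joint angles. The MTU-driving joint inverts L = L_init + r * dphi so
    # the analysis reconstructs the prescribed MTU exactly (constant lever).
    mtu_angle = 20.0 + mtu_delta / lever_rad
    pad_slope = 150.0  # deg/s monotone padding outside stance (swing-like)
    before = np.maximum(td - np.arange(n), 0) / rate * pad_slope
    after = np.maximum(np.arange(n) - to, 0) / rate * pad_slope
    if cfg.mtu_joint == "knee_deg":
        knee = mtu_angle + before + after
        ankle = np.full(n, 10.0)
    else:
        ankle = mtu_angle
        hump = np.where(u <= 0.5, _smoothstep(2 * u), _smoothstep(2.0 - 2 * u))
        knee = 15.0 + cfg.knee_flexion_amplitude_deg * hump + before + after

    emg_env = model.emg_envelope(u_ext)
    emg = emg_env * np.sin(2 * np.pi * cfg.emg_carrier_hz * t)

    peak_moment = cfg.moment_peak_Nm
    if peak_moment is None:
        peak_moment = 0.8 * cfg.Fmax_N * cfg.lever_arm_mm / 1000.0
    moment = np.where((u_ext >= 0) & (u_ext <= 1), peak_moment * np.sin(np.pi * u) ** 2, 0.0)

    channels = {
        "knee_deg": knee,
        "ankle_deg": ankle,
        "fascicle_mm": fascicle,
        "pennation_deg": pennation,
        "emg_V": emg,
        "moment_Nm": moment,
    }
    rng = np.random.default_rng(cfg.seed)
    noise = cfg.noise_map()
    for ch in CHANNELS:  # fixed draw order for reproducibility
        sd = noise[ch]
        if sd > 0:
            channels[ch] = channels[ch] + rng.normal(0.0, sd, size=n)

    units = {"knee_deg": "deg", "ankle_deg": "deg", "fascicle_mm": "mm",
             "pennation_deg": "deg", "emg_V": "V", "moment_Nm": "N.m"}
    traces = {ch: TimeSeriesTrace(channels[ch], rate, units[ch]) for ch in CHANNELS}
    gt = compute_ground_truth(cfg)
    gt["touchdown_index"] = float(td)
    gt["toeoff_index"] = float(to)
    return SyntheticTrial(cfg, traces, StanceWindow(td, to), gt)


def generate_mvc_dataset(
    L0_mm: float,
    Fmax_N: float,
    n_angles: int = 8,
    noise_sd: float = 0.0,
    seed: int = 0,
    curvature: float = -3.0,
    length_span: tuple[float, float] = (0.75, 1.2),
) -> pd.DataFrame:
    """MVC samples (fascicle length, tendon force) from a concave quadratic.

    Forces follow F = F_max + curvature * (L - L_0)^2 at ``n_angles``
    lengths spanning the vertex, plus additive Gaussian noise (SD in N).
    """
    if n_angles < 3:
        raise ValidationError("need at least 3 MVC angles")
    if L0_mm <= 0 or Fmax_N <= 0 or curvature >= 0 or noise_sd < 0:
        raise ValidationError("invalid MVC generator parameters")
    L = np.linspace(length_span[0] * L0_mm, length_span[1] * L0_mm, n_angles)
    F = Fmax_N + curvature * (L - L0_mm) ** 2
    if noise_sd > 0:
        F = F + np.random.default_rng(seed).normal(0.0, noise_sd, size=n_angles)
    return pd.DataFrame({"fascicle_mm": L, "force_N": F})


def generate_mvc_emg(
    sample_rate: float = 1000.0,
    duration: float = 1.0,
    amplitude: float = 1.0,
    carrier_hz: float = 150.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> TimeSeriesTrace:
    """Carrier with a ramp-plateau-ramp envelope emulating a raw MVC EMG
    recording (effort rises smoothly over the first and last 10 % of the
    record, as in a real maximal contraction)."""
    n = int(round(duration * sample_rate))
    t = np.arange(n) / sample_rate
    ramp = max(1, n // 10)
    env = np.ones(n)
    env[:ramp] = _smoothstep(np.arange(ramp) / ramp)
    env[-ramp:] = _smoothstep(np.arange(ramp, 0, -1) / ramp)
    x = amplitude * env * np.sin(2 * np.pi * carrier_hz * t)
    if noise_sd > 0:
        x = x + np.random.default_rng(seed).normal(0.0, noise_sd, size=t.size)
    return TimeSeriesTrace(x, sample_rate, "V")
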