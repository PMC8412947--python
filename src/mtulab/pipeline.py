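"""Per-trial analysis orchestration, V_max sensitivity, and group summaries.

``analyze_trial`` runs the whole chain on one stance trial: stance-event
detection from the knee angle, MTU/belly length reconstruction,
differentiation, time normalization onto the 101-point stance grid, force
potentials, enthalpy efficiency, decoupling coefficients, and EMG metrics.
Every reported scalar is the grid mean over stance, except enthalpy
efficiency, which by default is evaluated at the stance-mean fascicle
velocity (an instantaneous-then-average mode is available).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import signal

from . import io as _io
from .contractile import (
    ForceLengthCurve,
    MuscleParameters,
    fit_force_length,
    fl_potential,
    flv_potential,
    fv_potential,
    tendon_force,
)
from .decoupling import decoupling_profile
from .efficiency import EfficiencyCurve, evaluate_efficiency, reference_efficiency_curve
from .emg import normalize_emg, peak_activation_timing, process_emg
from .errors import ValidationError
from .kinematics import (
    STANCE_GRID,
    StanceWindow,
    belly_length,
    detect_stance,
    differentiate,
    mtu_length,
    stance_average,
    time_normalize,
)
from .synthetic import SyntheticTrial
from .traces import LeverArm, TimeSeriesTrace

__all__ = ["AnalysisConfig", "TrialReport", "GroupSummary", "analyze_trial",
           "sensitivity_vmax", "group_summary"]

log = logging.getLogger("mtulab")

_KINEMATIC_CHANNELS = ("knee_deg", "ankle_deg", "fascicle_mm", "pennation_deg")


@dataclass(frozen=True)
class AnalysisConfig:
    """Run configuration for one muscle/group.

    ``lever`` maps joint angle to tendon lever arm; ``mtu_joint`` names the
    joint-angle column whose excursion drives the MTU length (ankle for the
    plantar flexors, knee for the knee extensors). ``smoothing_cutoff_hz``
    optionally low-pass filters the kinematic channels (zero-phase, 4th
    order) before event detection and differentiation; default is no
    smoothing.
    """

    muscle_name: str
    ft: float
    vmax_norm: float
    lever: LeverArm
    mtu_joint: str = "ankle_deg"
    initial_mtu_length_mm: float = 400.0
    a_rel: float | None = None
    b_rel: float | None = None
    emg_mvc_peak: float | None = None
    eccentric_mode: str = "clamp"
    efficiency_mode: str = "mean_velocity"  # or "instantaneous"
    smoothing_cutoff_hz: float | None = None

    def __post_init__(self) -> None:
        if self.mtu_joint not in ("ankle_deg", "knee_deg"):
            raise ValidationError("mtu_joint must be 'ankle_deg' or 'knee_deg'")
        if self.efficiency_mode not in ("mean_velocity", "instantaneous"):
            raise ValidationError("efficiency_mode must be 'mean_velocity' or 'instantaneous'")

    @classmethod
    def from_json(cls, path) -> "AnalysisConfig":
        d = json.loads(Path(path).read_text())
        d["lever"] = _io.lever_from_dict(d["lever"])
        return cls(**d)

    def to_json(self, path) -> None:
        d = {
            "muscle_name": self.muscle_name, "ft": self.ft,
            "vmax_norm": self.vmax_norm, "lever": _io.lever_to_dict(self.lever),
            "mtu_joint": self.mtu_joint,
            "initial_mtu_length_mm": self.initial_mtu_length_mm,
            "a_rel": self.a_rel, "b_rel": self.b_rel,
            "emg_mvc_peak": self.emg_mvc_peak,
            "eccentric_mode": self.eccentric_mode,
            "efficiency_mode": self.efficiency_mode,
            "smoothing_cutoff_hz": self.smoothing_cutoff_hz,
        }
        _io.write_json(d, path)

    @classmethod
    def for_synthetic(cls, trial: SyntheticTrial, **overrides) -> "AnalysisConfig":
        """Configuration matching a synthetic trial's generator settings."""
        cfg = trial.config
        base = cls(
            muscle_name=cfg.preset, ft=cfg.ft, vmax_norm=cfg.vmax_norm,
            lever=LeverArm.constant(cfg.lever_arm_mm), mtu_joint=cfg.mtu_joint,
            initial_mtu_length_mm=cfg.initial_mtu_length_mm,
            a_rel=cfg.a_rel, b_rel=cfg.b_rel, emg_mvc_peak=None,
        )
        return replace(base, **overrides) if overrides else base


@dataclass
class TrialReport:
    """Stance-grid curves and stance-averaged scalars for one trial."""

    muscle: str
    params: MuscleParameters
    fl_curve: ForceLengthCurve
    window: StanceWindow
    sample_rate: float
    scalars: dict[str, float | None]
    curves: dict[str, np.ndarray] = field(repr=False)

    def curves_frame(self) -> pd.DataFrame:
        out = {"percent_stance": STANCE_GRID}
        out.update(self.curves)
        return pd.DataFrame(out)

    def save(self, json_path, curves_path=None) -> None:
        """Write scalars as JSON, stance-grid curves as sidecar CSV."""
        json_path = Path(json_path)
        if curves_path is None:
            curves_path = json_path.with_suffix(".curves.csv")
        self.curves_frame().to_csv(curves_path, index=False)
        doc = {
            "muscle": self.muscle,
            "L0_mm": self.params.L0_mm,
            "Fmax_N": self.params.Fmax_N,
            "vmax_norm": self.params.vmax_norm,
            "vmax_abs_mm_s": self.params.vmax_abs_mm_s,
            "a_rel": self.params.a_rel,
            "b_rel": self.params.b_rel,
            "touchdown_index": self.window.touchdown_index,
            "toeoff_index": self.window.toeoff_index,
            "scalars": self.scalars,
            "curves_file": str(curves_path),
        }
        _io.write_json(doc, json_path)


def _smooth(trace: TimeSeriesTrace, cutoff_hz: float) -> TimeSeriesTrace:
    sos = signal.butter(4, cutoff_hz, btype="lowpass", fs=trace.sample_rate, output="sos")
    return trace.with_values(signal.sosfiltfilt(sos, trace.values))


def _as_traces(trial) -> dict[str, TimeSeriesTrace]:
    if isinstance(trial, SyntheticTrial):
        return dict(trial.traces)
    if isinstance(trial, pd.DataFrame):
        return _io.trial_traces(trial)
    return _io.trial_traces(_io.read_trial(trial))


def _fit_curve(mvc, config: AnalysisConfig) -> ForceLengthCurve:
    df = mvc if isinstance(mvc, pd.DataFrame) else _io.read_mvc(mvc)
    if "force_N" in df.columns:
        lengths, forces = df["fascicle_mm"].to_numpy(), df["force_N"].to_numpy()
    else:
        forces = np.array([
            tendon_force(m, config.lever, a)
            for m, a in zip(df["moment_Nm"].to_numpy(), df["angle_deg"].to_numpy())
        ])
        lengths = df["fascicle_mm"].to_numpy()
    curve = fit_force_length(lengths, forces)
    if curve.extrapolated_vertex:
        log.warning("force-length vertex lies outside the fitted range (+/-20%%)")
    return curve


def analyze_trial(trial, mvc, config: AnalysisConfig,
                  efficiency_curve: EfficiencyCurve | None = None) -> TrialReport:
    """Run the full stance analysis on one trial.

    Parameters
    ----------
    trial
        Trial table (path, DataFrame with the canonical columns, or a
        :class:`~mtulab.synthetic.SyntheticTrial`).
    mvc
        MVC table (path or DataFrame) for the individual force-length fit.
    config
        Muscle/group run configuration.
    efficiency_curve
        Efficiency-velocity curve; defaults to the packaged reference.
    """
    traces = _as_traces(trial)
    missing = [c for c in ("knee_deg", "ankle_deg", "fascicle_mm", "pennation_deg", "emg_V")
               if c not in traces]
    if missing:
        raise ValidationError(f"trial is missing channels: {missing}")
    if config.smoothing_cutoff_hz is not None:
        for ch in _KINEMATIC_CHANNELS:
            traces[ch] = _smooth(traces[ch], config.smoothing_cutoff_hz)

    curve = _fit_curve(mvc, config)
    params = MuscleParameters(
        config.muscle_name, curve.L0_mm, curve.Fmax_N, config.ft,
        config.vmax_norm, a_rel=config.a_rel, b_rel=config.b_rel,
    )
    log.info("force-length fit: L0=%.1f mm, Fmax=%.0f N", params.L0_mm, params.Fmax_N)

    window = detect_stance(traces["knee_deg"])
    rate = traces["knee_deg"].sample_rate
    log.info("stance window: samples %d-%d (%.0f ms)", window.touchdown_index,
             window.toeoff_index, 1000 * window.duration(rate))

    mtu = mtu_length(traces[config.mtu_joint], config.lever, config.initial_mtu_length_mm)
    belly0 = float(traces["fascicle_mm"].values[0]
                   * np.cos(np.deg2rad(traces["pennation_deg"].values[0])))
    belly = belly_length(traces["fascicle_mm"], traces["pennation_deg"], belly0)

    grid = {
        "mtu_length_mm": time_normalize(mtu, window),
        "belly_length_mm": time_normalize(belly, window),
        "fascicle_length_mm": time_normalize(traces["fascicle_mm"], window),
        "pennation_deg": time_normalize(traces["pennation_deg"], window),
        "mtu_velocity_mm_s": time_normalize(differentiate(mtu), window),
        "belly_velocity_mm_s": time_normalize(differentiate(belly), window),
        "fascicle_velocity_mm_s": time_normalize(differentiate(traces["fascicle_mm"]), window),
    }
    grid["fascicle_norm"] = grid["fascicle_length_mm"] / params.L0_mm
    # model boundary: shortening-positive fascicle velocity in L_0/s
    grid["fascicle_velocity_norm"] = -grid["fascicle_velocity_mm_s"] / params.L0_mm

    grid["fl_potential"] = fl_potential(grid["fascicle_length_mm"], curve)
    grid["fv_potential"] = fv_potential(grid["fascicle_velocity_norm"], params,
                                        eccentric=config.eccentric_mode)
    grid["flv_potential"] = flv_potential(grid["fl_potential"], grid["fv_potential"])

    dc = decoupling_profile(grid["mtu_velocity_mm_s"], grid["belly_velocity_mm_s"],
                            grid["fascicle_velocity_mm_s"], params.vmax_abs_mm_s)
    grid["dc_tendon"], grid["dc_belly"], grid["dc_mtu"] = dc.dc_tendon, dc.dc_belly, dc.dc_mtu

    envelope = process_emg(traces["emg_V"])
    if config.emg_mvc_peak is not None:
        env_vals = envelope.values / config.emg_mvc_peak
    else:
        env_vals = envelope.values / envelope.peak if envelope.peak > 0 else envelope.values
        log.info("no MVC reference supplied; EMG normalized to trial peak")
    grid["emg_norm"] = time_normalize(envelope.trace.with_values(env_vals), window)

    eff_curve = efficiency_curve if efficiency_curve is not None else reference_efficiency_curve()
    mean_v_norm = stance_average(grid["fascicle_velocity_norm"])
    if config.efficiency_mode == "mean_velocity":
        eff = float(evaluate_efficiency(mean_v_norm, params, eff_curve))
    else:
        eff = stance_average(evaluate_efficiency(grid["fascicle_velocity_norm"], params, eff_curve))

    if "moment_Nm" in traces:
        moment_grid = time_normalize(traces["moment_Nm"], window)
        angle_grid = time_normalize(traces[config.mtu_joint], window)
        grid["tendon_force_N"] = np.array([
            tendon_force(m, config.lever, a) for m, a in zip(moment_grid, angle_grid)
        ])

    peak_pct = peak_activation_timing(grid["emg_norm"])
    scalars: dict[str, float | None] = {
        "stance_duration_s": window.duration(rate),
        "fl_potential": stance_average(grid["fl_potential"]),
        "fv_potential": stance_average(grid["fv_potential"]),
        "flv_potential": stance_average(grid["flv_potential"]),
        "efficiency": eff,
        "mean_fascicle_velocity_norm": mean_v_norm,
        "mean_fascicle_norm": stance_average(grid["fascicle_norm"]),
        "mean_pennation_deg": stance_average(grid["pennation_deg"]),
        "dc_tendon": dc.mean_tendon,
        "dc_belly": dc.mean_belly,
        "dc_mtu": dc.mean_mtu,
        "peak_emg_pct": peak_pct,
        "emg_normalized_peak": float(np.max(grid["emg_norm"])),
        "L0_mm": params.L0_mm,
        "Fmax_N": params.Fmax_N,
        "vmax_abs_mm_s": params.vmax_abs_mm_s,
    }
    return TrialReport(config.muscle_name, params, curve, window, rate, scalars, grid)


def sensitivity_vmax(trial, mvc, config: AnalysisConfig,
                     factors: Sequence[float] = (0.7, 1.0, 1.3),
                     efficiency_curve: EfficiencyCurve | None = None) -> pd.DataFrame:
    """Force-velocity potential and efficiency under scaled V_max.

    For each factor, V_max is scaled (a_rel unchanged, b_rel re-derived as
    a_rel * scaled V_max) and the stance-averaged force-velocity potential
    and the enthalpy efficiency are recomputed from the trial's measured
    velocity profile. The factor-1.0 row reproduces the baseline report.
    """
    for f in factors:
        if f <= 0:
            raise ValidationError("V_max factors must be positive")
    eff_curve = efficiency_curve if efficiency_curve is not None else reference_efficiency_curve()
    report = analyze_trial(trial, mvc, config, efficiency_curve=eff_curve)
    v_norm = report.curves["fascicle_velocity_norm"]
    mean_v = report.scalars["mean_fascicle_velocity_norm"]
    rows = []
    for f in sorted(set(factors) | {1.0}):
        p = report.params.with_vmax_factor(f)
        fv = stance_average(fv_potential(v_norm, p, eccentric=config.eccentric_mode))
        if config.efficiency_mode == "mean_velocity":
            eff = float(evaluate_efficiency(mean_v, p, eff_curve))
        else:
            eff = stance_average(evaluate_efficiency(v_norm, p, eff_curve))
        rows.append({"vmax_factor": f, "fv_potential": fv, "efficiency": eff})
    return pd.DataFrame(rows)


@dataclass
class GroupSummary:
    """Mean +/- SD of scalars and stance-grid curves across trial reports."""

    scalars: pd.DataFrame  # index: scalar name; columns: mean, sd, n
    curve_means: pd.DataFrame  # 101 rows per curve
    curve_sds: pd.DataFrame


def group_summary(reports: Iterable[TrialReport]) -> GroupSummary:
    """Aggregate reports: per-scalar mean and sample SD (n-1 denominator,
    0 for a single report) and per-grid-point mean/SD curves."""
    reports = list(reports)
    if not reports:
        raise ValidationError("group_summary needs at least one report")

    def sd(x: np.ndarray, axis=0):
        if x.shape[axis] < 2:
            return np.zeros(np.delete(x.shape, axis))
        return np.std(x, axis=axis, ddof=1)

    names = [k for k, v in reports[0].scalars.items() if v is not None]
    rows = {}
    for k in names:
        vals = np.array([r.scalars[k] for r in reports if r.scalars[k] is not None], dtype=float)
        rows[k] = {"mean": float(np.mean(vals)), "sd": float(sd(vals)), "n": len(vals)}
    scalars = pd.DataFrame(rows).T

    curve_names = [k for k in reports[0].curves if all(k in r.curves for r in reports)]
    means, sds = {"percent_stance": STANCE_GRID}, {"percent_stance": STANCE_GRID}
    for k in curve_names:
        stack = np.stack([r.curves[k] for r in reports])
        means[k] = np.mean(stack, axis=0)
        sds[k] = sd(stack)
    return GroupSummary(scalars, pd.DataFrame(means), pd.DataFrame(sds))
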