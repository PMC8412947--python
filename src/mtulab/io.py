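"""Plain-text I/O: trial tables, MVC tables, and JSON configuration."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .traces import LeverArm, TimeSeriesTrace

__all__ = [
    "REQUIRED_TRIAL_COLUMNS",
    "read_trial",
    "trial_traces",
    "read_mvc",
    "lever_from_dict",
    "lever_to_dict",
]

REQUIRED_TRIAL_COLUMNS = ("time_s", "knee_deg", "ankle_deg", "fascicle_mm", "pennation_deg", "emg_V")
OPTIONAL_TRIAL_COLUMNS = ("moment_Nm",)


def read_trial(path, column_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a delimited trial table; optionally rename columns first.

    ``column_map`` maps canonical names to the names used in the file.
    """
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns={v: k for k, v in column_map.items()})
    missing = [c for c in REQUIRED_TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"trial file is missing columns: {missing}")
    return df


def trial_traces(df: pd.DataFrame) -> dict[str, TimeSeriesTrace]:
    """Convert a trial table to traces, inferring the (uniform) sample rate."""
    t = df["time_s"].to_numpy(dtype=float)
    if t.size < 3:
        raise ValidationError("trial must have at least 3 samples")
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9) or dt[0] <= 0:
        raise ValidationError("trial time column must be uniformly increasing")
    rate = 1.0 / float(dt[0])
    cols = [c for c in REQUIRED_TRIAL_COLUMNS + OPTIONAL_TRIAL_COLUMNS if c in df.columns and c != "time_s"]
    return {c: TimeSeriesTrace(df[c].to_numpy(dtype=float), rate, t0=float(t[0])) for c in cols}


def read_mvc(path) -> pd.DataFrame:
    """Read an MVC table.

    Accepts either pre-converted (``fascicle_mm``, ``force_N``) rows or raw
    dynamometer rows (``angle_deg``, ``moment_Nm``, ``fascicle_mm``); the
    caller converts moments to tendon force via the lever arm in the latter
    case.
    """
    df = pd.read_csv(path)
    if {"fascicle_mm", "force_N"}.issubset(df.columns):
        return df
    if {"angle_deg", "moment_Nm", "fascicle_mm"}.issubset(df.columns):
        return df
    raise ValidationError(
        "MVC file needs columns (fascicle_mm, force_N) or (angle_deg, moment_Nm, fascicle_mm)"
    )


def lever_from_dict(spec: dict | float) -> LeverArm:
    """Build a lever arm from its JSON form: a number (constant, mm) or
    ``{"angles_deg": [...], "values_mm": [...]}``."""
    if isinstance(spec, (int, float)):
        return LeverArm.constant(float(spec))
    if isinstance(spec, dict) and {"angles_deg", "values_mm"}.issubset(spec):
        return LeverArm.from_table(spec["angles_deg"], spec["values_mm"])
    raise ValidationError("lever arm must be a number or an angle table dict")


def lever_to_dict(lever: LeverArm):
    if lever.kind == "constant":
        return lever.value_mm
    return {"angles_deg": list(map(float, lever.angles_deg)),
            "values_mm": list(map(float, lever.values_mm))}


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
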