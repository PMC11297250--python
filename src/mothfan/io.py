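"""Format dialects of the pipeline and their validators.

Formats: landmark CSV (time_s, side, landmark, x_m, y_m, z_m), flow-field
NetCDF (dims time/z/y/x, variables u/v/w, attrs period_s/origin_m/
spacing_m; an .npz archive with the same content is the fallback dialect),
kinematics JSON, sampling-volume CSV and stats CSV. ``validate`` checks a
file against its dialect and reports *every* violation rather than
stopping at the first.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .synthetic import LANDMARK_COLUMNS

STATS_COLUMNS = ["arrival_bin", "metric", "median", "p25", "p75", "lo", "hi", "n"]
VOLUME_COLUMNS = ["cycles_to_arrival", "x_m", "y_m", "z_m"]
KINEMATICS_KEYS = [
    "t_hat",
    "phi_deg",
    "theta_deg",
    "alpha_deg",
    "stations",
    "stroke_plane_angle_deg",
    "body_angle_deg",
    "wingbeat_frequency_hz",
    "wing_length_m",
]

FORMATS = ("landmarks", "flow", "kinematics", "volume", "stats")


def _validate_csv(path: Path, required: list[str]) -> tuple[list[str], pd.DataFrame | None]:
    problems: list[str] = []
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        return [f"{path}: no records"], None
    except Exception as err:  # malformed CSV
        return [f"{path}: unreadable CSV ({err})"], None
    if df.empty:
        problems.append(f"{path}: no records")
    for col in required:
        if col not in df.columns:
            problems.append(f"{path}: missing column {col!r}")
    return problems, df


def validate_landmarks(path) -> list[str]:
    path = Path(path)
    problems, df = _validate_csv(path, LANDMARK_COLUMNS)
    if df is None or df.empty:
        return problems
    if "side" in df.columns:
        bad = set(df["side"].unique()) - {"L", "R", "C"}
        if bad:
            problems.append(f"{path}: column 'side' holds invalid values {sorted(bad)}")
    for col in ("x_m", "y_m", "z_m", "time_s"):
        if col in df.columns and not np.issubdtype(df[col].dtype, np.number):
            problems.append(f"{path}: column {col!r} is not numeric")
    return problems


def validate_flow(path) -> list[str]:
    path = Path(path)
    problems: list[str] = []
    if path.suffix == ".npz":
        try:
            with np.load(path) as z:
                for key in ("u", "origin", "spacing", "period"):
                    if key not in z:
                        problems.append(f"{path}: missing array {key!r}")
                if "u" in z and (z["u"].ndim != 5 or z["u"].shape[-1] != 3):
                    problems.append(f"{path}: variable 'u' must have shape (S, nz, ny, nx, 3)")
                if "u" in z and z["u"].shape[0] < 4:
                    problems.append(f"{path}: need >= 4 snapshots")
        except Exception as err:
            problems.append(f"{path}: unreadable archive ({err})")
        return problems
    try:
        import xarray as xr

        with xr.open_dataset(path, engine="scipy") as ds:
            for dim in ("time", "z", "y", "x"):
                if dim not in ds.dims:
                    problems.append(f"{path}: missing dimension {dim!r}")
            for var in ("u", "v", "w"):
                if var not in ds:
                    problems.append(f"{path}: missing variable {var!r}")
            for attr in ("period_s", "origin_m", "spacing_m"):
                if attr not in ds.attrs:
                    problems.append(f"{path}: missing global attribute {attr!r}")
            if "time" in ds.dims and ds.sizes["time"] < 4:
                problems.append(f"{path}: need >= 4 snapshots, found {ds.sizes['time']}")
            if "time" in ds.coords and ds.sizes.get("time", 0) > 2:
                dt = np.diff(ds["time"].values)
                if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
                    problems.append(
                        f"{path}: snapshot times are not uniformly spaced over one period"
                    )
    except Exception as err:
        problems.append(f"{path}: unreadable NetCDF ({err})")
    return problems


def validate_kinematics(path) -> list[str]:
    path = Path(path)
    try:
        d = json.loads(path.read_text())
    except Exception as err:
        return [f"{path}: unreadable JSON ({err})"]
    problems = [f"{path}: missing key {k!r}" for k in KINEMATICS_KEYS if k not in d]
    if not d:
        problems.append(f"{path}: no records")
    return problems


def validate_volume(path) -> list[str]:
    problems, df = _validate_csv(Path(path), VOLUME_COLUMNS)
    if df is not None and "cycles_to_arrival" in df.columns and not df.empty:
        if (df["cycles_to_arrival"] < 1).any():
            problems.append(f"{path}: cycles_to_arrival must be >= 1")
    return problems


def validate_stats(path) -> list[str]:
    path = Path(path)
    problems, df = _validate_csv(path, STATS_COLUMNS)
    if df is None or df.empty:
        return problems
    if set(STATS_COLUMNS) <= set(df.columns):
        for i, row in df.iterrows():
            if not (row["lo"] <= row["p25"] <= row["median"] <= row["p75"] <= row["hi"]):
                problems.append(f"{path}: row {i} violates lo <= p25 <= median <= p75 <= hi")
            if row["n"] <= 0:
                problems.append(f"{path}: row {i} reports n <= 0")
    return problems


_VALIDATORS = {
    "landmarks": validate_landmarks,
    "flow": validate_flow,
    "kinematics": validate_kinematics,
    "volume": validate_volume,
    "stats": validate_stats,
}


def validate(path, format_name: str) -> list[str]:
    """Check ``path`` against the named dialect; return all violations."""
    if format_name not in _VALIDATORS:
        raise ValidationError(
            f"unknown format {format_name!r}; expected one of {sorted(_VALIDATORS)}"
        )
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"{path}: file does not exist")
    return _VALIDATORS[format_name](path)
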