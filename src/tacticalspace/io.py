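"""File formats: track/event CSVs, configuration-matrix CSVs, JSON results.

Schemas
-------
tracks.csv   ``time_s,player,team,x_m,y_m`` — one row per player per frame.
events.csv   ``t_start_s,t_end_s,holder,outcome,receiver`` — possession
             intervals; ``receiver`` is non-empty exactly when outcome is
             ``pass``.
matrix CSV   one row per category (first column the category name), one
             column per second; a JSON sidecar records player, condition,
             trial and the binning-scheme hash.

Raw GPS latitude/longitude input can be projected to local metres with
:func:`latlon_to_local` (equirectangular about a reference point — adequate
at pitch scale).
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .encoding import BinningScheme, ConfigurationMatrix
from .errors import SchemaError
from .simulate import OUT_OF_TIME

TRACK_COLUMNS = ["time_s", "player", "team", "x_m", "y_m"]
EVENT_COLUMNS = ["t_start_s", "t_end_s", "holder", "outcome", "receiver"]
EVENT_OUTCOMES = {"pass", "turnover", "goal", OUT_OF_TIME}

EARTH_RADIUS_M = 6371008.8


def _require_columns(df: pd.DataFrame, cols: list[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")


def read_tracks(path, flip_x: bool = False, pitch_length: float | None = None) -> pd.DataFrame:
    """Read a track CSV; optionally flip the attacking direction.

    ``flip_x`` mirrors x about the pitch midline (requires ``pitch_length``)
    for data recorded with the analyzed team attacking toward -x.
    """
    df = pd.read_csv(path)
    _require_columns(df, TRACK_COLUMNS, path)
    for col in ("time_s", "x_m", "y_m"):
        bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
        if len(bad):
            raise SchemaError(f"{path}: non-numeric {col!r} at line {bad[0] + 2}")
        df[col] = pd.to_numeric(df[col])
    if flip_x:
        if pitch_length is None:
            raise SchemaError("flip_x requires pitch_length")
        df["x_m"] = pitch_length - df["x_m"]
    return df[TRACK_COLUMNS]


def write_tracks(df: pd.DataFrame, path) -> None:
    df[TRACK_COLUMNS].to_csv(path, index=False)


def read_events(path) -> pd.DataFrame:
    df = pd.read_csv(path, keep_default_na=False)
    _require_columns(df, EVENT_COLUMNS, path)
    for col in ("t_start_s", "t_end_s"):
        bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
        if len(bad):
            raise SchemaError(f"{path}: non-numeric {col!r} at line {bad[0] + 2}")
        df[col] = pd.to_numeric(df[col])
    for i, row in df.iterrows():
        line = i + 2  # header + 1-based
        if row["t_end_s"] <= row["t_start_s"]:
            raise SchemaError(f"{path}: t_end_s <= t_start_s at line {line}")
        if row["outcome"] not in EVENT_OUTCOMES:
            raise SchemaError(f"{path}: unknown outcome {row['outcome']!r} at line {line}")
        has_receiver = str(row["receiver"]) != ""
        if row["outcome"] == "pass" and not has_receiver:
            raise SchemaError(f"{path}: pass without receiver at line {line}")
        if row["outcome"] != "pass" and has_receiver:
            raise SchemaError(f"{path}: receiver on non-pass outcome at line {line}")
        if row["outcome"] == "pass" and row["receiver"] == row["holder"]:
            raise SchemaError(f"{path}: self-pass at line {line}")
    return df[EVENT_COLUMNS]


def write_events(df: pd.DataFrame, path) -> None:
    df[EVENT_COLUMNS].to_csv(path, index=False)


def write_matrix(cm: ConfigurationMatrix, path, scheme: BinningScheme | None = None) -> None:
    """Write a configuration matrix as CSV plus a JSON sidecar."""
    path = Path(path)
    df = pd.DataFrame(
        cm.matrix, index=cm.category_names, columns=[str(t) for t in range(cm.n_seconds)]
    )
    df.index.name = "category"
    df.to_csv(path)
    sidecar = {
        "player": cm.player,
        "condition": cm.condition,
        "trial": cm.trial,
        "n_seconds": cm.n_seconds,
        "scheme_hash": (scheme or BinningScheme()).hash(),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_matrix(path) -> ConfigurationMatrix:
    path = Path(path)
    df = pd.read_csv(path, index_col=0)
    meta = json.loads(path.with_suffix(".json").read_text())
    cm = ConfigurationMatrix(
        player=meta["player"],
        condition=meta["condition"],
        trial=int(meta["trial"]),
        matrix=df.to_numpy(dtype=np.uint8),
        category_names=list(df.index),
    )
    cm.validate()
    return cm


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True))


def latlon_to_local(lat_deg, lon_deg, ref_lat_deg: float, ref_lon_deg: float) -> np.ndarray:
    """Project latitude/longitude (degrees) to local metres about a reference.

    Equirectangular projection: x = R cos(lat_ref) Δλ, y = R Δφ. Error is
    negligible (<0.1%) at the ~100 m scale of a pitch.
    """
    lat = np.radians(np.asarray(lat_deg, dtype=float))
    lon = np.radians(np.asarray(lon_deg, dtype=float))
    ref_lat = math.radians(ref_lat_deg)
    ref_lon = math.radians(ref_lon_deg)
    x = EARTH_RADIUS_M * math.cos(ref_lat) * (lon - ref_lon)
    y = EARTH_RADIUS_M * (lat - ref_lat)
    return np.stack([x, y], axis=-1)
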