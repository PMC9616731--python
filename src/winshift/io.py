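"""Readers and writers for the pipeline's CSV/JSON dialects.

All tables are plain CSV with a declared header; readers validate required
columns (reporting the file and the missing names), preserve extra columns,
and parse timestamps.  Writers are deterministic: fixed column order, fixed
float formatting, no index.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from winshift.errors import SchemaError
from winshift.ram import VisitSequence

VISITS_COLUMNS = [
    "bee_id",
    "colony_id",
    "bout_index",
    "bout_type",
    "visit_index",
    "arm_id",
    "timestamp_s",
]
SCORES_COLUMNS = ["bee_id", "ram_score", "ram_score_log1p", "n_bouts"]
RFID_COLUMNS = ["tag_id", "timestamp", "direction"]
WEIGH_COLUMNS = ["tag_id", "timestamp", "direction", "mass_mg", "pollen_oneleg_mg"]
BEES_COLUMNS = ["bee_id", "colony_id", "size_mm", "age_at_release", "tested"]
WEATHER_COLUMNS = ["date", "temp_C", "humidity_pct", "wind_ms"]


def require_columns(df: pd.DataFrame, columns: list[str], name: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{name}: missing required columns {missing}")


def _read_csv(path, columns: list[str], name: str, **kwargs) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, **kwargs)
    except Exception as exc:
        raise SchemaError(f"{name} ({path}): {exc}") from exc
    require_columns(df, columns, f"{name} ({path})")
    return df


def read_visits_csv(path) -> pd.DataFrame:
    df = _read_csv(path, [c for c in VISITS_COLUMNS if c != "colony_id"], "visit log")
    df["bee_id"] = df["bee_id"].astype(str)
    return df


def write_visits_csv(df: pd.DataFrame, path) -> None:
    require_columns(df, [c for c in VISITS_COLUMNS if c != "colony_id"], "visit log")
    ordered = [c for c in VISITS_COLUMNS if c in df.columns]
    ordered += [c for c in df.columns if c not in ordered]
    df[ordered].to_csv(path, index=False)


def visits_to_sequences(df: pd.DataFrame, n_arms: int) -> dict[str, list[VisitSequence]]:
    """Group a visit log into per-bee ordered bout sequences."""
    out: dict[str, list[VisitSequence]] = {}
    has_ts = "timestamp_s" in df.columns and df["timestamp_s"].notna().all()
    for (bee, bout_idx), grp in df.groupby(["bee_id", "bout_index"], sort=True):
        grp = grp.sort_values("visit_index")
        bout_types = grp["bout_type"].unique()
        if len(bout_types) != 1:
            raise SchemaError(f"bee {bee} bout {bout_idx}: mixed bout_type values")
        out.setdefault(str(bee), []).append(
            VisitSequence(
                bee_id=str(bee),
                bout_index=int(bout_idx),
                bout_type=str(bout_types[0]),
                arms=tuple(int(a) for a in grp["arm_id"]),
                n_arms=n_arms,
                timestamps=tuple(float(t) for t in grp["timestamp_s"]) if has_ts else None,
            )
        )
    for bee in out:
        out[bee].sort(key=lambda s: s.bout_index)
    return out


def write_scores_csv(scores: pd.DataFrame, path) -> None:
    require_columns(scores, SCORES_COLUMNS, "scores table")
    scores[SCORES_COLUMNS].to_csv(path, index=False, float_format="%.6f")


def read_scores_csv(path) -> pd.DataFrame:
    df = _read_csv(path, SCORES_COLUMNS, "scores table")
    df["bee_id"] = df["bee_id"].astype(str)
    return df


def read_rfid_csv(path) -> pd.DataFrame:
    df = _read_csv(path, RFID_COLUMNS, "rfid log")
    df["tag_id"] = df["tag_id"].astype(str)
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    return df


def read_weigh_csv(path) -> pd.DataFrame:
    df = _read_csv(path, WEIGH_COLUMNS, "weigh log")
    df["tag_id"] = df["tag_id"].astype(str)
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    return df


def read_bees_csv(path) -> pd.DataFrame:
    df = _read_csv(path, [c for c in BEES_COLUMNS if c != "tested"], "bee table")
    df["bee_id"] = df["bee_id"].astype(str)
    return df


def read_weather_csv(path) -> pd.DataFrame:
    df = _read_csv(path, WEATHER_COLUMNS, "weather table")
    return df


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def write_json(obj, path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (pd.Timestamp,)):
            return o.isoformat()
        return str(o)

    Path(path).write_text(json.dumps(obj, indent=1, default=_default, sort_keys=True) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())
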