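"""RFID/scale event logs → per-trip foraging efficiency records.

Bees leaving and entering the nest pass through directional RFID readers and
a weighing platform.  This module pairs directional reads into round trips,
attaches entry/exit weights, derives nectar and pollen loads (total pollen is
twice the single-corbicula sample; nectar is the weight gain net of pollen),
classifies trips by pollen mass, applies the minimum-duration filter that
removes orientation flights, and summarizes survival and lifetime effort.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from winshift.errors import ValidationError

__all__ = [
    "TripConfig",
    "pair_events_to_trips",
    "derive_loads",
    "classify_and_filter",
    "efficiency_table",
    "survival_and_effort",
    "kaplan_meier_summary",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TripConfig:
    """Thresholds for trip construction and classification.

    * ``debounce_s`` — RFID reads of the same direction within this window are
      echoes of one passage and collapsed to the first read.
    * ``weigh_match_tol_s`` — maximum |Δt| between an RFID read and the weigh
      event attached to it.
    * ``nectar_max_pollen_mg`` — trips with less pollen than this are nectar
      trips, more are pollen trips; the exact boundary goes to
      ``boundary_class``.
    * ``min_duration_min`` — shorter trips are excluded from efficiency
      analysis (likely orientation flights or waste disposal).
    """

    debounce_s: float = 5.0
    weigh_match_tol_s: float = 120.0
    nectar_max_pollen_mg: float = 3.0
    min_duration_min: float = 7.0
    boundary_class: str = "pollen"

    def __post_init__(self) -> None:
        for name in ("debounce_s", "weigh_match_tol_s", "nectar_max_pollen_mg", "min_duration_min"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.boundary_class not in ("nectar", "pollen"):
            raise ValidationError("boundary_class must be 'nectar' or 'pollen'")


def _debounce(events: pd.DataFrame, window_s: float) -> pd.DataFrame:
    """Drop same-direction reads within ``window_s`` of the previous kept read."""
    keep = []
    last_t: dict[str, pd.Timestamp] = {}
    for row in events.itertuples():
        prev = last_t.get(row.direction)
        if prev is not None and (row.timestamp - prev).total_seconds() < window_s:
            continue
        last_t[row.direction] = row.timestamp
        keep.append(row.Index)
    return events.loc[keep]


def pair_events_to_trips(
    rfid: pd.DataFrame,
    weighs: pd.DataFrame | None = None,
    config: TripConfig | None = None,
) -> tuple[pd.DataFrame, list[dict]]:
    """Greedy chronological pairing of directional reads into round trips.

    Per bee, each ``out`` read opens an excursion that the next ``in`` read
    closes.  An ``out`` followed by another ``out`` leaves the first as an
    open (censored) excursion; an ``in`` with no open excursion is dropped.
    Weigh events are attached to the nearest trip endpoint of matching
    direction within the tolerance.  Returns the trip table plus a list of
    logged issues (reason, bee, timestamp).
    """
    config = config or TripConfig()
    for col in ("tag_id", "timestamp", "direction"):
        if col not in rfid.columns:
            raise ValidationError(f"rfid table missing column {col!r}")
    rfid = rfid.copy()
    rfid["timestamp"] = pd.to_datetime(rfid["timestamp"])
    if not rfid["direction"].isin(["out", "in"]).all():
        raise ValidationError("rfid direction must be 'out' or 'in'")
    issues: list[dict] = []
    trip_rows = []
    for bee, grp in rfid.groupby("tag_id", sort=True):
        ev = _debounce(grp.sort_values("timestamp", kind="mergesort"), config.debounce_s)
        open_out: pd.Timestamp | None = None
        for row in ev.itertuples():
            if row.direction == "out":
                if open_out is not None:
                    trip_rows.append((bee, open_out, pd.NaT, "open", "no_return_read"))
                open_out = row.timestamp
            else:
                if open_out is None:
                    issues.append(
                        {"reason": "in_without_out", "bee_id": bee, "timestamp": row.timestamp}
                    )
                    continue
                trip_rows.append((bee, open_out, row.timestamp, "complete", ""))
                open_out = None
        if open_out is not None:
            trip_rows.append((bee, open_out, pd.NaT, "open", "no_return_read"))
    trips = pd.DataFrame(
        trip_rows, columns=["bee_id", "t_out", "t_in", "status", "reason"]
    )
    for col in ("t_out", "t_in"):
        trips[col] = pd.to_datetime(trips[col])
    trips["duration_min"] = (trips["t_in"] - trips["t_out"]).dt.total_seconds() / 60.0
    for col in ("w_out_mg", "w_in_mg", "pollen_oneleg_mg"):
        trips[col] = np.nan

    if weighs is not None and not weighs.empty:
        weighs = weighs.copy()
        weighs["timestamp"] = pd.to_datetime(weighs["timestamp"])
        matched = np.zeros(len(weighs), dtype=bool)
        weighs = weighs.reset_index(drop=True)
        for direction, t_col, m_col in (("out", "t_out", "w_out_mg"), ("in", "t_in", "w_in_mg")):
            sub = weighs[weighs["direction"] == direction]
            for i, trip in trips.iterrows():
                t_ref = trip[t_col]
                if pd.isna(t_ref):
                    continue
                cand = sub[sub["tag_id"] == trip["bee_id"]]
                if cand.empty:
                    continue
                dt = (cand["timestamp"] - t_ref).abs().dt.total_seconds()
                j = dt.idxmin()
                if dt.loc[j] <= config.weigh_match_tol_s:
                    trips.at[i, m_col] = weighs.at[j, "mass_mg"]
                    if direction == "in" and "pollen_oneleg_mg" in weighs.columns:
                        trips.at[i, "pollen_oneleg_mg"] = weighs.at[j, "pollen_oneleg_mg"]
                    matched[j] = True
        for j in np.flatnonzero(~matched):
            issues.append(
                {
                    "reason": "weigh_without_rfid_match",
                    "bee_id": weighs.at[j, "tag_id"],
                    "timestamp": weighs.at[j, "timestamp"],
                }
            )
    if issues:
        logger.info("pair_events_to_trips: %d events logged as issues", len(issues))
    return trips.reset_index(drop=True), issues


def derive_loads(trips: pd.DataFrame) -> pd.DataFrame:
    """Add nectar/pollen loads: pollen is doubled one-leg mass, nectar the rest.

    ``pollen_total_mg = 2 × pollen_oneleg_mg`` (pollen was sampled from one of
    the two corbiculae); ``nectar_mg = w_in − w_out − pollen_total_mg``.
    Negative nectar values (bees leaving heavier than they return) are
    retained.  Trips missing either weight are flagged ``weight_incomplete``
    and keep NaN loads; they still count toward foraging effort.
    """
    out = trips.copy()
    pollen_one = out["pollen_oneleg_mg"].fillna(0.0)
    out["pollen_total_mg"] = 2.0 * pollen_one
    out["nectar_mg"] = out["w_in_mg"] - out["w_out_mg"] - out["pollen_total_mg"]
    incomplete = out["w_in_mg"].isna() | out["w_out_mg"].isna()
    complete_trip = out["status"].eq("complete") if "status" in out.columns else True
    out["weight_incomplete"] = incomplete & complete_trip
    out.loc[incomplete, ["pollen_total_mg", "nectar_mg"]] = np.nan
    return out


def classify_and_filter(trips: pd.DataFrame, config: TripConfig | None = None) -> pd.DataFrame:
    """Assign trip_type ∈ {nectar, pollen, excluded} with reason codes.

    Order of rules: open excursions and weight-incomplete trips are excluded
    first, then the minimum-duration filter, then the pollen-mass split.  The
    exact-boundary pollen mass (default 3 mg) goes to ``config.boundary_class``
    and is logged.
    """
    config = config or TripConfig()
    out = trips.copy()
    out["trip_type"] = "excluded"
    out["exclude_reason"] = ""
    is_open = out["status"].ne("complete") if "status" in out.columns else False
    incomplete = out.get("weight_incomplete", pd.Series(False, index=out.index)).fillna(False)
    short = out["duration_min"] < config.min_duration_min
    out.loc[is_open, "exclude_reason"] = "open_excursion"
    out.loc[~is_open & incomplete, "exclude_reason"] = "weight_incomplete"
    out.loc[~is_open & ~incomplete & short, "exclude_reason"] = "short_trip"
    ok = ~is_open & ~incomplete & ~short
    boundary = out["pollen_total_mg"] == config.nectar_max_pollen_mg
    out.loc[ok & (out["pollen_total_mg"] < config.nectar_max_pollen_mg), "trip_type"] = "nectar"
    out.loc[ok & (out["pollen_total_mg"] > config.nectar_max_pollen_mg), "trip_type"] = "pollen"
    out.loc[ok & boundary, "trip_type"] = config.boundary_class
    n_boundary = int((ok & boundary).sum())
    if n_boundary:
        logger.info(
            "classify_and_filter: %d trips at the exact %g mg boundary assigned to %s",
            n_boundary,
            config.nectar_max_pollen_mg,
            config.boundary_class,
        )
    return out


def efficiency_table(
    trips: pd.DataFrame,
    weather: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-trip efficiency records (mg/min) for classified nectar/pollen trips.

    Adds ``eff_mg_per_min`` (nectar or pollen load over duration),
    ISO ``week_of_year``, ``experience_days`` (days since the bee's first
    recorded trip), and a date join onto daily weather when provided.
    Excluded trips never reach this table.
    """
    keep = trips[trips["trip_type"].isin(["nectar", "pollen"])].copy()
    keep["eff_mg_per_min"] = np.where(
        keep["trip_type"].eq("nectar"),
        keep["nectar_mg"] / keep["duration_min"],
        keep["pollen_total_mg"] / keep["duration_min"],
    )
    t_out = pd.to_datetime(keep["t_out"])
    iso = t_out.dt.isocalendar()
    keep["week_of_year"] = iso["week"].astype(int)
    keep["date"] = t_out.dt.date
    first_trip = t_out.groupby(keep["bee_id"]).transform("min")
    keep["experience_days"] = (t_out.dt.normalize() - first_trip.dt.normalize()).dt.days
    if weather is not None:
        wx = weather.copy()
        wx["date"] = pd.to_datetime(wx["date"]).dt.date
        before = keep["date"].nunique()
        keep = keep.merge(wx, on="date", how="left")
        missing = keep[wx.columns.drop("date")].isna().all(axis=1).sum()
        if missing:
            logger.info(
                "efficiency_table: %d of %d trip dates lack weather records",
                int(missing),
                before,
            )
    return keep.reset_index(drop=True)


def survival_and_effort(
    careers: pd.DataFrame,
    trips: pd.DataFrame,
    study_end: pd.Timestamp | str,
) -> pd.DataFrame:
    """Per-bee survival time and lifetime foraging effort from RFID trips.

    Survival runs from release to the bee's last read; bees never seen after
    release get 0 days with a flag.  A bee is presumed dead (event = 1) when
    its last read precedes ``study_end`` (colony euthanasia), otherwise it is
    administratively censored (event = 0).  ``n_trips_lifetime`` counts all
    complete RFID round trips regardless of weigh completeness.
    """
    study_end = pd.Timestamp(study_end)
    required = {"bee_id", "release_date"}
    if not required <= set(careers.columns):
        raise ValidationError(f"careers table needs columns {sorted(required)}")
    out = careers.copy()
    out["release_date"] = pd.to_datetime(out["release_date"])
    last_seen = (
        pd.concat([trips[["bee_id", "t_out"]].rename(columns={"t_out": "t"}),
                   trips[["bee_id", "t_in"]].rename(columns={"t_in": "t"})])
        .dropna()
        .groupby("bee_id")["t"]
        .max()
    )
    n_trips = trips[trips.get("status", "complete") == "complete"].groupby("bee_id").size()
    out["last_seen"] = out["bee_id"].map(last_seen)
    out["never_seen"] = out["last_seen"].isna()
    out["last_seen"] = out["last_seen"].fillna(out["release_date"])
    out["survival_days"] = (
        (out["last_seen"] - out["release_date"]).dt.total_seconds() / 86400.0
    ).clip(lower=0.0)
    out["event"] = (out["last_seen"] < study_end).astype(int)
    out.loc[out["event"] == 0, "survival_days"] = (
        (study_end - out.loc[out["event"] == 0, "release_date"]).dt.total_seconds() / 86400.0
    )
    out["n_trips_lifetime"] = out["bee_id"].map(n_trips).fillna(0).astype(int)
    return out


def kaplan_meier_summary(survival: pd.DataFrame) -> dict[str, float]:
    """Kaplan-Meier median survival (days) and cohort size."""
    from lifelines import KaplanMeierFitter

    km = KaplanMeierFitter()
    km.fit(survival["survival_days"], event_observed=survival["event"])
    return {
        "n": int(len(survival)),
        "n_events": int(survival["event"].sum()),
        "median_survival_days": float(km.median_survival_time_),
    }
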