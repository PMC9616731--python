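"""Synthetic-data generators for every pipeline input.

The generators emulate the study's data-collecting apparatus and the
statistical structure its analysis assumes, so that every downstream stage is
testable without field data:

* maze agents with a sliding-window short-term memory for recently visited
  arms (:func:`simulate_ram_bee`, :func:`simulate_cohort`);
* a seasonal foraging-efficiency process whose latent model is the inverse of
  the nectar analysis model — week trend, RAM score × week interaction, body
  size, quadratic experience, weather, bee and colony random effects
  (:func:`simulate_season`);
* week-correlated daily weather (:func:`simulate_weather`); and
* raw RFID/scale event logs that invert the trip-pairing stage
  (:func:`simulate_rfid_scale_logs`).

All generators are pure functions of their parameters and an explicit seed.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass
from datetime import date, datetime, timedelta
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from winshift.errors import ValidationError
from winshift.ram import DESIGNS, Design, VisitSequence

__all__ = [
    "AgentParams",
    "SeasonParams",
    "simulate_ram_bee",
    "simulate_cohort",
    "simulate_weather",
    "simulate_season",
    "simulate_rfid_scale_logs",
]


@dataclass(frozen=True)
class AgentParams:
    """A maze-foraging agent with a sliding-window short-term memory.

    The agent avoids the last ``memory_capacity`` *distinct* arms it visited;
    with probability ``lapse_rate`` (or when memory is empty) it instead moves
    according to ``movement_bias`` (default: uniform over the other arms).
    ``memory_capacity = n_arms - 1`` with no lapses is a perfect win-shift
    forager; ``memory_capacity = 0`` is a memoryless Markov mover.
    """

    memory_capacity: int
    n_arms: int = 4
    lapse_rate: float = 0.0
    movement_bias: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.memory_capacity <= self.n_arms:
            raise ValidationError(
                f"memory_capacity must be in 0..n_arms, got {self.memory_capacity}"
            )
        if not 0.0 <= self.lapse_rate <= 1.0:
            raise ValidationError(f"lapse_rate must be in [0, 1], got {self.lapse_rate}")
        if self.n_arms < 2:
            raise ValidationError(f"n_arms must be >= 2, got {self.n_arms}")
        if self.movement_bias is not None:
            bias = np.asarray(self.movement_bias, dtype=float)
            if bias.shape != (self.n_arms, self.n_arms):
                raise ValidationError("movement_bias must be n_arms x n_arms")
            object.__setattr__(self, "movement_bias", bias)


def _bias_row(params: AgentParams, current: int | None, rng: np.random.Generator) -> int:
    """Memoryless move from ``current`` (0-based); uniform-no-self by default."""
    n = params.n_arms
    if params.movement_bias is not None and current is not None:
        row = params.movement_bias[current]
        total = row.sum()
        if total <= 0:
            raise ValidationError("movement_bias row has zero mass")
        return int(rng.choice(n, p=row / total))
    if current is None:
        return int(rng.integers(n))
    others = [a for a in range(n) if a != current]
    return int(others[rng.integers(n - 1)])


def simulate_ram_bee(
    params: AgentParams,
    n_bouts: int,
    design: Design | str | None = "main",
    rng: np.random.Generator | None = None,
    bee_id: str = "agent",
    visit_cap: int | None = None,
    bout_offset: int = 0,
) -> list[VisitSequence]:
    """Simulate RAM bouts for one memory-window agent.

    Each bout starts on a random arm and ends when all arms have been visited
    or the visit cap (default ``12 * n_arms``) is reached.  Bout types follow
    the testing ``design`` (training bouts first, test bouts last); pass
    ``design=None`` to label every bout a test bout (free-running simulation).
    """
    rng = np.random.default_rng() if rng is None else rng
    design = DESIGNS[design] if isinstance(design, str) else design
    n = params.n_arms
    cap = 12 * n if visit_cap is None else visit_cap
    bouts = []
    for b in range(n_bouts):
        memory: list[int] = []  # last-m distinct arms, most recent last
        arms: list[int] = []
        visited: set[int] = set()
        current: int | None = None
        while len(visited) < n and len(arms) < cap:
            remembered = set(memory)
            allowed = [a for a in range(n) if a not in remembered]
            if (
                not allowed
                or not memory
                or (params.lapse_rate > 0 and rng.random() < params.lapse_rate)
            ):
                nxt = _bias_row(params, current, rng)
            else:
                nxt = int(allowed[rng.integers(len(allowed))])
            arms.append(nxt + 1)
            visited.add(nxt)
            if nxt in memory:
                memory.remove(nxt)
            memory.append(nxt)
            if params.memory_capacity == 0:
                memory.clear()
            else:
                del memory[: max(0, len(memory) - params.memory_capacity)]
            current = nxt
        bouts.append(
            VisitSequence(
                bee_id=bee_id,
                bout_index=bout_offset + b + 1,
                bout_type="test" if design is None else design.bout_type(bout_offset + b + 1),
                arms=tuple(arms),
                n_arms=n,
            )
        )
    return bouts


def simulate_cohort(
    n_bees: int = 20,
    n_arms: int = 4,
    design: Design | str = "main",
    memory_capacities: Sequence[int] = (0, 1, 2, 3),
    memory_probs: Sequence[float] | None = None,
    lapse_rate: float = 0.1,
    n_colonies: int = 4,
    rng: np.random.Generator | None = None,
    bee_prefix: str = "bee",
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, int]]:
    """Simulate a tested cohort: visit log, bee covariates, true memory sizes.

    Per-bee memory capacities are drawn from ``memory_capacities`` (uniformly
    unless ``memory_probs`` is given); body size (intertegular distance, mm)
    and age at release (days) are drawn from ranges typical of *B. terrestris*
    workers.  Returns ``(visits, bees, true_memory)`` where ``visits`` is in
    the visit-log CSV dialect and ``bees`` the covariate table.
    """
    rng = np.random.default_rng() if rng is None else rng
    design = DESIGNS[design] if isinstance(design, str) else design
    caps = [min(int(m), n_arms) for m in memory_capacities]
    visits_rows = []
    bee_rows = []
    true_memory: dict[str, int] = {}
    for i in range(n_bees):
        bee_id = f"{bee_prefix}{i + 1:03d}"
        colony_id = f"col{i % n_colonies + 1:02d}"
        m = int(rng.choice(caps, p=memory_probs))
        true_memory[bee_id] = m
        params = AgentParams(memory_capacity=m, n_arms=n_arms, lapse_rate=lapse_rate)
        bouts = simulate_ram_bee(params, design.n_bouts, design, rng, bee_id=bee_id)
        t0 = 0.0
        for bout in bouts:
            # visit gaps ~ exponential with a 10 s mean flight/handling time
            gaps = rng.exponential(10.0, size=len(bout.arms))
            times = t0 + np.cumsum(gaps)
            for j, (arm, ts) in enumerate(zip(bout.arms, times)):
                visits_rows.append(
                    (bee_id, colony_id, bout.bout_index, bout.bout_type, j + 1, arm, round(ts, 1))
                )
            t0 = times[-1] + 600.0  # inter-bout gap
        bee_rows.append(
            (
                bee_id,
                colony_id,
                round(float(rng.normal(4.5, 0.35)), 2),
                int(rng.integers(3, 15)),
                True,
            )
        )
    visits = pd.DataFrame(
        visits_rows,
        columns=[
            "bee_id",
            "colony_id",
            "bout_index",
            "bout_type",
            "visit_index",
            "arm_id",
            "timestamp_s",
        ],
    )
    bees = pd.DataFrame(
        bee_rows, columns=["bee_id", "colony_id", "size_mm", "age_at_release", "tested"]
    )
    return visits, bees, true_memory


def simulate_weather(
    start: str | date = "2019-04-01",
    n_days: int = 180,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Daily weather with a seasonal temperature sinusoid.

    Humidity is negatively correlated with temperature; wind is independent.
    Mimics daily means of hourly temperate-climate station records.
    """
    rng = np.random.default_rng() if rng is None else rng
    start = date.fromisoformat(start) if isinstance(start, str) else start
    dates = pd.date_range(start, periods=n_days, freq="D")
    doy = dates.dayofyear.to_numpy()
    temp = 11.0 + 7.0 * np.sin(2 * np.pi * (doy - 105) / 365.0) + rng.normal(0, 1.8, n_days)
    hum = np.clip(72.0 - 1.6 * (temp - temp.mean()) + rng.normal(0, 6.0, n_days), 20, 100)
    wind = rng.gamma(shape=2.0, scale=1.7, size=n_days)
    return pd.DataFrame(
        {
            "date": dates.date,
            "temp_C": np.round(temp, 2),
            "humidity_pct": np.round(hum, 1),
            "wind_ms": np.round(wind, 2),
        }
    )


@dataclass(frozen=True)
class SeasonParams:
    """Generative parameters for one synthetic foraging season.

    The latent per-trip nectar efficiency is

    ``eta = baseline(week) + beta_ram * s + beta_int * s * week + beta_size * size_c
    + experience polynomial + beta_weather * weather_resid + bee and colony
    random effects + residual``

    with ``s`` the log(1+RAM-score).  Variance components default so the
    marginal SD of ``eta`` is ~1, putting the latent scale in one-to-one
    correspondence with the rank-normalized (ORQ) analysis scale; observed
    mg/min is an affine map of ``eta`` spanning roughly the −7..15 mg/min
    range reported for wild foragers, with an optional monotone warp.
    ``beta_ram`` defaults to ``-beta_int * reversal_week`` so the RAM-score
    effect reverses sign mid-season (week 26).
    """

    n_colonies: int = 12
    bees_per_colony: int = 11
    start_week: int = 14
    stagger_weeks: int = 2
    days_observed: int = 8
    trips_per_day_lambda: float = 1.8
    year: int = 2019

    beta_int: float = 0.05
    reversal_week: float = 26.0
    beta_ram: float | None = None
    beta_size: float = 0.34
    beta_age: float = -0.02
    beta_exp1: float = 0.06
    beta_exp2: float = -0.004
    beta_weather: float = 0.12
    baseline_level: float = 0.0
    baseline_week_slope: float = -0.035

    bee_intercept_sd: float = 0.30
    bee_slope_sd: float = 0.02
    bee_re_corr: float = -0.2
    colony_sd: float = 0.15
    residual_sd: float = 0.90

    eff_center_mg_min: float = 2.5
    eff_scale_mg_min: float = 3.2
    warp: Callable[[np.ndarray], np.ndarray] | None = None

    p_short_trip: float = 0.12
    p_pollen_trip: float = 0.25
    scale_noise_sd_mg: float = 2.0
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("bee_intercept_sd", "bee_slope_sd", "colony_sd", "residual_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if not 1 <= self.start_week <= 52:
            raise ValidationError("start_week must be within 1..52")
        if self.beta_ram is None:
            object.__setattr__(self, "beta_ram", -self.beta_int * self.reversal_week)

    def baseline(self, week: np.ndarray | float) -> np.ndarray | float:
        return self.baseline_level + self.baseline_week_slope * (
            np.asarray(week, dtype=float) - 26.0
        )


def _iso_week_monday(year: int, week: int) -> date:
    return date.fromisocalendar(year, week, 1)


def simulate_season(
    params: SeasonParams,
    bees: pd.DataFrame,
    ram_scores: pd.DataFrame,
    weather: pd.DataFrame | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Simulate one field season of foraging trips for a scored cohort.

    ``bees`` needs columns bee_id, colony_id, size_mm, age_at_release;
    ``ram_scores`` needs bee_id and ram_score_log1p (e.g. from the scoring
    stage).  Colonies are released on a staggered schedule, each bee foraging
    on ``days_observed`` days within its colony's two recording weeks.  Trip
    durations and pollen loads deliberately include sub-7-min trips and
    >3 mg pollen loads so downstream filters are exercised.  Returns the trip
    table (with ``true_eta`` per trip) and a truth record holding every
    coefficient and realized random effect.
    """
    rng = np.random.default_rng(params.seed) if rng is None else rng
    if params.n_colonies < 1 or params.bees_per_colony < 1:
        raise ValidationError("need at least one colony and one bee")
    bees = bees.merge(ram_scores[["bee_id", "ram_score_log1p"]], on="bee_id", how="inner")
    if bees.empty:
        raise ValidationError("no bees with RAM scores to simulate")

    if weather is None:
        first_day = _iso_week_monday(params.year, params.start_week) - timedelta(days=7)
        horizon = 7 * (params.n_colonies * params.stagger_weeks + 6) + 14
        weather = simulate_weather(first_day, horizon, rng)
    # weather covariate enters as the week-residualized first PC, exactly as
    # the analysis defines it
    from winshift.seasonal import residualize_on_week, weather_composite

    wx = weather.copy()
    comp = weather_composite(wx)
    wx = wx.assign(weather_score=comp.scores)
    wdate = pd.to_datetime(wx["date"])
    wx["week"] = wdate.dt.isocalendar().week.astype(int)
    wx["weather_resid"] = residualize_on_week(
        wx["weather_score"].to_numpy(), wx["week"].to_numpy()
    )
    weather_by_date = wx.set_index(wdate.dt.date)["weather_resid"]

    colonies = sorted(bees["colony_id"].unique())
    release_week = {
        c: params.start_week + params.stagger_weeks * i for i, c in enumerate(colonies)
    }
    b_colony = {c: rng.normal(0, params.colony_sd) for c in colonies}

    # correlated bee intercept/experience-slope random effects
    cov = np.array(
        [
            [params.bee_intercept_sd**2,
             params.bee_re_corr * params.bee_intercept_sd * params.bee_slope_sd],
            [params.bee_re_corr * params.bee_intercept_sd * params.bee_slope_sd,
             params.bee_slope_sd**2],
        ]
    )
    bee_re = {
        row.bee_id: rng.multivariate_normal([0.0, 0.0], cov)
        for row in bees.itertuples()
    }

    size_center = float(bees["size_mm"].mean())
    age_center = float(bees["age_at_release"].mean())
    rows = []
    for row in bees.itertuples():
        wk = release_week[row.colony_id]
        if wk > 52:
            raise ValidationError("stagger schedule runs past week 52")
        release = _iso_week_monday(params.year, wk)
        obs_days = sorted(
            rng.choice(np.arange(14), size=min(params.days_observed, 14), replace=False)
        )
        first_day_offset = obs_days[0]
        b0, b1 = bee_re[row.bee_id]
        for d in obs_days:
            day = release + timedelta(days=int(d))
            n_trips = rng.poisson(params.trips_per_day_lambda)
            t = datetime.combine(day, datetime.min.time()) + timedelta(hours=9)
            for _ in range(n_trips):
                experience = float(d - first_day_offset)
                week = float(day.isocalendar().week)
                short = rng.random() < params.p_short_trip
                pollen_trip = (not short) and rng.random() < params.p_pollen_trip
                if short:
                    duration = float(rng.uniform(2.0, 6.9))
                else:
                    duration = float(np.clip(rng.lognormal(math.log(25.0), 0.45), 7.05, 180))
                wres = float(weather_by_date.get(day, 0.0))
                s = float(row.ram_score_log1p)
                eta = (
                    float(params.baseline(week))
                    + params.beta_ram * s
                    + params.beta_int * s * week
                    + params.beta_size * (row.size_mm - size_center)
                    + params.beta_age * (row.age_at_release - age_center)
                    + params.beta_exp1 * experience
                    + params.beta_exp2 * experience**2
                    + params.beta_weather * wres
                    + b_colony[row.colony_id]
                    + b0
                    + b1 * experience
                    + rng.normal(0, params.residual_sd)
                )
                latent = params.eff_center_mg_min + params.eff_scale_mg_min * eta
                nectar_eff = float(params.warp(latent)) if params.warp else float(latent)
                nectar_mg = nectar_eff * duration
                if pollen_trip:
                    pollen_oneleg = float(rng.uniform(2.0, 10.0))
                else:
                    pollen_oneleg = float(rng.uniform(0.0, 1.4)) if rng.random() < 0.1 else 0.0
                w_out = float(rng.normal(185.0, 4.0))
                t_out = t + timedelta(minutes=float(rng.uniform(0, 10)))
                t_in = t_out + timedelta(minutes=duration)
                rows.append(
                    {
                        "bee_id": row.bee_id,
                        "colony_id": row.colony_id,
                        "t_out": t_out,
                        "t_in": t_in,
                        "duration_min": duration,
                        "w_out_mg": w_out,
                        "w_in_mg": w_out + nectar_mg + 2 * pollen_oneleg,
                        "pollen_oneleg_mg": pollen_oneleg,
                        "week_of_year": int(week),
                        "experience_days": int(experience),
                        "true_eta": eta,
                        "true_nectar_eff": nectar_eff,
                    }
                )
                t = t_in + timedelta(minutes=float(rng.uniform(10, 45)))
    trips = pd.DataFrame(rows).sort_values(["bee_id", "t_out"]).reset_index(drop=True)
    truth = {
        "params": {
            k: v
            for k, v in asdict(params).items()
            if isinstance(v, (int, float, str, type(None)))
        },
        "bee_random_effects": {k: list(map(float, v)) for k, v in bee_re.items()},
        "colony_random_effects": {k: float(v) for k, v in b_colony.items()},
        "release_week": release_week,
        "size_center": size_center,
        "age_center": age_center,
    }
    return trips, truth


def simulate_rfid_scale_logs(
    trips: pd.DataFrame,
    rng: np.random.Generator | None = None,
    noise_sd_mg: float = 0.0,
    duplicate_reads: bool = False,
    duplicate_gap_s: float = 2.0,
    weigh_offset_s: float = 15.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Emit raw RFID and weigh-event logs whose parsing recovers ``trips``.

    This is the exact inverse of the trip-pairing stage: each trip becomes an
    out/in RFID read pair plus out/in weigh events.  ``duplicate_reads`` adds
    an echo read shortly after each true read (inside the default debounce
    window); ``noise_sd_mg`` adds Gaussian scale noise (the field scales were
    accurate to about ±2 mg).  Overlapping trips for one bee are an error.
    """
    rng = np.random.default_rng() if rng is None else rng
    required = {"bee_id", "t_out", "t_in", "w_out_mg", "w_in_mg", "pollen_oneleg_mg"}
    missing = required - set(trips.columns)
    if missing:
        raise ValidationError(f"trips table missing columns: {sorted(missing)}")
    for bee, grp in trips.groupby("bee_id", sort=False):
        g = grp.sort_values("t_out")
        if (g["t_out"].shift(-1) < g["t_in"]).any():
            raise ValidationError(f"bee {bee} has overlapping trips")
    rfid_rows = []
    weigh_rows = []
    for r in trips.itertuples():
        t_out = pd.Timestamp(r.t_out)
        t_in = pd.Timestamp(r.t_in)
        for direction, t in (("out", t_out), ("in", t_in)):
            rfid_rows.append((r.bee_id, t, direction))
            if duplicate_reads:
                rfid_rows.append((r.bee_id, t + pd.Timedelta(seconds=duplicate_gap_s), direction))
        w_out = r.w_out_mg + (rng.normal(0, noise_sd_mg) if noise_sd_mg else 0.0)
        w_in = r.w_in_mg + (rng.normal(0, noise_sd_mg) if noise_sd_mg else 0.0)
        weigh_rows.append(
            (r.bee_id, t_out + pd.Timedelta(seconds=weigh_offset_s), "out", w_out, 0.0)
        )
        weigh_rows.append(
            (r.bee_id, t_in - pd.Timedelta(seconds=weigh_offset_s), "in", w_in, r.pollen_oneleg_mg)
        )
    rfid = (
        pd.DataFrame(rfid_rows, columns=["tag_id", "timestamp", "direction"])
        .sort_values(["tag_id", "timestamp"], kind="mergesort")
        .reset_index(drop=True)
    )
    weighs = (
        pd.DataFrame(
            weigh_rows,
            columns=["tag_id", "timestamp", "direction", "mass_mg", "pollen_oneleg_mg"],
        )
        .sort_values(["tag_id", "timestamp"], kind="mergesort")
        .reset_index(drop=True)
    )
    return rfid, weighs
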