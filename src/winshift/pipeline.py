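"""End-to-end pipeline orchestration (simulate → score → validate → trips → analyze)."""

from __future__ import annotations

import hashlib
import logging
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from winshift import io as wio
from winshift import nullmodels, ram, seasonal, synth, trips as trips_mod
from winshift.config import RunConfig
from winshift.errors import WinshiftError

logger = logging.getLogger(__name__)


def _file_hash(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def stage_simulate(config: RunConfig, outdir: Path, seed: int) -> dict:
    """Generate the full synthetic fixture set into ``outdir``."""
    rng = np.random.default_rng(seed)
    design = ram.DESIGNS[config.design]
    caps = tuple(range(min(config.n_arms, 4)))
    visits, bees, true_memory = synth.simulate_cohort(
        n_bees=config.n_bees,
        n_arms=config.n_arms,
        design=design,
        memory_capacities=caps,
        lapse_rate=config.lapse_rate,
        n_colonies=config.n_colonies,
        rng=rng,
    )
    wio.write_visits_csv(visits, outdir / "visits.csv")
    bees.to_csv(outdir / "bees.csv", index=False)

    # score internally to drive the season generator
    seqs = wio.visits_to_sequences(visits, n_arms=config.n_arms)
    scores = pd.DataFrame(
        [
            {
                "bee_id": bee,
                "ram_score": (rs := ram.ram_score(bouts, design.n_test)).score,
                "ram_score_log1p": rs.score_log1p,
                "n_bouts": len(bouts),
            }
            for bee, bouts in seqs.items()
        ]
    )
    params = synth.SeasonParams(**config.season) if config.season else synth.SeasonParams()
    n_colonies = bees["colony_id"].nunique()
    params = replace(params, n_colonies=n_colonies, bees_per_colony=max(1, config.n_bees // n_colonies))
    weather = synth.simulate_weather(rng=rng)
    trips_true, truth = synth.simulate_season(params, bees, scores, weather=weather, rng=rng)
    rfid, weighs = synth.simulate_rfid_scale_logs(trips_true, rng=rng)
    rfid.to_csv(outdir / "rfid.csv", index=False)
    weighs.to_csv(outdir / "weights.csv", index=False)
    weather.to_csv(outdir / "weather.csv", index=False)
    truth["true_memory"] = true_memory
    wio.write_json(truth, outdir / "truth.json")
    return {
        "n_bees": int(len(bees)),
        "n_visits": int(len(visits)),
        "n_true_trips": int(len(trips_true)),
        "files": ["visits.csv", "bees.csv", "rfid.csv", "weights.csv", "weather.csv", "truth.json"],
    }


def stage_score(visits_path: Path, design: str, n_arms: int, out_path: Path) -> dict:
    visits = wio.read_visits_csv(visits_path)
    d = ram.DESIGNS[design]
    seqs = wio.visits_to_sequences(visits, n_arms=n_arms)
    rows = []
    for bee, bouts in seqs.items():
        rs = ram.ram_score(bouts, d.n_test)
        rows.append(
            {
                "bee_id": bee,
                "ram_score": rs.score,
                "ram_score_log1p": rs.score_log1p,
                "n_bouts": len(bouts),
            }
        )
    scores = pd.DataFrame(rows)
    wio.write_scores_csv(scores, out_path)
    return {"n_bees": int(len(scores)), "mean_ram_score": float(scores["ram_score"].mean())}


def stage_validate(
    visits_path: Path,
    bees_path: Path,
    out_path: Path,
    n_arms: int,
    replicates: int,
    statistic: str,
    null: str,
    seed: int,
) -> dict:
    visits = wio.read_visits_csv(visits_path)
    bees = wio.read_bees_csv(bees_path)
    seqs = wio.visits_to_sequences(visits, n_arms=n_arms)
    test_bouts = {
        bee: [b for b in bouts if b.bout_type == "test"] for bee, bouts in seqs.items()
    }
    result = nullmodels.run_validation(
        test_bouts,
        bees,
        n_arms=n_arms,
        n_replicates=replicates,
        statistic=statistic,
        null=null,
        seed=seed,
    )
    summary = result.to_dict()
    wio.write_json(summary, out_path)
    null_csv = out_path.with_suffix(".csv")
    pd.DataFrame(
        {"replicate_id": np.arange(len(result.values)), "value": result.values}
    ).assign(statistic=result.statistic_name).to_csv(null_csv, index=False)
    return summary


def stage_trips(
    rfid_path: Path,
    weighs_path: Path,
    out_path: Path,
    config: RunConfig,
    weather_path: Path | None = None,
    bees_path: Path | None = None,
) -> dict:
    rfid = wio.read_rfid_csv(rfid_path)
    weighs = wio.read_weigh_csv(weighs_path)
    tcfg = trips_mod.TripConfig(
        debounce_s=config.debounce_s,
        weigh_match_tol_s=config.weigh_match_tol_s,
        nectar_max_pollen_mg=config.nectar_max_pollen_mg,
        min_duration_min=config.min_duration_min,
    )
    paired, issues = trips_mod.pair_events_to_trips(rfid, weighs, tcfg)
    loaded = trips_mod.derive_loads(paired)
    classified = trips_mod.classify_and_filter(loaded, tcfg)
    weather = wio.read_weather_csv(weather_path) if weather_path else None
    if weather is not None:
        comp = seasonal.weather_composite(weather)
        weather = weather.assign(weather_score=comp.scores)
        weeks = pd.to_datetime(weather["date"]).dt.isocalendar().week.astype(int)
        weather["weather_resid"] = seasonal.residualize_on_week(
            weather["weather_score"].to_numpy(), weeks.to_numpy()
        )
    eff = trips_mod.efficiency_table(classified, weather)
    classified.to_csv(out_path, index=False)
    eff_path = out_path.with_name(out_path.stem + "_efficiency.csv")
    eff.to_csv(eff_path, index=False)
    counts = classified["trip_type"].value_counts().to_dict()
    info = {
        "n_paired": int(len(classified)),
        "n_issues": len(issues),
        "trip_type_counts": {k: int(v) for k, v in counts.items()},
        "efficiency_rows": int(len(eff)),
    }
    if bees_path is not None:
        careers = wio.read_bees_csv(bees_path)
        if "release_date" not in careers.columns:
            first = classified.groupby("bee_id")["t_out"].min().dt.normalize()
            careers = careers.assign(
                release_date=careers["bee_id"].map(first)
            ).dropna(subset=["release_date"])
        surv = trips_mod.survival_and_effort(
            careers, classified, study_end=classified["t_in"].max()
        )
        surv.to_csv(out_path.with_name(out_path.stem + "_survival.csv"), index=False)
        info["survival"] = trips_mod.kaplan_meier_summary(surv)
    return info


def stage_analyze(
    efficiency_path: Path,
    scores_path: Path,
    bees_path: Path,
    outdir: Path,
    analyses: tuple[str, ...],
) -> dict:
    eff = pd.read_csv(efficiency_path)
    scores = wio.read_scores_csv(scores_path)
    bees = wio.read_bees_csv(bees_path)
    results = {}
    for analysis in analyses:
        frame = seasonal.build_analysis_frame(
            analysis, efficiency=eff, scores=scores, bees=bees
        )
        specs = seasonal.candidate_set(analysis)
        sel = seasonal.fit_and_select(specs, frame)
        wio.write_json(
            {
                "criterion": sel.criterion,
                "selected": sel.selected.spec.name,
                "fits": [f.to_dict() for f in sel.fits],
            },
            outdir / f"fits_{analysis}.json",
        )
        (outdir / f"selection_{analysis}.txt").write_text("\n".join(sel.trace) + "\n")
        summary = {"selected": sel.selected.spec.name, "criterion": sel.criterion}
        if "week:" in " ".join(sel.selected.spec.fixed):
            weeks = np.arange(frame["week"].min(), frame["week"].max() + 1)
            focal = seasonal._FOCAL_TERM[analysis]
            prof = seasonal.interaction_profile(sel.selected, weeks, focal=focal)
            prof.table.to_csv(outdir / f"profile_{analysis}.csv", index=False)
            summary["reversal_week"] = prof.reversal_week
        results[analysis] = summary
    return results


def synthetic_study(
    seed: int,
    season_params: "synth.SeasonParams | None" = None,
    n_bees: int = 132,
    n_colonies: int = 12,
    n_arms: int = 4,
) -> dict:
    """One full in-memory synthetic study: cohort → scores → season → trips.

    Convenience wrapper used by simulation experiments: returns a dict with
    the scored cohort, the true trip table, the classified trips, the
    efficiency table (with weather covariates), and the nectar analysis
    frame, all generated from one seed.
    """
    rng = np.random.default_rng(seed)
    visits, bees, true_memory = synth.simulate_cohort(
        n_bees=n_bees, n_arms=n_arms, n_colonies=n_colonies, rng=rng
    )
    seqs = wio.visits_to_sequences(visits, n_arms)
    scores = pd.DataFrame(
        [
            {
                "bee_id": bee,
                "ram_score": (rs := ram.ram_score(bouts, 3)).score,
                "ram_score_log1p": rs.score_log1p,
                "n_bouts": len(bouts),
            }
            for bee, bouts in seqs.items()
        ]
    )
    params = season_params or synth.SeasonParams()
    weather = synth.simulate_weather(rng=rng)
    trips_true, truth = synth.simulate_season(params, bees, scores, weather=weather, rng=rng)
    classified = trips_mod.classify_and_filter(
        trips_mod.derive_loads(trips_true.assign(status="complete"))
    )
    eff = trips_mod.efficiency_table(classified, weather)
    comp = seasonal.weather_composite(eff)
    eff = eff.assign(weather_score=comp.scores)
    eff["weather_resid"] = seasonal.residualize_on_week(
        eff["weather_score"].to_numpy(), eff["week_of_year"].to_numpy()
    )
    frame = seasonal.build_analysis_frame("nectar", efficiency=eff, scores=scores, bees=bees)
    return {
        "visits": visits,
        "bees": bees,
        "true_memory": true_memory,
        "scores": scores,
        "weather": weather,
        "trips": trips_true,
        "classified": classified,
        "efficiency": eff,
        "nectar_frame": frame,
        "truth": truth,
        "params": params,
    }


def run_pipeline(config: RunConfig, outdir: Path, seed: int | None = None) -> dict:
    """Execute the configured stages, writing artifacts and a run manifest.

    A stage failure aborts the run; the manifest (written regardless) marks
    the stages completed, input hashes, seeds and row counts.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = config.seed if seed is None else seed
    manifest: dict = {
        "config": config.to_dict(),
        "config_hash": config.hash(),
        "seed": seed,
        "stages": {},
        "completed": [],
    }
    try:
        for stage in config.stages:
            if stage == "simulate":
                info = stage_simulate(config, outdir, seed)
            elif stage == "score":
                info = stage_score(
                    outdir / "visits.csv", config.design, config.n_arms, outdir / "scores.csv"
                )
            elif stage == "validate":
                info = stage_validate(
                    outdir / "visits.csv",
                    outdir / "bees.csv",
                    outdir / "null_summary.json",
                    config.n_arms,
                    config.replicates,
                    config.statistic,
                    config.null,
                    seed + 1,
                )
            elif stage == "trips":
                info = stage_trips(
                    outdir / "rfid.csv",
                    outdir / "weights.csv",
                    outdir / "trips.csv",
                    config,
                    outdir / "weather.csv" if (outdir / "weather.csv").exists() else None,
                )
            elif stage == "analyze":
                info = stage_analyze(
                    outdir / "trips_efficiency.csv",
                    outdir / "scores.csv",
                    outdir / "bees.csv",
                    outdir,
                    config.analyses,
                )
            else:
                raise WinshiftError(f"unknown stage {stage!r}")
            manifest["stages"][stage] = info
            manifest["completed"].append(stage)
    finally:
        manifest["input_hashes"] = {
            p.name: _file_hash(p)
            for p in sorted(outdir.glob("*.csv"))
        }
        wio.write_json(manifest, outdir / "manifest.json")
    return manifest
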