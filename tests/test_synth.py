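"""Synthetic-data generators: agents, cohorts, weather, seasons, event logs."""

import numpy as np
import pandas as pd
import pytest

from winshift.errors import ValidationError
from winshift.ram import score_bout
from winshift.synth import (
    AgentParams,
    SeasonParams,
    simulate_cohort,
    simulate_ram_bee,
    simulate_rfid_scale_logs,
    simulate_season,
    simulate_weather,
)
from winshift.trips import TripConfig, pair_events_to_trips


class TestAgents:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    @pytest.mark.parametrize("n_arms", [4, 8])
    def test_perfect_memory_never_errs(self, seed, n_arms):
        params = AgentParams(memory_capacity=n_arms - 1, n_arms=n_arms, lapse_rate=0.0)
        bouts = simulate_ram_bee(params, 20, None, np.random.default_rng(seed))
        assert all(score_bout(b).errors == 0 for b in bouts)
        assert all(score_bout(b).completed for b in bouts)

    def test_memoryless_agent_matches_markov_oracle(self, rng):
        # uniform-no-self movement: absorbing-chain mean of 2.5 errors/bout
        params = AgentParams(memory_capacity=0, n_arms=4)
        bouts = simulate_ram_bee(params, 4000, None, rng)
        errs = np.array([score_bout(b).errors for b in bouts])
        assert abs(errs.mean() - 2.5) < 3 * errs.std() / np.sqrt(len(errs))

    def test_mean_errors_strictly_decrease_with_memory(self, rng):
        means = []
        for m in (0, 1, 2, 3):
            params = AgentParams(memory_capacity=m, n_arms=4, lapse_rate=0.0)
            bouts = simulate_ram_bee(params, 2000, None, rng)
            means.append(np.mean([score_bout(b).errors for b in bouts]))
        assert all(a > b for a, b in zip(means, means[1:]))

    def test_invalid_params_rejected(self):
        with pytest.raises(ValidationError):
            AgentParams(memory_capacity=5, n_arms=4)
        with pytest.raises(ValidationError):
            AgentParams(memory_capacity=1, n_arms=4, lapse_rate=1.5)


class TestCohort:
    def test_validation_layout_shapes(self):
        visits, bees, memory = simulate_cohort(
            n_bees=20,
            n_arms=8,
            design="validation",
            n_colonies=4,
            rng=np.random.default_rng(0),
        )
        assert bees.shape[0] == 20
        assert bees["colony_id"].nunique() == 4
        per_bee = visits.groupby("bee_id")["bout_index"].nunique()
        assert (per_bee == 20).all()  # 10 training + 10 test
        assert visits[visits.bout_type == "test"].groupby("bee_id")["bout_index"].nunique().eq(10).all()
        assert visits["arm_id"].between(1, 8).all()

    def test_seeded_output_is_byte_identical(self, tmp_path):
        outs = []
        for run in range(2):
            visits, bees, _ = simulate_cohort(n_bees=6, rng=np.random.default_rng(5))
            path = tmp_path / f"v{run}.csv"
            visits.to_csv(path, index=False)
            outs.append(path.read_bytes())
        assert outs[0] == outs[1]

    def test_degenerate_memory_distribution_gives_zero_scores(self):
        from winshift import ram
        from winshift.io import visits_to_sequences

        visits, _, memory = simulate_cohort(
            n_bees=6,
            memory_capacities=(3,),
            lapse_rate=0.0,
            rng=np.random.default_rng(1),
        )
        assert set(memory.values()) == {3}
        for bee, bouts in visits_to_sequences(visits, 4).items():
            assert ram.ram_score(bouts, 3).score == 0.0

    def test_ram_score_declines_with_memory_capacity(self):
        # rank correlation across bees spanning the memory range
        from scipy.stats import spearmanr

        from winshift import ram
        from winshift.io import visits_to_sequences

        visits, _, memory = simulate_cohort(
            n_bees=50, lapse_rate=0.05, rng=np.random.default_rng(2)
        )
        seqs = visits_to_sequences(visits, 4)
        scores = {b: ram.ram_score(s, 3).score for b, s in seqs.items()}
        ms = [memory[b] for b in scores]
        rho = spearmanr(ms, list(scores.values())).statistic
        assert rho < -0.8


class TestWeather:
    def test_temperature_humidity_anticorrelated(self):
        wx = simulate_weather(n_days=180, rng=np.random.default_rng(0))
        assert np.corrcoef(wx["temp_C"], wx["humidity_pct"])[0, 1] < 0

    def test_seeded_weather_is_identical(self):
        a = simulate_weather(rng=np.random.default_rng(3))
        b = simulate_weather(rng=np.random.default_rng(3))
        pd.testing.assert_frame_equal(a, b)

    def test_first_component_dominance_within_bounds(self):
        from winshift.seasonal import weather_composite

        wx = simulate_weather(n_days=200, rng=np.random.default_rng(4))
        comp = weather_composite(wx)
        assert 1 / 3 < comp.variance_explained < 1.0


def _tiny_cohort(seed=0, n_bees=8):
    rng = np.random.default_rng(seed)
    visits, bees, _ = simulate_cohort(n_bees=n_bees, n_colonies=2, rng=rng)
    from winshift import ram
    from winshift.io import visits_to_sequences

    scores = pd.DataFrame(
        [
            {
                "bee_id": b,
                "ram_score": (r := ram.ram_score(s, 3)).score,
                "ram_score_log1p": r.score_log1p,
            }
            for b, s in visits_to_sequences(visits, 4).items()
        ]
    )
    return bees, scores


class TestSeason:
    def test_zero_effects_zero_noise_reduces_to_baseline(self):
        bees, scores = _tiny_cohort()
        params = SeasonParams(
            n_colonies=2,
            bees_per_colony=4,
            beta_int=0.0,
            beta_ram=0.0,
            beta_size=0.0,
            beta_age=0.0,
            beta_exp1=0.0,
            beta_exp2=0.0,
            beta_weather=0.0,
            bee_intercept_sd=0.0,
            bee_slope_sd=0.0,
            colony_sd=0.0,
            residual_sd=0.0,
        )
        trips, truth = simulate_season(params, bees, scores, rng=np.random.default_rng(0))
        expected = params.baseline(trips["week_of_year"].to_numpy())
        assert np.allclose(trips["true_eta"], expected)
        assert np.allclose(
            trips["true_nectar_eff"],
            params.eff_center_mg_min + params.eff_scale_mg_min * expected,
        )

    def test_seeded_season_is_reproducible(self):
        bees, scores = _tiny_cohort()
        params = SeasonParams(n_colonies=2, bees_per_colony=4, residual_sd=0.0)
        a, truth_a = simulate_season(params, bees, scores, rng=np.random.default_rng(7))
        b, truth_b = simulate_season(params, bees, scores, rng=np.random.default_rng(7))
        pd.testing.assert_frame_equal(a, b)
        assert truth_a["colony_random_effects"] == truth_b["colony_random_effects"]

    def test_latent_eta_reconstructs_from_truth_record(self):
        # with residual off, eta is an exact function of the stored effects
        bees, scores = _tiny_cohort()
        params = SeasonParams(
            n_colonies=2, bees_per_colony=4, residual_sd=0.0, beta_weather=0.0
        )
        trips, truth = simulate_season(params, bees, scores, rng=np.random.default_rng(9))
        merged = trips.merge(bees, on=["bee_id", "colony_id"]).merge(
            scores[["bee_id", "ram_score_log1p"]], on="bee_id"
        )
        s = merged["ram_score_log1p"].to_numpy()
        exp = merged["experience_days"].to_numpy().astype(float)
        b0 = merged["bee_id"].map({k: v[0] for k, v in truth["bee_random_effects"].items()})
        b1 = merged["bee_id"].map({k: v[1] for k, v in truth["bee_random_effects"].items()})
        bc = merged["colony_id"].map(truth["colony_random_effects"])
        eta = (
            params.baseline(merged["week_of_year"].to_numpy())
            + params.beta_ram * s
            + params.beta_int * s * merged["week_of_year"].to_numpy()
            + params.beta_size * (merged["size_mm"] - truth["size_center"]).to_numpy()
            + params.beta_age * (merged["age_at_release"] - truth["age_center"]).to_numpy()
            + params.beta_exp1 * exp
            + params.beta_exp2 * exp**2
            + b0.to_numpy()
            + b1.to_numpy() * exp
            + bc.to_numpy()
        )
        assert np.allclose(eta, merged["true_eta"].to_numpy(), atol=1e-9)

    def test_filters_are_exercised_by_design(self):
        bees, scores = _tiny_cohort(n_bees=16)
        params = SeasonParams(n_colonies=2, bees_per_colony=8)
        trips, _ = simulate_season(params, bees, scores, rng=np.random.default_rng(3))
        assert (trips["duration_min"] < 7).any()
        assert (2 * trips["pollen_oneleg_mg"] > 3).any()


class TestRfidScaleLogs:
    def _trips(self, n=60, seed=0):
        bees, scores = _tiny_cohort(seed)
        params = SeasonParams(n_colonies=2, bees_per_colony=4)
        trips, _ = simulate_season(params, bees, scores, rng=np.random.default_rng(seed))
        return trips.head(n)

    def test_lossless_round_trip(self):
        trips = self._trips()
        rfid, weighs = simulate_rfid_scale_logs(trips)
        recovered, issues = pair_events_to_trips(rfid, weighs)
        assert issues == []
        rec = recovered.sort_values(["bee_id", "t_out"]).reset_index(drop=True)
        exp = trips.sort_values(["bee_id", "t_out"]).reset_index(drop=True)
        assert len(rec) == len(exp)
        for col in ("w_out_mg", "w_in_mg", "pollen_oneleg_mg"):
            assert np.allclose(rec[col], exp[col])
        assert (rec["t_out"].to_numpy() == exp["t_out"].to_numpy()).all()
        assert (rec["t_in"].to_numpy() == exp["t_in"].to_numpy()).all()

    def test_duplicate_reads_survive_default_debounce(self):
        trips = self._trips()
        rfid, weighs = simulate_rfid_scale_logs(trips, duplicate_reads=True)
        recovered, _ = pair_events_to_trips(rfid, weighs, TripConfig())
        assert len(recovered) == len(trips)
        rec = recovered.sort_values(["bee_id", "t_out"]).reset_index(drop=True)
        exp = trips.sort_values(["bee_id", "t_out"]).reset_index(drop=True)
        assert (rec["t_out"].to_numpy() == exp["t_out"].to_numpy()).all()

    def test_scale_noise_propagates_as_gaussian_differences(self):
        trips = self._trips(n=500, seed=1)
        if len(trips) < 400:  # ensure enough rows from the generator
            trips = pd.concat([trips] * 2, ignore_index=True)
            trips["bee_id"] = [f"{b}_{i//len(trips.bee_id.unique())}" for i, b in enumerate(trips.bee_id)]
        rfid, weighs = simulate_rfid_scale_logs(
            trips, rng=np.random.default_rng(2), noise_sd_mg=2.0
        )
        recovered, _ = pair_events_to_trips(rfid, weighs)
        rec = recovered.sort_values(["bee_id", "t_out"]).reset_index(drop=True)
        exp = trips.sort_values(["bee_id", "t_out"]).reset_index(drop=True)
        nectar_err = (
            (rec["w_in_mg"] - rec["w_out_mg"]) - (exp["w_in_mg"] - exp["w_out_mg"])
        ).to_numpy()
        # difference of two independent N(0, 2mg) errors: sd = 2*sqrt(2)
        sd = 2 * np.sqrt(2)
        assert (np.abs(nectar_err) < 3 * sd).mean() >= 0.99

    def test_overlapping_trips_are_rejected(self):
        t0 = pd.Timestamp("2019-05-06 09:00")
        trips = pd.DataFrame(
            {
                "bee_id": ["b1", "b1"],
                "t_out": [t0, t0 + pd.Timedelta(minutes=5)],
                "t_in": [t0 + pd.Timedelta(minutes=30), t0 + pd.Timedelta(minutes=40)],
                "w_out_mg": [100.0, 100.0],
                "w_in_mg": [110.0, 110.0],
                "pollen_oneleg_mg": [0.0, 0.0],
            }
        )
        with pytest.raises(ValidationError, match="overlap"):
            simulate_rfid_scale_logs(trips)
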