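"""ORQ normalization, weather composite, smoothing, and model selection."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from winshift.errors import ValidationError
from winshift.seasonal import (
    FitResult,
    ModelSpec,
    OrqTransform,
    aic,
    aicc,
    build_analysis_frame,
    candidate_set,
    fit_and_select,
    interaction_profile,
    orq_fit_transform,
    residualize_on_week,
    select_best,
    weather_composite,
)


class TestOrq:
    def test_three_point_closed_form(self):
        _, z = orq_fit_transform([1.0, 2.0, 3.0])
        expected = norm.ppf([0.25, 0.5, 0.75])
        assert np.allclose(z, expected)
        assert z[0] == pytest.approx(-0.6745, abs=1e-4)

    def test_matches_rank_formula_on_tiefree_input(self, rng):
        x = rng.normal(size=101)
        _, z = orq_fit_transform(x)
        # independent oracle: position in the sorted sample
        order = np.argsort(x)
        expected = np.empty_like(x)
        expected[order] = norm.ppf((np.arange(101) + 1) / 102)
        assert np.allclose(z, expected)

    def test_strictly_increasing_input_maps_to_increasing_output(self, rng):
        x = np.cumsum(rng.uniform(0.1, 1.0, size=50))
        _, z = orq_fit_transform(x)
        assert np.all(np.diff(z) > 0)

    def test_inverse_round_trip_on_training_data(self, rng):
        x = rng.lognormal(size=200)
        t, z = orq_fit_transform(x)
        assert np.allclose(t.inverse(t.transform(x)), x, atol=1e-9)

    def test_ties_get_average_ranks(self):
        _, z = orq_fit_transform([1.0, 1.0, 2.0, 3.0])
        assert z[0] == z[1]

    def test_new_data_interpolates_monotonically(self, rng):
        x = rng.normal(size=80)
        t, _ = orq_fit_transform(x)
        grid = np.linspace(x.min() - 1, x.max() + 1, 200)
        out = t.transform(grid)
        assert np.all(np.diff(out) >= 0)

    def test_normalizes_skewed_input(self, rng):
        x = rng.lognormal(size=400)
        _, z = orq_fit_transform(x)
        assert abs(z.mean()) < 0.05
        assert abs(np.median(z)) < 0.05

    def test_constant_input_rejected(self):
        with pytest.raises(ValidationError):
            OrqTransform([2.0, 2.0, 2.0])


class TestWeatherComposite:
    def test_two_collinear_plus_one_orthogonal_gives_two_thirds(self, rng):
        temp = rng.normal(15, 5, size=300)
        humidity = 2.0 * temp + 1.0  # exactly collinear with temperature
        wind_raw = rng.normal(size=300)
        # orthogonalize wind against temperature in-sample
        X = np.column_stack([np.ones(300), temp])
        wind = wind_raw - X @ np.linalg.lstsq(X, wind_raw, rcond=None)[0]
        df = pd.DataFrame({"temp_C": temp, "humidity_pct": humidity, "wind_ms": wind})
        comp = weather_composite(df)
        assert comp.variance_explained == pytest.approx(2 / 3, abs=1e-9)

    def test_spherical_limit_approaches_one_third(self, rng):
        df = pd.DataFrame(
            {
                "temp_C": rng.normal(size=20000),
                "humidity_pct": rng.normal(size=20000),
                "wind_ms": rng.normal(size=20000),
            }
        )
        comp = weather_composite(df)
        assert comp.variance_explained == pytest.approx(1 / 3, abs=0.02)

    def test_constant_columns_dropped_single_variable_passthrough(self, rng):
        temp = rng.normal(15, 5, size=50)
        df = pd.DataFrame({"temp_C": temp, "humidity_pct": 70.0, "wind_ms": 3.0})
        comp = weather_composite(df)
        assert comp.used_columns == ["temp_C"]
        z = (temp - temp.mean()) / temp.std()
        assert np.allclose(comp.scores, z)

    def test_temperature_loading_sign_is_positive(self, rng):
        wx = pd.DataFrame(
            {
                "temp_C": rng.normal(15, 5, 100),
                "humidity_pct": rng.normal(70, 8, 100),
                "wind_ms": rng.normal(3, 1, 100),
            }
        )
        assert weather_composite(wx).loadings["temp_C"] > 0


class TestResidualize:
    def test_annihilates_functions_in_the_smoother_span(self, rng):
        week = rng.integers(14, 39, size=400).astype(float)
        scores = 0.3 * week + 1.0  # linear trends lie in every spline basis
        resid = residualize_on_week(scores, week)
        assert np.abs(resid).max() < 1e-8

    def test_recovers_noise_variance(self, rng):
        week = rng.integers(10, 40, size=500).astype(float)
        noise = rng.normal(0, 1.0, size=500)
        scores = np.sin(week / 6.0) + noise
        resid = residualize_on_week(scores, week)
        assert np.var(resid) == pytest.approx(np.var(noise), rel=0.10)

    def test_residuals_orthogonal_to_fitted(self, rng):
        week = rng.integers(1, 30, size=300).astype(float)
        scores = rng.normal(size=300) + 0.1 * week
        resid = residualize_on_week(scores, week)
        fitted = scores - resid
        if fitted.std() > 0:
            assert abs(np.corrcoef(resid, fitted)[0, 1]) < 1e-8

    def test_few_weeks_falls_back_to_polynomial(self, rng):
        week = np.repeat([1.0, 2.0, 3.0, 4.0, 5.0], 20)
        scores = week**2 + rng.normal(0, 0.1, size=100)
        with pytest.warns(UserWarning, match="cubic polynomial"):
            resid = residualize_on_week(scores, week)
        assert np.abs(resid).max() < 1.0


class TestCandidateSet:
    def test_protocol_is_four_nested_specs(self):
        specs = candidate_set("nectar")
        names = [s.name for s in specs]
        assert names == ["null", "covariates", "covariates+focal", "covariates+focal_x_week"]
        null, cov, focal, inter = specs
        assert null.fixed == ()
        assert "ram_log1p" not in cov.fixed
        assert "ram_log1p" in focal.fixed
        assert "week:ram_log1p" in inter.fixed
        assert set(focal.fixed) < set(inter.fixed)
        assert "covariates" in inter.nested_within

    def test_nectar_model_structure(self):
        inter = candidate_set("nectar")[-1]
        assert inter.family == "gaussian"
        assert inter.response_transform == "orq"
        assert "I(experience**2)" in inter.fixed
        assert "weather_resid" in inter.fixed
        assert inter.random == "bee_intercept_x_experience_slope"

    def test_pollen_model_structure(self):
        inter = candidate_set("pollen")[-1]
        assert inter.family == "gamma_log"
        assert "experience" in inter.fixed
        assert "I(experience**2)" not in inter.fixed  # linear experience
        assert inter.random == "bee_intercept_uncorr_experience_slope"

    def test_survival_and_effort_families(self):
        assert candidate_set("survival")[0].family == "coxph_frailty"
        assert candidate_set("effort")[0].family == "poisson_olre"

    def test_control_comparison_uses_treatment_term(self):
        focal = candidate_set("control_comparison")[2]
        assert "C(tested)" in focal.fixed

    def test_unknown_analysis_rejected(self):
        with pytest.raises(ValidationError):
            candidate_set("dance_language")


def _fake_fit(name, loglik, k, n=1000, nested_within=()):
    spec = ModelSpec(
        name=name,
        analysis="nectar",
        response="y",
        family="gaussian",
        fixed=("x",) * 0,
        random="bee_intercept",
        nested_within=nested_within,
    )
    return FitResult(
        spec=spec, loglik=loglik, k=k, n=n, params={}, bse={}, conf_int={}, converged=True
    )


class TestSelectionRule:
    def test_clear_winner_by_delta_aic(self):
        # AIC 104.7 vs 100.0: Δ = 4.7 > 2, the better model wins
        null = _fake_fit("null", loglik=-50.35, k=2)
        full = _fake_fit("full", loglik=-45.0, k=5, nested_within=("null",))
        assert null.aic == pytest.approx(104.7)
        assert full.aic == pytest.approx(100.0)
        selected, criterion, _ = select_best([null, full], criterion="AIC")
        assert selected.spec.name == "full"

    def test_simplest_selected_on_comparable_fit(self):
        a = _fake_fit("A", loglik=-45.0, k=5)  # AIC 100.0
        b = _fake_fit("B", loglik=-46.75, k=4, nested_within=("A",))  # AIC 101.5
        selected, _, trace = select_best([a, b], criterion="AIC")
        assert selected.spec.name == "B"
        assert any("fewer parameters" in t for t in trace)

    def test_non_nested_near_tie_keeps_the_best(self):
        a = _fake_fit("A", loglik=-45.0, k=5)
        b = _fake_fit("B", loglik=-46.0, k=4)  # within 2 but not nested
        selected, _, _ = select_best([a, b], criterion="AIC")
        assert selected.spec.name == "A"

    def test_criterion_switches_to_aicc_for_small_samples(self):
        a = _fake_fit("A", loglik=-45.0, k=5, n=100)
        b = _fake_fit("B", loglik=-46.75, k=4, n=100)
        _, criterion, _ = select_best([a, b])
        assert criterion == "AICc"
        _, criterion, _ = select_best(
            [_fake_fit("A", -45.0, 5, n=10000), _fake_fit("B", -46.75, 4, n=10000)]
        )
        assert criterion == "AIC"

    def test_information_criterion_identities(self):
        f = _fake_fit("A", loglik=-45.0, k=5, n=100)
        assert f.aic == -2 * f.loglik + 2 * f.k
        assert f.aicc == f.aic + 2 * f.k * (f.k + 1) / (f.n - f.k - 1)
        assert aicc(-45.0, 5, 6) == float("inf")
        assert aic(-45.0, 5) == pytest.approx(100.0)


class TestInteractionProfile:
    def _fit_with_interaction(self, b_ram=-1.0, b_int=0.05, v=1e-4):
        spec = ModelSpec(
            name="covariates+focal_x_week",
            analysis="nectar",
            response="y",
            family="gaussian",
            fixed=("week", "ram_log1p", "week:ram_log1p"),
            random="bee_intercept",
        )
        names = ["ram_log1p", "week:ram_log1p"]
        cov = pd.DataFrame(np.diag([v, v / 100]), index=names, columns=names)
        return FitResult(
            spec=spec,
            loglik=0.0,
            k=5,
            n=100,
            params={"ram_log1p": b_ram, "week:ram_log1p": b_int},
            bse={"ram_log1p": np.sqrt(v), "week:ram_log1p": np.sqrt(v / 100)},
            conf_int={},
            converged=True,
            cov_params=cov,
        )

    def test_reversal_week_root_arithmetic(self):
        prof = interaction_profile(self._fit_with_interaction(), weeks=np.arange(10, 31))
        assert prof.reversal_week == pytest.approx(20.0)
        assert prof.reversal_week_se > 0
        slopes = prof.table.set_index("week")["slope"]
        assert slopes.loc[10] == pytest.approx(-0.5)
        assert slopes.loc[30] == pytest.approx(0.5)

    def test_zero_interaction_gives_constant_profile(self):
        prof = interaction_profile(
            self._fit_with_interaction(b_int=0.0), weeks=np.arange(10, 31)
        )
        assert prof.reversal_week is None
        assert prof.table["slope"].nunique() == 1

    def test_root_outside_range_not_reported(self):
        prof = interaction_profile(self._fit_with_interaction(), weeks=np.arange(25, 31))
        assert prof.reversal_week is None

    def test_missing_interaction_term_is_an_error(self):
        fit = _fake_fit("covariates", loglik=0.0, k=2)
        with pytest.raises(ValidationError):
            interaction_profile(fit, weeks=[1, 2, 3])


@pytest.fixture(scope="module")
def small_study():
    from winshift.pipeline import synthetic_study

    return synthetic_study(seed=424, n_bees=36, n_colonies=4)


class TestGaussianFits:
    def test_nectar_selection_runs_and_reports_identities(self, small_study):
        frame = small_study["nectar_frame"]
        sel = fit_and_select(candidate_set("nectar"), frame)
        assert sel.selected.spec.name in {
            "null",
            "covariates",
            "covariates+focal",
            "covariates+focal_x_week",
        }
        for f in sel.fits:
            assert f.aic == pytest.approx(-2 * f.loglik + 2 * f.k)
            assert f.n == len(frame)
        assert any("selected" in line for line in sel.trace)

    def test_orq_scale_coefficients_are_finite_and_cov_consistent(self, small_study):
        frame = small_study["nectar_frame"]
        sel = fit_and_select(candidate_set("nectar"), frame)
        fit = [f for f in sel.fits if f.spec.name == "covariates+focal_x_week"][0]
        assert np.isfinite(list(fit.params.values())).all()
        for name, se in fit.bse.items():
            assert se >= 0
            lo, hi = fit.conf_int[name]
            assert lo <= fit.params[name] <= hi


class TestRBackends:
    def test_pollen_gamma_glmm_fit(self, small_study):
        frame = build_analysis_frame(
            "pollen",
            efficiency=small_study["efficiency"],
            scores=small_study["scores"],
            bees=small_study["bees"],
        )
        spec = candidate_set("pollen")[2]
        from winshift.backends import fit_glmm_r

        fit = fit_glmm_r(spec, frame)
        assert fit.n == len(frame)
        assert np.isfinite(fit.loglik)
        assert fit.aic == pytest.approx(-2 * fit.loglik + 2 * fit.k)
        assert "ram_log1p" in fit.params

    def test_survival_cox_frailty_and_effort_poisson(self, small_study):
        from winshift.backends import fit_cox_frailty_r, fit_glmm_r
        from winshift.trips import survival_and_effort

        trips = small_study["trips"].assign(status="complete")
        bees = small_study["bees"]
        careers = bees.assign(
            release_date=trips.groupby("bee_id")["t_out"]
            .min()
            .dt.normalize()
            .reindex(bees.bee_id)
            .to_numpy()
        ).dropna(subset=["release_date"])
        surv = survival_and_effort(careers, trips, study_end=trips["t_in"].max())
        frame = build_analysis_frame(
            "survival", survival=surv, scores=small_study["scores"], bees=bees
        )
        cox = fit_cox_frailty_r(candidate_set("survival")[2], frame)
        assert np.isfinite(cox.loglik)
        assert "ram_log1p" in cox.params

        frame_e = build_analysis_frame(
            "effort", survival=surv, scores=small_study["scores"], bees=bees
        )
        pois = fit_glmm_r(candidate_set("effort")[2], frame_e)
        assert np.isfinite(pois.loglik)
        assert pois.aic == pytest.approx(-2 * pois.loglik + 2 * pois.k)


class TestAnalysisFrame:
    def test_vocabulary_columns_present(self, small_study):
        frame = small_study["nectar_frame"]
        for col in ("week", "experience", "ram_log1p", "size_mm", "age_at_release",
                    "weather_resid", "year", "bee_id", "colony_id", "eff_mg_per_min"):
            assert col in frame.columns
        assert frame["ram_log1p"].notna().all()

    def test_pollen_frame_only_contains_pollen_trips(self, small_study):
        frame = build_analysis_frame(
            "pollen",
            efficiency=small_study["efficiency"],
            scores=small_study["scores"],
            bees=small_study["bees"],
        )
        assert (frame["trip_type"] == "pollen").all()
        assert (frame["eff_mg_per_min"] > 0).all()
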