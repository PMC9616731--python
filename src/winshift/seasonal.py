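"""Seasonal analysis scaffolding: normalization, weather scores, model selection.

The headline analysis asks whether the RAM score × week-of-year interaction
improves a mixed model of per-trip foraging efficiency, i.e. whether the
value of short-term memory changes across the season.  The protocol is
information-theoretic: a fixed candidate set {null, covariates, covariates +
RAM, covariates + RAM × week} is fitted per analysis and the best model is the
one with the lowest AIC (or AICc at small n), requiring Δ > 2 over simpler
nested alternatives.

This module owns the response transform (ordered-quantile normalization), the
composite weather covariate (first principal component of temperature,
humidity and wind, residualized on week so "weather" means weather beyond
season), candidate-set construction, the selection rule, and the per-week
interaction profile.  The actual optimizers are established backends:
statsmodels MixedLM for Gaussian mixed models, and lme4 / survival (via
:mod:`winshift.backends`) for Gamma/Poisson GLMMs and Cox frailty models.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from winshift.errors import ValidationError

__all__ = [
    "OrqTransform",
    "orq_fit_transform",
    "WeatherComposite",
    "weather_composite",
    "residualize_on_week",
    "ModelSpec",
    "FitResult",
    "candidate_set",
    "build_analysis_frame",
    "fit_and_select",
    "select_best",
    "SelectionResult",
    "interaction_profile",
    "InteractionProfile",
    "aic",
    "aicc",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Ordered-quantile (rank-based inverse normal) transform
# ---------------------------------------------------------------------------

class OrqTransform:
    """Ordered-quantile normalization: z_i = Φ⁻¹(rank(x_i) / (n + 1)).

    Ties get average ranks.  New data are transformed by monotone linear
    interpolation of the fitted (x, z) mapping with linear extrapolation in
    the tails; :meth:`inverse` is the reverse interpolation, exact on the
    training sample.
    """

    def __init__(self, x: Sequence[float]):
        x = np.asarray(x, dtype=float)
        if x.ndim != 1 or x.size < 3:
            raise ValidationError("ORQ transform needs a 1-D sample of length >= 3")
        if not np.all(np.isfinite(x)):
            raise ValidationError("ORQ transform requires finite values")
        if np.ptp(x) == 0:
            raise ValidationError("ORQ transform undefined for constant input")
        self.n = x.size
        ranks = rankdata(x, method="average")
        z = norm.ppf(ranks / (self.n + 1))
        # strictly increasing knots: unique x with their (tie-averaged) z
        ux, inverse = np.unique(x, return_inverse=True)
        uz = np.bincount(inverse, weights=z) / np.bincount(inverse)
        self._x_knots = ux
        self._z_knots = uz
        self._z_train = z

    def _extrapolate(self, v, xs, ys):
        out = np.interp(v, xs, ys)
        lo_slope = (ys[1] - ys[0]) / (xs[1] - xs[0])
        hi_slope = (ys[-1] - ys[-2]) / (xs[-1] - xs[-2])
        out = np.where(v < xs[0], ys[0] + (v - xs[0]) * lo_slope, out)
        out = np.where(v > xs[-1], ys[-1] + (v - xs[-1]) * hi_slope, out)
        return out

    def transform(self, x: Sequence[float]) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return self._extrapolate(x, self._x_knots, self._z_knots)

    def inverse(self, z: Sequence[float]) -> np.ndarray:
        z = np.asarray(z, dtype=float)
        return self._extrapolate(z, self._z_knots, self._x_knots)


def orq_fit_transform(x: Sequence[float]) -> tuple[OrqTransform, np.ndarray]:
    """Fit the ORQ transform and return it with the transformed sample."""
    t = OrqTransform(x)
    return t, t._z_train.copy()


# ---------------------------------------------------------------------------
# Composite weather score
# ---------------------------------------------------------------------------

@dataclass
class WeatherComposite:
    """First principal component of standardized daily weather variables."""

    loadings: dict[str, float]
    variance_explained: float
    scores: np.ndarray
    used_columns: list[str]
    residual_scores: np.ndarray | None = None


WEATHER_COLUMNS = ("temp_C", "humidity_pct", "wind_ms")


def weather_composite(
    daily: pd.DataFrame, columns: Sequence[str] = WEATHER_COLUMNS
) -> WeatherComposite:
    """Reduce temperature, humidity and wind to one standardized component.

    Columns are z-scored; constant columns are dropped with a log message;
    rows with any missing value are deleted listwise.  The sign convention
    fixes a positive loading on the first column (temperature).
    """
    cols = [c for c in columns if c in daily.columns]
    if len(cols) < 1:
        raise ValidationError(f"weather table has none of {columns}")
    X = daily[cols].astype(float)
    complete = X.notna().all(axis=1)
    if (~complete).any():
        logger.info("weather_composite: dropping %d incomplete days", int((~complete).sum()))
    X = X[complete]
    if len(X) < 3:
        raise ValidationError("weather composite needs at least 3 complete days")
    keep = [c for c in cols if X[c].std(ddof=0) > 0]
    dropped = sorted(set(cols) - set(keep))
    if dropped:
        logger.info("weather_composite: dropping constant columns %s", dropped)
    if not keep:
        raise ValidationError("all weather columns are constant")
    Z = (X[keep] - X[keep].mean()) / X[keep].std(ddof=0)
    corr = np.corrcoef(Z.to_numpy(), rowvar=False).reshape(len(keep), len(keep))
    eigval, eigvec = np.linalg.eigh(corr)
    lead = eigvec[:, -1]
    if lead[0] < 0:
        lead = -lead
    scores_complete = Z.to_numpy() @ lead
    scores = np.full(len(daily), np.nan)
    scores[np.flatnonzero(complete.to_numpy())] = scores_complete
    return WeatherComposite(
        loadings={c: float(v) for c, v in zip(keep, lead)},
        variance_explained=float(eigval[-1] / eigval.sum()),
        scores=scores,
        used_columns=keep,
    )


def residualize_on_week(
    scores: Sequence[float],
    week: Sequence[int],
    df_grid: Sequence[int] = (4, 5, 6, 7, 8),
) -> np.ndarray:
    """Residuals of a smooth of score on week (seasonal detrending).

    Fits a natural-cubic-regression-spline smooth of score on week, choosing
    the basis dimension from ``df_grid`` by generalized cross-validation, and
    returns score − fitted.  Being a projection fit, residuals are exactly
    orthogonal to the fitted values.  With fewer than 8 distinct weeks the
    smooth falls back to a cubic polynomial (with a warning).
    """
    scores = np.asarray(scores, dtype=float)
    week = np.asarray(week, dtype=float)
    if scores.shape != week.shape:
        raise ValidationError("scores and week must have equal length")
    ok = np.isfinite(scores) & np.isfinite(week)
    resid = np.full(scores.shape, np.nan)
    x, y = week[ok], scores[ok]
    n_distinct = np.unique(x).size
    if n_distinct < 2:
        resid[ok] = y - y.mean()
        return resid

    def _fit(X: np.ndarray) -> tuple[np.ndarray, float]:
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        fitted = X @ beta
        rss = float(np.sum((y - fitted) ** 2))
        k = np.linalg.matrix_rank(X)
        gcv = len(y) * rss / (len(y) - k) ** 2
        return fitted, gcv

    if n_distinct < 8:
        warnings.warn(
            "fewer than 8 distinct weeks; falling back to a cubic polynomial",
            stacklevel=2,
        )
        deg = min(3, n_distinct - 1)
        X = np.vander(x - x.mean(), deg + 1)
        fitted, _ = _fit(X)
    else:
        from patsy import dmatrix

        best = None
        for df_basis in df_grid:
            if df_basis >= n_distinct:
                continue
            X = np.asarray(
                dmatrix("cr(x, df=df_basis)", {"x": x, "df_basis": df_basis})
            )
            fitted, gcv = _fit(X)
            if best is None or gcv < best[0]:
                best = (gcv, fitted)
        fitted = best[1]
    resid[ok] = y - fitted
    return resid


# ---------------------------------------------------------------------------
# Candidate models and AIC/AICc selection
# ---------------------------------------------------------------------------

def aic(loglik: float, k: int) -> float:
    return -2.0 * loglik + 2.0 * k


def aicc(loglik: float, k: int, n: int) -> float:
    if n - k - 1 <= 0:
        return float("inf")
    return aic(loglik, k) + 2.0 * k * (k + 1) / (n - k - 1)


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of one candidate model.

    ``fixed`` are patsy-style fixed-effect terms; ``random`` is a structure
    descriptor understood by the family's backend; ``nested_within`` lists
    the names of candidate models this one is nested in (used by the
    simplest-on-tie selection rule).
    """

    name: str
    analysis: str
    response: str
    family: str  # gaussian | gamma_log | poisson_olre | coxph_frailty
    fixed: tuple[str, ...]
    random: str
    response_transform: str | None = None
    nested_within: tuple[str, ...] = ()

    def formula(self, response: str | None = None) -> str:
        rhs = " + ".join(self.fixed) if self.fixed else "1"
        return f"{response or self.response} ~ {rhs}"


@dataclass
class FitResult:
    """Outcome of fitting one candidate model."""

    spec: ModelSpec
    loglik: float
    k: int
    n: int
    params: dict[str, float]
    bse: dict[str, float]
    conf_int: dict[str, tuple[float, float]]
    converged: bool
    cov_params: pd.DataFrame | None = None
    backend: str = ""
    notes: str = ""

    @property
    def aic(self) -> float:
        return aic(self.loglik, self.k)

    @property
    def aicc(self) -> float:
        return aicc(self.loglik, self.k, self.n)

    def to_dict(self) -> dict:
        return {
            "name": self.spec.name,
            "analysis": self.spec.analysis,
            "family": self.spec.family,
            "loglik": self.loglik,
            "k": self.k,
            "n": self.n,
            "aic": self.aic,
            "aicc": self.aicc,
            "converged": self.converged,
            "backend": self.backend,
            "coefficients": {
                name: {
                    "estimate": self.params[name],
                    "se": self.bse.get(name),
                    "ci95": list(self.conf_int.get(name, (None, None))),
                }
                for name in self.params
            },
        }


_ANALYSES = ("nectar", "pollen", "survival", "effort", "control_comparison")

# covariate vocabulary per analysis; the RAM term and its week interaction are
# appended by the candidate-set protocol
_BASE_TERMS: dict[str, tuple[str, ...]] = {
    "nectar": (
        "week",
        "age_at_release",
        "size_mm",
        "C(year)",
        "experience",
        "I(experience**2)",
        "weather_resid",
    ),
    "pollen": (
        "week",
        "age_at_release",
        "size_mm",
        "C(year)",
        "experience",
        "weather_resid",
    ),
    "survival": ("week", "age_at_release", "size_mm", "C(year)", "weather_resid"),
    "effort": ("week", "age_at_release", "size_mm", "C(year)", "weather_resid"),
    "control_comparison": (
        "week",
        "age_at_release",
        "size_mm",
        "C(year)",
        "experience",
        "I(experience**2)",
        "weather_resid",
    ),
}

_FAMILY: dict[str, str] = {
    "nectar": "gaussian",
    "pollen": "gamma_log",
    "survival": "coxph_frailty",
    "effort": "poisson_olre",
    "control_comparison": "gaussian",
}

_RESPONSE: dict[str, str] = {
    "nectar": "eff_mg_per_min",
    "pollen": "eff_mg_per_min",
    "survival": "survival_days",
    "effort": "n_trips_lifetime",
    "control_comparison": "eff_mg_per_min",
}

_TRANSFORM: dict[str, str | None] = {
    "nectar": "orq",
    "pollen": None,
    "survival": None,
    "effort": None,
    "control_comparison": "orq",
}

_RANDOM: dict[str, str] = {
    "nectar": "bee_intercept_x_experience_slope",
    "pollen": "bee_intercept_uncorr_experience_slope",
    "survival": "colony_frailty",
    "effort": "colony_intercept_olre",
    "control_comparison": "bee_intercept_x_experience_slope",
}

# the "predictor of interest" slot: RAM score for the main analyses,
# testing-cohort membership for the control comparison
_FOCAL_TERM: dict[str, str] = {
    "nectar": "ram_log1p",
    "pollen": "ram_log1p",
    "survival": "ram_log1p",
    "effort": "ram_log1p",
    "control_comparison": "C(tested)",
}


def candidate_set(analysis: str) -> list[ModelSpec]:
    """The four-model protocol for one analysis.

    Returns {null, covariates, covariates + focal predictor, covariates +
    focal × week} with the analysis-specific response, family and random
    structure.  The null model contains only the intercept and random terms.
    """
    if analysis not in _ANALYSES:
        raise ValidationError(f"unknown analysis {analysis!r}; expected one of {_ANALYSES}")
    base = _BASE_TERMS[analysis]
    focal = _FOCAL_TERM[analysis]
    interaction = f"week:{focal}"
    common = dict(
        analysis=analysis,
        response=_RESPONSE[analysis],
        family=_FAMILY[analysis],
        random=_RANDOM[analysis],
        response_transform=_TRANSFORM[analysis],
    )
    return [
        ModelSpec(name="null", fixed=(), **common),
        ModelSpec(name="covariates", fixed=base, nested_within=(), **common),
        ModelSpec(
            name="covariates+focal",
            fixed=base + (focal,),
            nested_within=("covariates", "null"),
            **common,
        ),
        ModelSpec(
            name="covariates+focal_x_week",
            fixed=base + (focal, interaction),
            nested_within=("covariates+focal", "covariates", "null"),
            **common,
        ),
    ]


_IDENT_RE = re.compile(r"[A-Za-z_][A-Za-z0-9_]*")


def _effective_terms(spec: ModelSpec, data: pd.DataFrame) -> tuple[str, ...]:
    """Drop fixed terms whose data columns are constant (or absent).

    A single-level factor (e.g. one year of data) or an all-constant
    covariate carries no information and would make the design matrix
    singular; such terms are removed with a log message.
    """
    kept = []
    for term in spec.fixed:
        cols = [
            t for t in _IDENT_RE.findall(term) if t not in ("C", "I") and t in data.columns
        ]
        referenced = [t for t in _IDENT_RE.findall(term) if t not in ("C", "I")]
        if any(c not in data.columns for c in referenced):
            logger.info("dropping term %s: column missing from data", term)
            continue
        if cols and all(data[c].nunique(dropna=True) <= 1 for c in cols):
            logger.info("dropping term %s: constant in data", term)
            continue
        kept.append(term)
    return tuple(kept)


def _uncenter(
    fe_names: list[str],
    params: "np.ndarray",
    cov: "np.ndarray",
    centers: dict[str, float],
) -> tuple[list[str], "np.ndarray", "np.ndarray"]:
    """Map coefficients of a fit on centered covariates back to the raw scale.

    ``centers`` maps centered column names (``week_c``) to the subtracted
    means.  Handles main effects, interactions containing one centered
    variable, and the centered quadratic ``I(x_c ** 2)``.
    """
    final_names = []
    for name in fe_names:
        out = name
        for c_col in centers:
            out = out.replace(c_col, c_col[:-2])
        final_names.append(out)
    p = len(fe_names)
    M = np.zeros((p, p))
    idx = {n: i for i, n in enumerate(final_names)}
    for j, name in enumerate(fe_names):
        M[idx[final_names[j]], j] += 1.0
        for c_col, m in centers.items():
            raw = c_col[:-2]
            if name == c_col:
                M[idx["Intercept"], j] += -m
            elif name == f"I({c_col} ** 2)":
                M[idx["Intercept"], j] += m * m
                M[idx[raw], j] += -2.0 * m
            elif ":" in name and c_col in name.split(":"):
                rest = ":".join(t for t in name.split(":") if t != c_col)
                M[idx[rest], j] += -m
    return final_names, M @ params, M @ cov @ M.T


_TOKEN_RES = {raw: re.compile(rf"\b{raw}\b") for raw in ("week", "experience")}


def _fit_gaussian(spec: ModelSpec, data: pd.DataFrame) -> FitResult:
    import statsmodels.formula.api as smf
    from statsmodels.tools.sm_exceptions import ConvergenceWarning

    d = data.copy()
    response = spec.response
    if spec.response_transform == "orq":
        _, z = orq_fit_transform(d[response].to_numpy())
        d["_y"] = z
        response = "_y"
    elif spec.response_transform == "log1p":
        d["_y"] = np.log1p(d[response].to_numpy())
        response = "_y"
    terms = _effective_terms(spec, d)
    # centre poorly scaled covariates for the optimizer; coefficients and
    # their covariance are mapped back to the raw scale afterwards
    centers: dict[str, float] = {}
    fit_terms = []
    for term in terms:
        t = term
        for raw, token in _TOKEN_RES.items():
            if raw in set(_IDENT_RE.findall(term)) and raw in d.columns:
                c_col = f"{raw}_c"
                if c_col not in centers:
                    centers[c_col] = float(d[raw].mean())
                    d[c_col] = d[raw] - centers[c_col]
                t = token.sub(c_col, t)
        fit_terms.append(t)
    formula = f"{response} ~ " + (" + ".join(fit_terms) if fit_terms else "1")
    if "experience" in d.columns:
        slope_col = "experience_c" if "experience_c" in centers else "experience"
    else:
        d["experience"] = 0.0
        slope_col = "experience"
    if spec.random == "bee_intercept_x_experience_slope":
        re_formula, vc, n_re = f"~{slope_col}", None, 3
    elif spec.random == "bee_intercept_uncorr_experience_slope":
        re_formula, vc, n_re = "1", {"experience": f"0 + {slope_col}"}, 2
    elif spec.random == "bee_intercept":
        re_formula, vc, n_re = "1", None, 1
    else:
        raise ValidationError(f"gaussian backend cannot fit random structure {spec.random!r}")
    if slope_col == "experience_c" and slope_col not in d.columns:
        d[slope_col] = d["experience"] - d["experience"].mean()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.simplefilter("ignore", UserWarning)
        model = smf.mixedlm(
            formula, d, groups=d["bee_id"], re_formula=re_formula, vc_formula=vc
        )

        def _ok(res) -> bool:
            try:
                return (
                    np.isfinite(res.llf)
                    and np.all(np.isfinite(np.asarray(res.params, dtype=float)))
                    and np.all(np.isfinite(res.cov_params().to_numpy()))
                )
            except Exception:
                return False

        fit = None
        converged = False
        for method in ("lbfgs", "powell"):
            try:
                cand = model.fit(reml=False, method=method, maxiter=3000, disp=False)
            except Exception:
                continue
            if not _ok(cand):
                continue
            if fit is None or cand.llf > fit.llf:
                fit = cand
                converged = bool(getattr(cand, "converged", True))
            if converged and method == "lbfgs":
                break
        if fit is None:
            raise ValidationError(f"mixed model {spec.name!r} could not be fitted")
    fe_names = list(model.exog_names)
    beta = np.array([fit.params[name] for name in fe_names])
    cov = fit.cov_params().loc[fe_names, fe_names].to_numpy()
    names, beta, cov = _uncenter(fe_names, beta, cov, centers)
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    zq = norm.ppf(0.975)
    k = len(fe_names) + n_re + 1  # fixed effects + RE (co)variances + residual
    return FitResult(
        spec=spec,
        loglik=float(fit.llf),
        k=k,
        n=int(fit.nobs),
        params=dict(zip(names, map(float, beta))),
        bse=dict(zip(names, map(float, se))),
        conf_int={
            nm: (float(b - zq * s), float(b + zq * s))
            for nm, b, s in zip(names, beta, se)
        },
        converged=converged,
        cov_params=pd.DataFrame(cov, index=names, columns=names),
        backend="statsmodels.MixedLM(ML)",
    )


def _fit(spec: ModelSpec, data: pd.DataFrame) -> FitResult:
    if spec.family == "gaussian":
        return _fit_gaussian(spec, data)
    from winshift import backends

    if spec.family in ("gamma_log", "poisson_olre"):
        return backends.fit_glmm_r(spec, data)
    if spec.family == "coxph_frailty":
        return backends.fit_cox_frailty_r(spec, data)
    raise ValidationError(f"unknown family {spec.family!r}")


@dataclass
class SelectionResult:
    fits: list[FitResult]
    selected: FitResult
    criterion: str
    trace: list[str] = field(default_factory=list)


def fit_and_select(
    specs: Sequence[ModelSpec],
    data: pd.DataFrame,
    delta_threshold: float = 2.0,
) -> SelectionResult:
    """Fit every candidate and select by the ΔAIC/ΔAICc > 2 protocol.

    AIC is used when n / k_max ≥ 40, AICc otherwise.  The best model is the
    one with the lowest criterion; if nested candidates sit within
    ``delta_threshold`` of it, the simplest (fewest parameters) is selected.
    Non-converged fits are excluded with a warning.
    """
    fits: list[FitResult] = []
    trace: list[str] = []
    for spec in specs:
        try:
            fit = _fit(spec, data)
        except Exception as exc:
            logger.warning("fit of %s failed: %s", spec.name, exc)
            trace.append(f"{spec.name}: FAILED ({exc})")
            continue
        fits.append(fit)
    usable = [f for f in fits if f.converged]
    for f in fits:
        if not f.converged:
            trace.append(f"{f.spec.name}: excluded (non-convergence)")
    if not usable:
        raise ValidationError("no candidate model converged")
    selected, criterion, sel_trace = select_best(usable, delta_threshold=delta_threshold)
    trace.extend(sel_trace)
    return SelectionResult(fits=fits, selected=selected, criterion=criterion, trace=trace)


def select_best(
    usable: Sequence[FitResult],
    delta_threshold: float = 2.0,
    criterion: str | None = None,
) -> tuple[FitResult, str, list[str]]:
    """Apply the Δ-criterion selection rule to already-fitted candidates.

    AIC is used when n / k_max ≥ 40, AICc otherwise (override via
    ``criterion``).  The lowest-criterion model wins unless a nested,
    simpler candidate lies within ``delta_threshold`` of it, in which case
    the simplest such model is returned.
    """
    usable = list(usable)
    if not usable:
        raise ValidationError("no candidate fits supplied")
    trace: list[str] = []
    if criterion is None:
        k_max = max(f.k for f in usable)
        n = min(f.n for f in usable)
        criterion = "AIC" if n / k_max >= 40 else "AICc"
    crit = {f.spec.name: (f.aic if criterion == "AIC" else f.aicc) for f in usable}
    best = min(usable, key=lambda f: crit[f.spec.name])
    for f in sorted(usable, key=lambda f: crit[f.spec.name]):
        trace.append(
            f"{f.spec.name}: {criterion}={crit[f.spec.name]:.2f} "
            f"(k={f.k}, logLik={f.loglik:.2f})"
        )
    # simplest-on-tie among nested candidates within the threshold
    contenders = [
        f
        for f in usable
        if crit[f.spec.name] <= crit[best.spec.name] + delta_threshold
        and (
            f is best
            or f.spec.name in best.spec.nested_within
            or best.spec.name in f.spec.nested_within
        )
    ]
    selected = min(contenders, key=lambda f: (f.k, crit[f.spec.name]))
    if selected is not best:
        trace.append(
            f"selected {selected.spec.name} over {best.spec.name}: "
            f"Δ{criterion} ≤ {delta_threshold} and fewer parameters"
        )
    else:
        others = [crit[f.spec.name] for f in usable if f is not best]
        margin = min(others) - crit[best.spec.name] if others else float("nan")
        trace.append(f"selected {best.spec.name} (Δ{criterion} to next best = {margin:.2f})")
    return selected, criterion, trace


def build_analysis_frame(
    analysis: str,
    efficiency: pd.DataFrame | None = None,
    scores: pd.DataFrame | None = None,
    bees: pd.DataFrame | None = None,
    survival: pd.DataFrame | None = None,
    year: int | None = None,
) -> pd.DataFrame:
    """Assemble the model-vocabulary data frame for one analysis.

    Trip-level analyses (nectar, pollen, control_comparison) take the
    efficiency table (one row per classified trip, with ``eff_mg_per_min``,
    ``week_of_year``, ``experience_days`` and optional ``weather_resid``);
    bee-level analyses (survival, effort) take the survival/effort table.
    RAM scores and bee covariates are joined on ``bee_id``.  Output column
    names match the candidate-set vocabulary (week, experience, ram_log1p...).
    """
    if analysis not in _ANALYSES:
        raise ValidationError(f"unknown analysis {analysis!r}")
    if analysis in ("nectar", "pollen", "control_comparison"):
        if efficiency is None:
            raise ValidationError(f"{analysis} analysis needs the efficiency table")
        want_type = "pollen" if analysis == "pollen" else "nectar"
        d = efficiency[efficiency["trip_type"] == want_type].copy()
        d["week"] = d["week_of_year"].astype(float)
        d["experience"] = d["experience_days"].astype(float)
    else:
        if survival is None:
            raise ValidationError(f"{analysis} analysis needs the survival/effort table")
        d = survival.copy()
        if "week" not in d.columns:
            rel = pd.to_datetime(d["release_date"])
            d["week"] = rel.dt.isocalendar().week.astype(float)
    if bees is not None:
        cols = [c for c in ("bee_id", "colony_id", "size_mm", "age_at_release", "tested") if c in bees.columns]
        d = d.merge(bees[cols], on="bee_id", how="left", suffixes=("", "_bee"))
    if scores is not None:
        d = d.merge(
            scores[["bee_id", "ram_score_log1p"]].rename(
                columns={"ram_score_log1p": "ram_log1p"}
            ),
            on="bee_id",
            how="left",
        )
    if "year" not in d.columns:
        if year is None and "t_out" in d.columns:
            year = int(pd.to_datetime(d["t_out"]).dt.year.mode().iloc[0])
        d["year"] = year if year is not None else 0
    if "weather_resid" not in d.columns:
        if "weather_score" not in d.columns and all(
            c in d.columns for c in WEATHER_COLUMNS
        ):
            d["weather_score"] = weather_composite(d).scores
        if "weather_score" in d.columns:
            d["weather_resid"] = residualize_on_week(
                d["weather_score"].to_numpy(), d["week"].to_numpy()
            )
        else:
            d["weather_resid"] = 0.0
    needed = {"nectar": ("ram_log1p",), "pollen": ("ram_log1p",)}.get(analysis, ())
    for col in needed:
        d = d[d[col].notna()]
    return d.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Interaction profile
# ---------------------------------------------------------------------------

@dataclass
class InteractionProfile:
    """Per-week slope of efficiency on the focal predictor, with 95% CIs."""

    table: pd.DataFrame  # columns: week, slope, lo, hi
    reversal_week: float | None
    reversal_week_se: float | None


def interaction_profile(
    fit: FitResult,
    weeks: Sequence[float],
    focal: str = "ram_log1p",
) -> InteractionProfile:
    """slope(week) = β_focal + β_interaction × week, with delta-method CIs.

    Also reports the sign-reversal week (the root of the slope) with a
    delta-method standard error when the root falls inside the requested
    week range.
    """
    inter = f"week:{focal}"
    names = set(fit.params)
    if inter not in names and f"{focal}:week" in names:
        inter = f"{focal}:week"
    if focal not in names or inter not in names:
        raise ValidationError(
            f"fit {fit.spec.name!r} lacks the focal/interaction terms ({focal}, {inter})"
        )
    b_f = fit.params[focal]
    b_i = fit.params[inter]
    if fit.cov_params is not None:
        v_f = float(fit.cov_params.loc[focal, focal])
        v_i = float(fit.cov_params.loc[inter, inter])
        c_fi = float(fit.cov_params.loc[focal, inter])
    else:
        v_f, v_i, c_fi = fit.bse[focal] ** 2, fit.bse[inter] ** 2, 0.0
    weeks = np.asarray(weeks, dtype=float)
    slope = b_f + b_i * weeks
    var = np.maximum(v_f + weeks**2 * v_i + 2 * weeks * c_fi, 0.0)
    se = np.sqrt(var)
    z = norm.ppf(0.975)
    table = pd.DataFrame(
        {"week": weeks, "slope": slope, "lo": slope - z * se, "hi": slope + z * se}
    )
    reversal = reversal_se = None
    if b_i != 0.0:
        root = -b_f / b_i
        if weeks.min() <= root <= weeks.max():
            reversal = float(root)
            # delta method on w* = -bf/bi
            g = np.array([-1.0 / b_i, b_f / b_i**2])
            V = np.array([[v_f, c_fi], [c_fi, v_i]])
            reversal_se = float(np.sqrt(g @ V @ g))
    return InteractionProfile(table=table, reversal_week=reversal, reversal_week_se=reversal_se)
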