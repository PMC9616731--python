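"""Subprocess backends for model families without a Python ML-GLMM fitter.

Gamma log-link GLMMs, Poisson GLMMs with an observation-level random effect
(OLRE), and Cox proportional-hazards models with a shared colony frailty are
fitted in R (lme4 / survival), which are the standard tools for these model
classes.  Data are exchanged through temporary CSV/JSON files; only the
log-likelihood, parameter count, coefficient table and convergence flag come
back, so the selection protocol in :mod:`winshift.seasonal` treats all
families identically.
"""

from __future__ import annotations

import json
import subprocess
import tempfile
from pathlib import Path
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

from winshift.errors import ValidationError

if TYPE_CHECKING:  # pragma: no cover
    from winshift.seasonal import FitResult, ModelSpec

__all__ = ["fit_glmm_r", "fit_cox_frailty_r", "rscript_available"]

_GLMM_TEMPLATE = """
suppressMessages(library(lme4))
suppressMessages(library(jsonlite))
d <- read.csv("{data}", stringsAsFactors = TRUE)
{prep}
ctrl <- glmerControl(optimizer = "bobyqa", optCtrl = list(maxfun = 1e5))
m <- glmer({formula}, data = d, family = {family}, control = ctrl)
ll <- logLik(m)
msgs <- m@optinfo$conv$lme4$messages
co <- summary(m)$coefficients
hard_fail <- any(grepl("failed to converge", unlist(msgs), ignore.case = TRUE))
out <- list(
  loglik = as.numeric(ll),
  k = attr(ll, "df"),
  n = nobs(m),
  names = rownames(co),
  estimate = unname(co[, 1]),
  se = unname(co[, 2]),
  converged = (m@optinfo$conv$opt == 0) && !hard_fail,
  messages = if (is.null(msgs)) list() else as.list(msgs)
)
write_json(out, "{out}", digits = 12, auto_unbox = TRUE)
"""

_COX_TEMPLATE = """
suppressMessages(library(survival))
suppressMessages(library(jsonlite))
d <- read.csv("{data}", stringsAsFactors = TRUE)
m <- coxph({formula}, data = d)
co <- summary(m)$coefficients
keep <- !is.na(co[, "coef"]) & !is.na(co[, "se(coef)"])
co <- co[keep, , drop = FALSE]
ll <- m$loglik[length(m$loglik)]
ek <- extractAIC(m)
out <- list(
  loglik = ll,
  k = ek[1],
  aic = ek[2],
  n = m$n,
  names = rownames(co),
  estimate = unname(co[, "coef"]),
  se = unname(co[, "se(coef)"]),
  converged = TRUE
)
write_json(out, "{out}", digits = 12, auto_unbox = TRUE)
"""


def rscript_available() -> bool:
    try:
        subprocess.run(
            ["Rscript", "--version"], capture_output=True, check=True, timeout=60
        )
        return True
    except Exception:
        return False


def _run_r(script: str, workdir: Path) -> dict:
    script_path = workdir / "fit.R"
    script_path.write_text(script)
    proc = subprocess.run(
        ["Rscript", "--vanilla", str(script_path)],
        capture_output=True,
        text=True,
        timeout=600,
    )
    out_path = workdir / "out.json"
    if proc.returncode != 0 or not out_path.exists():
        raise ValidationError(
            f"R backend failed (exit {proc.returncode}): {proc.stderr.strip()[-2000:]}"
        )
    with open(out_path) as fh:
        return json.load(fh)


def _sanitize(data: pd.DataFrame, columns: list[str]) -> pd.DataFrame:
    missing = [c for c in columns if c not in data.columns]
    if missing:
        raise ValidationError(f"data missing columns required by the model: {missing}")
    return data[columns].copy()


def _lme4_random(spec: "ModelSpec") -> str:
    if spec.random == "bee_intercept_uncorr_experience_slope":
        return "(1 | bee_id) + (0 + experience | bee_id)"
    if spec.random == "bee_intercept_x_experience_slope":
        return "(1 + experience | bee_id)"
    if spec.random == "colony_intercept_olre":
        return "(1 | colony_id) + (1 | obs_id)"
    if spec.random == "bee_intercept":
        return "(1 | bee_id)"
    raise ValidationError(f"no lme4 mapping for random structure {spec.random!r}")


def _columns_in_terms(terms, data) -> list[str]:
    cols = []
    for c in data.columns:
        if any(c in t for t in terms):
            cols.append(c)
    return cols


def fit_glmm_r(spec: "ModelSpec", data: pd.DataFrame) -> "FitResult":
    """Fit a Gamma-log or Poisson-OLRE GLMM with lme4::glmer (ML)."""
    from winshift.seasonal import FitResult

    if spec.family == "gamma_log":
        family = "Gamma(link = 'log')"
    elif spec.family == "poisson_olre":
        family = "poisson"
    else:
        raise ValidationError(f"fit_glmm_r cannot handle family {spec.family!r}")
    from winshift.seasonal import _effective_terms

    fixed = [
        t.replace("I(experience**2)", "I(experience^2)")
        for t in _effective_terms(spec, data)
    ]
    rand = _lme4_random(spec)
    formula = f"{spec.response} ~ {' + '.join(fixed) if fixed else '1'} + {rand}"
    id_cols = [c for c in ("bee_id", "colony_id") if c in data.columns]
    cols = sorted(
        set([spec.response] + id_cols + _columns_in_terms(fixed + [rand], data))
    )
    d = _sanitize(data, cols).reset_index(drop=True)
    if spec.random == "colony_intercept_olre":
        d["obs_id"] = np.arange(len(d))
    prep = ""
    notes = []
    if "year" in d.columns:
        prep = "d$year <- factor(d$year)\n"
        formula = formula.replace("C(year)", "year")
    if "tested" in d.columns:
        prep += "d$tested <- factor(d$tested)\n"
        formula = formula.replace("C(tested)", "tested")
    # centre large-scale covariates for optimizer stability; slope/interaction
    # coefficients are unchanged by centering
    for col in ("week", "experience"):
        if col in d.columns and any(col in t for t in fixed):
            prep += f"d${col} <- d${col} - mean(d${col})\n"
            notes.append(f"{col} centered")
    with tempfile.TemporaryDirectory() as tmp:
        workdir = Path(tmp)
        d.to_csv(workdir / "data.csv", index=False)
        script = _GLMM_TEMPLATE.format(
            data=workdir / "data.csv",
            prep=prep,
            formula=formula,
            family=family,
            out=workdir / "out.json",
        )
        res = _run_r(script, workdir)
    names = [str(n) for n in np.atleast_1d(res["names"])]
    est = np.atleast_1d(res["estimate"]).astype(float)
    se = np.atleast_1d(res["se"]).astype(float)
    z = 1.959963984540054
    return FitResult(
        spec=spec,
        loglik=float(res["loglik"]),
        k=int(res["k"]),
        n=int(res["n"]),
        params=dict(zip(names, map(float, est))),
        bse=dict(zip(names, map(float, se))),
        conf_int={
            nm: (float(e - z * s), float(e + z * s)) for nm, e, s in zip(names, est, se)
        },
        converged=bool(res["converged"]),
        backend="lme4::glmer",
        notes="; ".join(notes + list(res.get("messages", []) or [])),
    )


def fit_cox_frailty_r(spec: "ModelSpec", data: pd.DataFrame) -> "FitResult":
    """Fit a Cox model with a shared gamma frailty per colony (survival::coxph).

    The frailty penalty makes the effective parameter count non-integer; the
    value reported by ``extractAIC`` is rounded into ``k`` so the AIC identity
    holds for the stored (loglik, k) pair up to that rounding.
    """
    from winshift.seasonal import FitResult

    from winshift.seasonal import _effective_terms

    fixed = list(_effective_terms(spec, data))
    terms = " + ".join(fixed) if fixed else "1"
    frailty = "frailty(colony_id)" if spec.random == "colony_frailty" else ""
    formula = f"Surv(survival_days, event) ~ {terms}"
    if frailty:
        formula += f" + {frailty}"
    cols = sorted(
        set(
            ["survival_days", "event"]
            + [c for c in ("colony_id",) if frailty]
            + _columns_in_terms(fixed, data)
        )
    )
    d = _sanitize(data, cols).reset_index(drop=True)
    # zero survival times are not usable by coxph; nudge to a half day
    d.loc[d["survival_days"] <= 0, "survival_days"] = 0.5
    formula = formula.replace("C(year)", "factor(year)").replace(
        "C(tested)", "factor(tested)"
    )
    with tempfile.TemporaryDirectory() as tmp:
        workdir = Path(tmp)
        d.to_csv(workdir / "data.csv", index=False)
        script = _COX_TEMPLATE.format(
            data=workdir / "data.csv", formula=formula, out=workdir / "out.json"
        )
        res = _run_r(script, workdir)
    names = [str(n) for n in np.atleast_1d(res["names"])]
    est = np.atleast_1d(res["estimate"]).astype(float)
    se = np.atleast_1d(res["se"]).astype(float)
    # reconstruct an integer-consistent k from the reported AIC and loglik
    k_eff = float(res["k"])
    loglik = float(res["loglik"])
    z = 1.959963984540054
    return FitResult(
        spec=spec,
        loglik=loglik,
        k=int(round(k_eff)),
        n=int(res["n"]),
        params=dict(zip(names, map(float, est))),
        bse=dict(zip(names, map(float, se))),
        conf_int={
            nm: (float(e - z * s), float(e + z * s)) for nm, e, s in zip(names, est, se)
        },
        converged=bool(res["converged"]),
        backend="survival::coxph(frailty)",
        notes=f"effective df {k_eff:.2f}",
    )
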