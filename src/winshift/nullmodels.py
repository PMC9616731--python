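"""Movement-rule null models for RAM performance.

Real bees could, in principle, achieve low revisit rates through stereotyped
movement rules (e.g. "always turn to the adjacent arm") rather than through
memory for visited locations.  To rule this out, a first-order Markov
"simulant" is built for each real bee from its empirical arm-to-arm transition
matrix, whole cohorts of simulants are resampled thousands of times, and the
observed cohort performance is located within the simulated null distribution
via a percentile p-value.  A second baseline uses randomly generated
transition matrices to estimate chance-level performance.

A first-order Markov simulant inherits a bee's gross movement statistics but
has no memory beyond its current position, so real bees that rely on
short-term memory should make systematically fewer revisit errors than their
own simulants.
"""

from __future__ import annotations

import json
import logging
from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Iterable, Iterator, NamedTuple, Sequence

import numpy as np
import pandas as pd

from winshift.errors import ValidationError
from winshift.ram import VisitSequence, score_bout

__all__ = [
    "TransitionMatrix",
    "StopRule",
    "SimulantBout",
    "SimulantDataset",
    "NullDistribution",
    "StatisticResult",
    "estimate_transition_matrix",
    "random_transition_matrix",
    "simulate_simulant_bout",
    "generate_simulant_datasets",
    "simulant_mean_errors",
    "dataset_statistic",
    "percentile_p_value",
    "run_validation",
]

logger = logging.getLogger(__name__)

_ROW_TOL = 1e-9


@dataclass(frozen=True)
class TransitionMatrix:
    """Row-stochastic arm-to-arm movement probabilities for one bee.

    ``P[a, b]`` is the probability of moving from arm ``a+1`` to arm ``b+1``
    (0-based storage of 1-based arm ids); ``start_dist`` is the distribution
    of first-visited arms.
    """

    bee_id: str
    n_arms: int
    P: np.ndarray
    counts: np.ndarray
    start_dist: np.ndarray

    def __post_init__(self) -> None:
        P = np.asarray(self.P, dtype=float)
        counts = np.asarray(self.counts, dtype=float)
        start = np.asarray(self.start_dist, dtype=float)
        object.__setattr__(self, "P", P)
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "start_dist", start)
        if self.n_arms < 2:
            raise ValidationError(f"n_arms must be >= 2, got {self.n_arms}")
        if P.shape != (self.n_arms, self.n_arms):
            raise ValidationError(f"P has shape {P.shape}, expected square {self.n_arms}")
        if np.any(P < -_ROW_TOL) or np.any(P > 1 + _ROW_TOL):
            raise ValidationError(f"bee {self.bee_id}: P entries outside [0, 1]")
        if not np.allclose(P.sum(axis=1), 1.0, atol=_ROW_TOL):
            raise ValidationError(f"bee {self.bee_id}: rows of P do not sum to 1")
        if np.any(counts < 0) or not np.allclose(counts, np.round(counts)):
            raise ValidationError(f"bee {self.bee_id}: counts must be non-negative integers")
        if abs(start.sum() - 1.0) > _ROW_TOL or np.any(start < -_ROW_TOL):
            raise ValidationError(f"bee {self.bee_id}: start_dist is not a distribution")

    def to_dict(self) -> dict:
        return {
            "bee_id": self.bee_id,
            "n_arms": self.n_arms,
            "P": self.P.tolist(),
            "counts": self.counts.astype(int).tolist(),
            "start_dist": self.start_dist.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TransitionMatrix":
        return cls(
            bee_id=str(d["bee_id"]),
            n_arms=int(d["n_arms"]),
            P=np.asarray(d["P"], dtype=float),
            counts=np.asarray(d["counts"], dtype=float),
            start_dist=np.asarray(d["start_dist"], dtype=float),
        )


def save_matrices(matrices: Sequence[TransitionMatrix], path) -> None:
    with open(path, "w") as fh:
        json.dump([m.to_dict() for m in matrices], fh, indent=1)


def load_matrices(path) -> list[TransitionMatrix]:
    with open(path) as fh:
        return [TransitionMatrix.from_dict(d) for d in json.load(fh)]


@dataclass(frozen=True)
class StopRule:
    """Bout termination: stop when all arms are visited, or at a visit cap.

    Mirrors the real task's end condition (the bee is fed to repletion at the
    last undepleted arm).  ``cap`` defaults to ``12 * n_arms`` visits.
    """

    cap: int | None = None

    def cap_for(self, n_arms: int) -> int:
        cap = 12 * n_arms if self.cap is None else self.cap
        if cap < 1:
            raise ValidationError(f"visit cap must be >= 1, got {cap}")
        return cap


class SimulantBout(NamedTuple):
    seq: VisitSequence
    truncated: bool


@dataclass
class SimulantDataset:
    """One resampled cohort: a simulant per real bee, with matched covariates."""

    replicate_id: int
    bees: pd.DataFrame  # columns: bee_id, size_mm, age_at_release, colony_id, n_bouts
    bouts: list[VisitSequence]
    errors_by_bee: dict[str, np.ndarray] = field(default_factory=dict)


@dataclass(frozen=True)
class NullDistribution:
    """Observed cohort statistic against its Monte-Carlo null distribution."""

    statistic_name: str
    values: np.ndarray
    observed: float
    p_value: float
    tail: str
    seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "statistic_name": self.statistic_name,
            "observed": self.observed,
            "p_value": self.p_value,
            "n_replicates": int(len(self.values)),
            "tail": self.tail,
            "seed": self.seed,
        }


def estimate_transition_matrix(
    bouts: Iterable[VisitSequence],
    n_arms: int,
    pseudo_count: float = 0.0,
    bee_id: str | None = None,
) -> TransitionMatrix:
    """Empirical transition matrix from a bee's test bouts.

    Transitions are counted only within bouts, never across bout boundaries.
    Rows are normalized as ``(count + pseudo_count) / rowsum``; a row with no
    observed transitions and zero pseudo-count falls back to uniform.
    ``start_dist`` holds the empirical frequencies of first-visited arms.
    """
    if n_arms < 2:
        raise ValidationError(f"n_arms must be >= 2, got {n_arms}")
    if pseudo_count < 0:
        raise ValidationError("pseudo_count must be >= 0")
    counts = np.zeros((n_arms, n_arms))
    starts = np.zeros(n_arms)
    bouts = list(bouts)
    for b in bouts:
        if bee_id is None:
            bee_id = b.bee_id
        if b.n_arms != n_arms:
            raise ValidationError(
                f"bout of bee {b.bee_id} has n_arms={b.n_arms}, expected {n_arms}"
            )
        if b.arms:
            starts[b.arms[0] - 1] += 1
        for a, c in zip(b.arms, b.arms[1:]):
            counts[a - 1, c - 1] += 1
    if counts.sum() == 0:
        raise ValidationError(f"bee {bee_id}: no within-bout transitions observed")
    smoothed = counts + pseudo_count
    rowsum = smoothed.sum(axis=1, keepdims=True)
    P = np.where(rowsum > 0, smoothed / np.where(rowsum == 0, 1, rowsum), 1.0 / n_arms)
    if starts.sum() > 0:
        start_dist = starts / starts.sum()
    else:
        start_dist = np.full(n_arms, 1.0 / n_arms)
    return TransitionMatrix(
        bee_id=bee_id or "?", n_arms=n_arms, P=P, counts=counts, start_dist=start_dist
    )


def random_transition_matrix(
    n_arms: int,
    forbid_self: bool = False,
    rng: np.random.Generator | None = None,
    bee_id: str = "random",
) -> TransitionMatrix:
    """Random row-stochastic matrix: each row flat-Dirichlet over allowed arms.

    With ``forbid_self`` the diagonal is held at zero, i.e. rows are uniform on
    the simplex over the other ``n_arms - 1`` destinations.  The start
    distribution is uniform.
    """
    if n_arms < 2:
        raise ValidationError(f"n_arms must be >= 2, got {n_arms}")
    rng = np.random.default_rng() if rng is None else rng
    P = np.zeros((n_arms, n_arms))
    for a in range(n_arms):
        allowed = [b for b in range(n_arms) if not (forbid_self and b == a)]
        P[a, allowed] = rng.dirichlet(np.ones(len(allowed)))
    return TransitionMatrix(
        bee_id=bee_id,
        n_arms=n_arms,
        P=P,
        counts=np.zeros((n_arms, n_arms)),
        start_dist=np.full(n_arms, 1.0 / n_arms),
    )


def _cumulative_rows(T: TransitionMatrix) -> tuple[list[list[float]], list[float]]:
    """Per-row cumulative probabilities for fast inverse-CDF sampling."""
    if np.any(T.P.sum(axis=1) <= 0):
        raise ValidationError(f"bee {T.bee_id}: transition row with all-zero probabilities")
    cum_rows = [list(np.cumsum(row)) for row in T.P]
    start_cum = list(np.cumsum(T.start_dist))
    return cum_rows, start_cum


def _sample_bout_arms(
    cum_rows: list[list[float]],
    start_cum: list[float],
    n_arms: int,
    cap: int,
    rng: np.random.Generator,
) -> tuple[list[int], bool]:
    rand = rng.random
    arm = min(bisect_right(start_cum, rand()), n_arms - 1)
    arms = [arm + 1]
    visited = 1 << arm
    n_visited = 1
    while n_visited < n_arms and len(arms) < cap:
        arm = min(bisect_right(cum_rows[arm], rand()), n_arms - 1)
        arms.append(arm + 1)
        bit = 1 << arm
        if not visited & bit:
            visited |= bit
            n_visited += 1
    return arms, n_visited < n_arms


def simulate_simulant_bout(
    T: TransitionMatrix,
    stop: StopRule | None = None,
    rng: np.random.Generator | None = None,
    bout_index: int = 1,
) -> SimulantBout:
    """One simulant bout: first arm from ``start_dist``, then Markov moves.

    The bout ends when every arm has been visited or the visit cap is hit
    (``truncated`` marks the latter).
    """
    rng = np.random.default_rng() if rng is None else rng
    stop = StopRule() if stop is None else stop
    cap = stop.cap_for(T.n_arms)
    cum_rows, start_cum = _cumulative_rows(T)
    arms, truncated = _sample_bout_arms(cum_rows, start_cum, T.n_arms, cap, rng)
    seq = VisitSequence(
        bee_id=f"sim:{T.bee_id}",
        bout_index=bout_index,
        bout_type="test",
        arms=tuple(arms),
        n_arms=T.n_arms,
    )
    return SimulantBout(seq=seq, truncated=truncated)


def _bout_error_totals(
    cum_rows: list[list[float]],
    start_cum: list[float],
    n_arms: int,
    n_bouts: int,
    cap: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-bout revisit-error counts without materializing visit sequences.

    Errors equal visits minus distinct arms visited, exactly as in
    :func:`winshift.ram.score_bout`.
    """
    rand = rng.random
    out = np.empty(n_bouts, dtype=np.int64)
    last = n_arms - 1
    for b in range(n_bouts):
        arm = min(bisect_right(start_cum, rand()), last)
        visited = 1 << arm
        n_visited = 1
        steps = 1
        errors = 0
        while n_visited < n_arms and steps < cap:
            arm = min(bisect_right(cum_rows[arm], rand()), last)
            bit = 1 << arm
            if visited & bit:
                errors += 1
            else:
                visited |= bit
                n_visited += 1
            steps += 1
        out[b] = errors
    return out


def generate_simulant_datasets(
    matrices: Sequence[TransitionMatrix],
    covariates: pd.DataFrame,
    n_replicates: int = 10_000,
    rng: np.random.Generator | None = None,
    stop: StopRule | None = None,
    n_bouts_col: str = "n_bouts",
) -> Iterator[SimulantDataset]:
    """Stream of resampled cohorts, one simulant per real bee.

    ``covariates`` must carry one row per bee (``bee_id`` column or index)
    with that bee's size/age covariates and its test-bout count in
    ``n_bouts_col``; each simulant inherits them.  Replicates are generated
    lazily so large replicate counts never hold all bouts in memory.
    """
    rng = np.random.default_rng() if rng is None else rng
    stop = StopRule() if stop is None else stop
    cov = covariates.reset_index() if covariates.index.name == "bee_id" else covariates.copy()
    if "bee_id" not in cov.columns:
        raise ValidationError("covariates need a bee_id column or index")
    cov = cov.set_index("bee_id")
    matrix_ids = [m.bee_id for m in matrices]
    missing = set(matrix_ids) ^ set(cov.index.astype(str))
    if missing:
        raise ValidationError(f"bee ids differ between matrices and covariates: {sorted(missing)}")
    prepared = []
    for m in matrices:
        cum_rows, start_cum = _cumulative_rows(m)
        n_bouts = int(cov.loc[m.bee_id, n_bouts_col])
        prepared.append((m, cum_rows, start_cum, n_bouts))

    def _generate() -> Iterator[SimulantDataset]:
        for r in range(n_replicates):
            bouts: list[VisitSequence] = []
            errors_by_bee: dict[str, np.ndarray] = {}
            for m, cum_rows, start_cum, n_bouts in prepared:
                cap = stop.cap_for(m.n_arms)
                errs = np.empty(n_bouts, dtype=np.int64)
                for i in range(n_bouts):
                    arms, _ = _sample_bout_arms(cum_rows, start_cum, m.n_arms, cap, rng)
                    seq = VisitSequence(
                        bee_id=m.bee_id,
                        bout_index=i + 1,
                        bout_type="test",
                        arms=tuple(arms),
                        n_arms=m.n_arms,
                    )
                    errs[i] = score_bout(seq).errors
                    bouts.append(seq)
                errors_by_bee[m.bee_id] = errs
            yield SimulantDataset(
                replicate_id=r,
                bees=cov.reset_index().copy(),
                bouts=bouts,
                errors_by_bee=errors_by_bee,
            )

    return _generate()


def simulant_mean_errors(
    matrices: Sequence[TransitionMatrix],
    n_bouts_by_bee: dict[str, int],
    n_replicates: int,
    rng: np.random.Generator | None = None,
    stop: StopRule | None = None,
) -> np.ndarray:
    """Per-replicate grand mean of simulant bout errors (fast path).

    Equivalent to scoring :func:`generate_simulant_datasets` output with the
    ``mean_errors`` statistic, but skips building visit-sequence objects so
    that thousands of replicates remain cheap.
    """
    rng = np.random.default_rng() if rng is None else rng
    stop = StopRule() if stop is None else stop
    prepared = []
    for m in matrices:
        cum_rows, start_cum = _cumulative_rows(m)
        prepared.append((cum_rows, start_cum, m.n_arms, int(n_bouts_by_bee[m.bee_id])))
    out = np.empty(n_replicates)
    for r in range(n_replicates):
        total = 0
        n = 0
        for cum_rows, start_cum, n_arms, n_bouts in prepared:
            errs = _bout_error_totals(
                cum_rows, start_cum, n_arms, n_bouts, stop.cap_for(n_arms), rng
            )
            total += int(errs.sum())
            n += n_bouts
        out[r] = total / n
    return out


class StatisticResult(NamedTuple):
    value: float
    statistic_used: str


def dataset_statistic(
    dataset: SimulantDataset, statistic: str = "mean_errors"
) -> StatisticResult:
    """Cohort performance statistic for one (real or simulant) dataset.

    ``mean_errors`` is the grand mean of per-bout revisit errors.
    ``model_intercept`` is the intercept of a hierarchical Poisson model of
    per-bout errors on body size and age with a per-bee random intercept
    (variational fit); if the model cannot be fitted the grand mean is
    returned instead, flagged via ``statistic_used``.
    """
    if dataset.errors_by_bee:
        per_bee = dataset.errors_by_bee
    else:
        per_bee = {}
        for b in dataset.bouts:
            per_bee.setdefault(b.bee_id, []).append(score_bout(b).errors)
        per_bee = {k: np.asarray(v) for k, v in per_bee.items()}
    all_errors = np.concatenate([np.atleast_1d(v) for v in per_bee.values()])
    mean_errors = float(all_errors.mean())
    if statistic == "mean_errors":
        return StatisticResult(mean_errors, "mean_errors")
    if statistic != "model_intercept":
        raise ValidationError(f"unknown statistic {statistic!r}")

    rows = []
    cov = dataset.bees.set_index(dataset.bees["bee_id"].astype(str))
    for bee, errs in per_bee.items():
        key = bee.removeprefix("sim:")
        size = float(cov.loc[key, "size_mm"]) if "size_mm" in cov.columns else 0.0
        age = float(cov.loc[key, "age_at_release"]) if "age_at_release" in cov.columns else 0.0
        for e in np.atleast_1d(errs):
            rows.append((bee, size, age, int(e)))
    df = pd.DataFrame(rows, columns=["bee_id", "size_mm", "age_at_release", "errors"])
    try:
        from statsmodels.genmod.bayes_mixed_glm import PoissonBayesMixedGLM

        # constant covariates are dropped to keep the VB fit well-posed
        terms = [
            c for c in ("size_mm", "age_at_release") if df[c].nunique() > 1
        ]
        fml = "errors ~ " + (" + ".join(terms) if terms else "1")
        model = PoissonBayesMixedGLM.from_formula(fml, {"bee": "0 + C(bee_id)"}, df)
        fit = model.fit_vb()
        intercept = float(fit.fe_mean[0])
        return StatisticResult(intercept, "model_intercept")
    except Exception as exc:  # pragma: no cover - backend failure path
        logger.warning("model_intercept fit failed (%s); falling back to mean_errors", exc)
        return StatisticResult(mean_errors, "mean_errors")


def percentile_p_value(
    observed: float, null_values: Sequence[float], tail: str = "lower"
) -> float:
    """Monte-Carlo percentile p-value with the add-one correction.

    ``lower``: p = (1 + #{v <= observed}) / (N + 1), for "fewer errors than the
    null" claims; ``upper`` mirrors it.  Never returns exactly zero.
    """
    null_values = np.asarray(null_values, dtype=float)
    if null_values.size == 0:
        raise ValidationError("null_values must be non-empty")
    if tail == "lower":
        k = int(np.sum(null_values <= observed))
    elif tail == "upper":
        k = int(np.sum(null_values >= observed))
    else:
        raise ValidationError(f"tail must be 'lower' or 'upper', got {tail!r}")
    return (1 + k) / (null_values.size + 1)


def run_validation(
    bouts_by_bee: dict[str, list[VisitSequence]],
    covariates: pd.DataFrame,
    n_arms: int,
    n_replicates: int = 10_000,
    statistic: str = "mean_errors",
    null: str = "empirical",
    tail: str = "lower",
    seed: int | None = None,
    pseudo_count: float = 0.0,
    stop: StopRule | None = None,
) -> NullDistribution:
    """Full RAM validation: observed cohort vs transition-matrix simulants.

    ``null='empirical'`` uses each bee's own transition matrix; ``'random'``
    replaces them with flat-Dirichlet random matrices of the same size (the
    chance baseline).  The lower tail asks whether real bees make fewer
    errors than their movement-rule simulants.
    """
    rng = np.random.default_rng(seed)
    matrices = [
        estimate_transition_matrix(bouts, n_arms=n_arms, pseudo_count=pseudo_count, bee_id=bee)
        for bee, bouts in bouts_by_bee.items()
    ]
    if null == "random":
        matrices = [
            random_transition_matrix(n_arms, rng=rng, bee_id=m.bee_id) for m in matrices
        ]
    elif null != "empirical":
        raise ValidationError(f"null must be 'empirical' or 'random', got {null!r}")

    observed_dataset = SimulantDataset(
        replicate_id=-1,
        bees=covariates.copy(),
        bouts=[b for bouts in bouts_by_bee.values() for b in bouts],
    )
    observed = dataset_statistic(observed_dataset, statistic)

    n_bouts_by_bee = {bee: len(bouts) for bee, bouts in bouts_by_bee.items()}
    if statistic == "mean_errors":
        values = simulant_mean_errors(matrices, n_bouts_by_bee, n_replicates, rng, stop)
    else:
        cov = covariates.copy()
        cov["n_bouts"] = cov["bee_id"].astype(str).map(n_bouts_by_bee)
        values = np.array(
            [
                dataset_statistic(ds, statistic).value
                for ds in generate_simulant_datasets(
                    matrices, cov, n_replicates, rng, stop
                )
            ]
        )
    p = percentile_p_value(observed.value, values, tail=tail)
    return NullDistribution(
        statistic_name=observed.statistic_used,
        values=values,
        observed=observed.value,
        p_value=p,
        tail=tail,
        seed=seed,
    )
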