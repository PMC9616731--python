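"""Radial-arm-maze (RAM) bout scoring and per-bee memory scores.

The RAM is a win-shift paradigm: each arm of the maze holds a single food
reward per foraging bout, so every return to an arm that was already visited
within the same bout is wasted effort.  Revisits are counted as *errors* and
the per-bee performance measure ("RAM score") is the mean number of errors
over the final test bouts of the design.  Lower scores indicate better
short-term memory for recently visited locations; nothing carries over between
bouts because all arms are re-baited.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from winshift.errors import DesignError, EmptyBoutError, ValidationError

__all__ = [
    "VisitSequence",
    "BoutScore",
    "RamScore",
    "Design",
    "DESIGNS",
    "score_bout",
    "ram_score",
    "bout_durations",
]

BOUT_TYPES = ("training", "test")


@dataclass(frozen=True)
class Design:
    """A RAM testing design: total bout count and how many final bouts are scored."""

    n_bouts: int
    n_test: int

    def __post_init__(self) -> None:
        if not 1 <= self.n_test <= self.n_bouts:
            raise ValidationError(
                f"invalid design: n_test={self.n_test}, n_bouts={self.n_bouts}"
            )

    def bout_type(self, bout_index: int) -> str:
        """Bout type for a 1-based bout index under this design."""
        if not 1 <= bout_index <= self.n_bouts:
            raise ValidationError(
                f"bout_index {bout_index} outside design of {self.n_bouts} bouts"
            )
        return "test" if bout_index > self.n_bouts - self.n_test else "training"


#: Main study design (12 bouts, last 3 scored) and the eight-arm validation
#: design (20 bouts, last 10 scored).
DESIGNS: dict[str, Design] = {
    "main": Design(n_bouts=12, n_test=3),
    "validation": Design(n_bouts=20, n_test=10),
}


@dataclass(frozen=True)
class VisitSequence:
    """Ordered arm visits within one RAM bout for one bee.

    Arms are 1-based identifiers in ``1..n_arms``.  ``timestamps`` (seconds,
    non-decreasing, one per visit) are optional and only needed for duration
    summaries.
    """

    bee_id: str
    bout_index: int
    bout_type: str
    arms: tuple[int, ...]
    n_arms: int
    timestamps: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "arms", tuple(int(a) for a in self.arms))
        if self.timestamps is not None:
            object.__setattr__(
                self, "timestamps", tuple(float(t) for t in self.timestamps)
            )
        if self.bout_index < 1:
            raise ValidationError(f"bout_index must be >= 1, got {self.bout_index}")
        if self.bout_type not in BOUT_TYPES:
            raise ValidationError(f"bout_type must be one of {BOUT_TYPES}")
        if self.n_arms < 2:
            raise ValidationError(f"n_arms must be >= 2, got {self.n_arms}")
        for a in self.arms:
            if not 1 <= a <= self.n_arms:
                raise ValidationError(
                    f"arm id {a} outside 1..{self.n_arms} "
                    f"(bee {self.bee_id}, bout {self.bout_index})"
                )
        if self.timestamps is not None:
            if len(self.timestamps) != len(self.arms):
                raise ValidationError(
                    "timestamps must have the same length as arms "
                    f"(bee {self.bee_id}, bout {self.bout_index})"
                )
            if any(
                b < a for a, b in zip(self.timestamps, self.timestamps[1:])
            ):
                raise ValidationError(
                    "timestamps must be non-decreasing "
                    f"(bee {self.bee_id}, bout {self.bout_index})"
                )

    def __len__(self) -> int:
        return len(self.arms)


@dataclass(frozen=True)
class BoutScore:
    """Error count and coverage for a single scored bout."""

    errors: int
    distinct_arms_visited: int
    completed: bool
    duration_min: float | None = None


@dataclass(frozen=True)
class RamScore:
    """Per-bee RAM score: mean errors over the designated test bouts."""

    bee_id: str
    score: float
    score_log1p: float = field(default=float("nan"))
    n_test_bouts: int = 0

    def __post_init__(self) -> None:
        if self.score < 0:
            raise ValidationError(f"RAM score must be >= 0, got {self.score}")
        if math.isnan(self.score_log1p):
            object.__setattr__(self, "score_log1p", math.log1p(self.score))


def score_bout(seq: VisitSequence, count_immediate_repeats: bool = True) -> BoutScore:
    """Score one bout: errors are revisits to arms already visited in the bout.

    Because the reward platform is replaced after every landing, an immediate
    re-landing on the current arm is a revisit and counts as an error by
    default; pass ``count_immediate_repeats=False`` to collapse consecutive
    duplicates first (sensitivity analysis only).
    """
    if len(seq.arms) == 0:
        raise EmptyBoutError(
            f"bout {seq.bout_index} of bee {seq.bee_id} has no visits"
        )
    arms: Sequence[int] = seq.arms
    if not count_immediate_repeats:
        arms = [a for i, a in enumerate(seq.arms) if i == 0 or a != seq.arms[i - 1]]
    distinct = len(set(arms))
    errors = len(arms) - distinct
    duration = None
    if seq.timestamps is not None and len(seq.timestamps) >= 1:
        duration = (seq.timestamps[-1] - seq.timestamps[0]) / 60.0
    return BoutScore(
        errors=errors,
        distinct_arms_visited=distinct,
        completed=distinct == seq.n_arms,
        duration_min=duration,
    )


def ram_score(
    bouts: Iterable[VisitSequence],
    test_bout_count: int = 3,
    count_immediate_repeats: bool = True,
) -> RamScore:
    """Mean errors over the last ``test_bout_count`` test bouts of one bee.

    Bouts terminated early (not all arms visited, e.g. because the nest
    shutter was opened) are scored by the same revisit rule; no imputation.
    """
    bouts = list(bouts)
    if not bouts:
        raise DesignError("no bouts supplied")
    bee_ids = {b.bee_id for b in bouts}
    if len(bee_ids) != 1:
        raise DesignError(f"bouts span multiple bees: {sorted(bee_ids)}")
    bee_id = bouts[0].bee_id
    test_bouts = sorted(
        (b for b in bouts if b.bout_type == "test"), key=lambda b: b.bout_index
    )
    if len(test_bouts) < test_bout_count:
        raise DesignError(
            f"bee {bee_id}: {len(test_bouts)} test bouts available, "
            f"{test_bout_count} required"
        )
    scored = test_bouts[-test_bout_count:]
    errors = [
        score_bout(b, count_immediate_repeats=count_immediate_repeats).errors
        for b in scored
    ]
    return RamScore(
        bee_id=bee_id,
        score=float(np.mean(errors)),
        n_test_bouts=test_bout_count,
    )


def bout_durations(seqs: Iterable[VisitSequence]) -> dict[str, float]:
    """Median and quartiles of per-bout durations (minutes, last − first visit).

    Raises :class:`ValidationError` if any bout lacks timestamps.
    """
    durations = []
    for s in seqs:
        if s.timestamps is None:
            raise ValidationError(
                f"bout {s.bout_index} of bee {s.bee_id} has no timestamps"
            )
        durations.append((s.timestamps[-1] - s.timestamps[0]) / 60.0)
    if not durations:
        raise ValidationError("no bouts supplied")
    q1, med, q3 = np.percentile(durations, [25, 50, 75])
    return {
        "n_bouts": len(durations),
        "median_min": float(med),
        "q1_min": float(q1),
        "q3_min": float(q3),
    }
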