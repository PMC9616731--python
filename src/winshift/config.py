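"""Run configuration for the end-to-end pipeline."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import yaml

from winshift.errors import ValidationError


@dataclass
class RunConfig:
    """Everything a reproducible pipeline run needs.

    Thresholds default to the study's choices (3 mg pollen split, 7 min
    minimum trip, 5 s RFID debounce, 120 s weigh matching); the design names
    refer to the RAM testing layouts (``main``: 12 bouts / last 3 scored,
    ``validation``: 20 bouts / last 10 scored).
    """

    seed: int = 0
    design: str = "main"
    n_arms: int = 4
    # simulate stage
    n_bees: int = 40
    n_colonies: int = 4
    lapse_rate: float = 0.1
    season: dict = field(default_factory=dict)  # SeasonParams overrides
    # validate stage
    replicates: int = 200
    statistic: str = "mean_errors"
    null: str = "empirical"
    # trips stage
    debounce_s: float = 5.0
    weigh_match_tol_s: float = 120.0
    nectar_max_pollen_mg: float = 3.0
    min_duration_min: float = 7.0
    # analyze stage
    analyses: tuple[str, ...] = ("nectar",)
    stages: tuple[str, ...] = ("simulate", "score", "validate", "trips", "analyze")

    def __post_init__(self) -> None:
        for name in ("debounce_s", "weigh_match_tol_s", "nectar_max_pollen_mg", "min_duration_min"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.replicates < 0:
            raise ValidationError("replicates must be >= 0")
        self.analyses = tuple(self.analyses)
        self.stages = tuple(self.stages)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)

    def hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]
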