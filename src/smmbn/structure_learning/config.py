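"""Learning-algorithm configuration and the default ensemble roster."""

from __future__ import annotations

import dataclasses
import json
from typing import Any

import yaml

from ..exceptions import ConfigurationError

__all__ = ["AlgorithmConfig", "default_roster", "ALGORITHMS"]

#: algorithm id -> family
ALGORITHMS = {
    "hc": "score-based",
    "tabu": "score-based",
    "gs": "constraint-based",
    "iamb": "constraint-based",
    "fast-iamb": "constraint-based",
    "inter-iamb": "constraint-based",
    "mmhc": "hybrid",
    "rsmax2": "hybrid",
}

_SCORED = {"hc", "tabu", "mmhc", "rsmax2"}


@dataclasses.dataclass(frozen=True)
class AlgorithmConfig:
    """One structure-learning configuration (algorithm + score/test knobs)."""

    algorithm: str
    score: str | None = None
    test: str = "g2"
    alpha: float = 0.05
    tabu_length: int = 10
    max_non_improving: int = 20
    max_sepset: int = 3
    min_obs_per_df: float | None = 5.0
    restrict: str = "mmpc"  # hybrid restrict phase: mmpc | iamb
    maximize: str = "hc"  # hybrid maximize phase: hc | tabu
    label: str | None = None

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ConfigurationError(f"unknown algorithm {self.algorithm!r}")
        if self.algorithm in _SCORED:
            if self.score is None:
                object.__setattr__(self, "score", "bic")
        elif self.score is not None:
            raise ConfigurationError(
                f"{self.algorithm!r} is not score-based; score must be None"
            )
        if not 0 < self.alpha < 1:
            raise ConfigurationError("alpha must be in (0, 1)")
        if self.test != "g2":
            raise ConfigurationError(f"unknown test {self.test!r}")
        if self.restrict not in ("mmpc", "iamb"):
            raise ConfigurationError(f"unknown restrict phase {self.restrict!r}")
        if self.maximize not in ("hc", "tabu"):
            raise ConfigurationError(f"unknown maximize phase {self.maximize!r}")
        if self.label is None:
            object.__setattr__(self, "label", self._default_label())

    @property
    def family(self) -> str:
        return ALGORITHMS[self.algorithm]

    def _default_label(self) -> str:
        if self.algorithm in ("hc", "tabu"):
            stem = {"hc": "HC", "tabu": "TS"}[self.algorithm]
            return f"{stem}-{self.score.upper()}"
        return self.algorithm.upper()

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "AlgorithmConfig":
        return cls(**d)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "AlgorithmConfig":
        return cls.from_dict(json.loads(text))

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "AlgorithmConfig":
        return cls.from_dict(yaml.safe_load(text))


def default_roster() -> list[AlgorithmConfig]:
    """The ensemble roster: two greedy searches x two scores, four
    Markov-blanket learners and two hybrids."""
    return [
        AlgorithmConfig("hc", score="bic"),
        AlgorithmConfig("hc", score="aic"),
        AlgorithmConfig("tabu", score="bic"),
        AlgorithmConfig("tabu", score="aic"),
        AlgorithmConfig("gs"),
        AlgorithmConfig("iamb"),
        AlgorithmConfig("fast-iamb"),
        AlgorithmConfig("inter-iamb"),
        AlgorithmConfig("mmhc", score="bic", restrict="mmpc", maximize="hc"),
        AlgorithmConfig("rsmax2", score="bic", restrict="iamb", maximize="tabu"),
    ]
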