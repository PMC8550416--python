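"""Configuration of the synthetic birth-record cohort generator."""

from __future__ import annotations

import dataclasses
import math
from typing import Mapping

from ..exceptions import ConfigurationError

__all__ = ["CohortConfig", "RACES", "AGES", "PARITIES"]

RACES = ("white", "black", "hispanic", "other")
AGES = ("<20", "20-34", "35-39", "40+")
PARITIES = ("0", "1", "2+")


def _freeze(mapping: Mapping[str, float]) -> dict[str, float]:
    return {str(k): float(v) for k, v in mapping.items()}


@dataclasses.dataclass(frozen=True)
class CohortConfig:
    """Knobs of the layered ground-truth network.

    The outcome CPT is parameterized by per-parent log-odds effects on top
    of a base log-odds that is solved numerically so the exact outcome
    marginal matches ``prevalence_target``.  Race-conditional comorbidity
    rows default to the published conditional probabilities (anemia
    0.14/0.07/0.11/0.12 and hypertensive disorder 0.13/0.11/0.09/0.09 for
    black/white/hispanic/other); all remaining rows are free calibration
    choices.
    """

    n: int = 50_000
    seed: int = 0
    prevalence_target: float = 0.02
    race_dist: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: {
            "white": 0.60, "black": 0.20, "hispanic": 0.12, "other": 0.08
        }
    )
    anemia_by_race: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: {
            "white": 0.07, "black": 0.14, "hispanic": 0.11, "other": 0.12
        }
    )
    hdp_by_race: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: {
            "white": 0.11, "black": 0.13, "hispanic": 0.09, "other": 0.09
        }
    )
    preexisting_htn_by_age: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: {
            "<20": 0.02, "20-34": 0.05, "35-39": 0.15, "40+": 0.30
        }
    )
    diabetes_by_age: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: {
            "<20": 0.03, "20-34": 0.06, "35-39": 0.18, "40+": 0.35
        }
    )
    prior_cesarean_by_parity: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: {"0": 0.02, "1": 0.28, "2+": 0.45}
    )
    obesity_p: float = 0.25
    mental_health_p: float = 0.15
    #: per-parent log-odds increments of the outcome; 0 means no effect
    outcome_effects: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: {
            "anemia": math.log(4.5),
            "hdp": math.log(4.0),
            "prior_cesarean": math.log(3.0),
        }
    )
    #: off-diagonal probability mass of quartile-to-quartile couplings
    quartile_noise: float = 0.30

    def __post_init__(self) -> None:
        object.__setattr__(self, "race_dist", _freeze(self.race_dist))
        for field in (
            "anemia_by_race",
            "hdp_by_race",
            "preexisting_htn_by_age",
            "diabetes_by_age",
            "prior_cesarean_by_parity",
        ):
            object.__setattr__(self, field, _freeze(getattr(self, field)))
        object.__setattr__(
            self,
            "outcome_effects",
            {str(k): float(v) for k, v in self.outcome_effects.items()},
        )
        if self.n < 1:
            raise ConfigurationError("n must be >= 1")
        if abs(sum(self.race_dist.values()) - 1.0) > 1e-9:
            raise ConfigurationError("race distribution must sum to 1")
        if set(self.race_dist) != set(RACES):
            raise ConfigurationError(f"race_dist must cover {RACES}")
        probs = [
            *self.race_dist.values(),
            *self.anemia_by_race.values(),
            *self.hdp_by_race.values(),
            *self.preexisting_htn_by_age.values(),
            *self.diabetes_by_age.values(),
            *self.prior_cesarean_by_parity.values(),
            self.obesity_p,
            self.mental_health_p,
        ]
        if not all(0.0 < p < 1.0 for p in probs):
            raise ConfigurationError("probabilities must lie in (0, 1)")
        if not 0.0 < self.prevalence_target < 1.0:
            raise ConfigurationError("prevalence target must lie in (0, 1)")
        if not 0.0 < self.quartile_noise < 1.0:
            raise ConfigurationError("quartile noise must lie in (0, 1)")

    def replace(self, **changes) -> "CohortConfig":
        return dataclasses.replace(self, **changes)
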