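"""The calibrated layered ground-truth network behind the synthetic cohort.

Three layers: demographics and county quartile variables (layer 0),
comorbidity flags (layer 1) and the binary outcome (layer 2, parents
anemia / hypertensive disorder / prior cesarean).  The outcome base
log-odds is solved so the exact outcome marginal equals the configured
prevalence target.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy import optimize

from ..bn_core.cpt import CptSet
from ..bn_core.dataset import VariableSpec
from ..bn_core.graph import Dag
from ..exceptions import ConfigurationError
from .config import AGES, PARITIES, RACES, CohortConfig

__all__ = [
    "default_ground_truth",
    "exact_outcome_prevalence",
    "exact_outcome_given_race",
    "solve_outcome_base",
    "OUTCOME",
    "OUTCOME_PARENTS",
]

OUTCOME = "smm"
OUTCOME_PARENTS = ("anemia", "hdp", "prior_cesarean")

YESNO = ("no", "yes")
QUARTILES = ("Q1", "Q2", "Q3", "Q4")

_AGE_DIST = (0.08, 0.72, 0.14, 0.06)
_EDU_LEVELS = ("less_hs", "hs_grad", "some_college")
_EDU_DIST = (0.12, 0.35, 0.53)
_INSURANCE_LEVELS = ("medicaid", "private", "other")
_INSURANCE_BY_EDU = {
    "less_hs": (0.80, 0.12, 0.08),
    "hs_grad": (0.55, 0.35, 0.10),
    "some_college": (0.20, 0.72, 0.08),
}
_MARRIED_BY_RACE = {"white": 0.65, "black": 0.30, "hispanic": 0.55, "other": 0.60}
_PARITY_DIST = (0.40, 0.32, 0.28)
_PCT_BLACK_BY_RACE = {
    "white": (0.55, 0.28, 0.12, 0.05),
    "black": (0.03, 0.07, 0.20, 0.70),
    "hispanic": (0.25, 0.30, 0.25, 0.20),
    "other": (0.25, 0.25, 0.25, 0.25),
}


def _binary_rows(p_yes_by_level, levels) -> np.ndarray:
    return np.array([[1.0 - p_yes_by_level[l], p_yes_by_level[l]] for l in levels])


def _quartile_coupling(noise: float) -> np.ndarray:
    """4x4 row-stochastic coupling: stay with prob 1-noise, else uniform."""
    table = np.full((4, 4), noise / 3.0)
    np.fill_diagonal(table, 1.0 - noise)
    return table


def _sigmoid(z: float) -> float:
    return 1.0 / (1.0 + math.exp(-z))


def _outcome_parent_joint(config: CohortConfig) -> dict[tuple[int, int, int], float]:
    """Exact joint of (anemia, hdp, prior cesarean) under the ground truth.

    Anemia and hypertensive disorder are conditionally independent given
    race; prior cesarean depends only on parity, which is independent of
    race, so the joint factorizes into a race mixture times a parity
    mixture.
    """
    race_p = [config.race_dist[r] for r in RACES]
    p_c = sum(
        _PARITY_DIST[i] * config.prior_cesarean_by_parity[PARITIES[i]]
        for i in range(len(PARITIES))
    )
    joint: dict[tuple[int, int, int], float] = {}
    for a, h, c in itertools.product((0, 1), repeat=3):
        p_ah = 0.0
        for r, pr in zip(RACES, race_p):
            pa = config.anemia_by_race[r]
            ph = config.hdp_by_race[r]
            p_ah += pr * (pa if a else 1 - pa) * (ph if h else 1 - ph)
        joint[(a, h, c)] = p_ah * (p_c if c else 1 - p_c)
    return joint


def _effects_vector(config: CohortConfig) -> dict[str, float]:
    effects = dict.fromkeys(OUTCOME_PARENTS, 0.0)
    for name, value in config.outcome_effects.items():
        if name not in effects:
            raise ConfigurationError(f"unknown outcome parent {name!r}")
        effects[name] = float(value)
    return effects


def _prevalence_at(base: float, config: CohortConfig) -> float:
    effects = _effects_vector(config)
    joint = _outcome_parent_joint(config)
    return sum(
        p
        * _sigmoid(
            base
            + a * effects["anemia"]
            + h * effects["hdp"]
            + c * effects["prior_cesarean"]
        )
        for (a, h, c), p in joint.items()
    )


def solve_outcome_base(config: CohortConfig) -> float:
    """Base log-odds making the exact outcome marginal hit the target."""
    lo, hi = -25.0, 15.0
    f = lambda b: _prevalence_at(b, config) - config.prevalence_target
    if f(lo) > 0 or f(hi) < 0:
        raise ConfigurationError(
            "prevalence target infeasible for the given outcome effects"
        )
    return float(optimize.brentq(f, lo, hi, xtol=1e-12))


def default_ground_truth(config: CohortConfig | None = None) -> tuple[Dag, CptSet]:
    """Build the layered ground-truth network for ``config``."""
    config = config or CohortConfig()
    q = _quartile_coupling(config.quartile_noise)

    specs = [
        VariableSpec("race", RACES, 0),
        VariableSpec("age", AGES, 0),
        VariableSpec("education", _EDU_LEVELS, 0),
        VariableSpec("insurance", _INSURANCE_LEVELS, 0),
        VariableSpec("married", YESNO, 0),
        VariableSpec("parity", PARITIES, 0),
        VariableSpec("pct_black_q", QUARTILES, 0),
        VariableSpec("pct_urban_q", QUARTILES, 0),
        VariableSpec("pct_poverty_q", QUARTILES, 0),
        VariableSpec("pct_owner_q", QUARTILES, 0),
        VariableSpec("obgyn_q", QUARTILES, 0),
        VariableSpec("anemia", YESNO, 1),
        VariableSpec("hdp", YESNO, 1),
        VariableSpec("preexisting_htn", YESNO, 1),
        VariableSpec("prior_cesarean", YESNO, 1),
        VariableSpec("diabetes", YESNO, 1),
        VariableSpec("obesity", YESNO, 1),
        VariableSpec("mental_health", YESNO, 1),
        VariableSpec(OUTCOME, YESNO, 2),
    ]

    parents = {
        "race": (),
        "age": (),
        "education": (),
        "insurance": ("education",),
        "married": ("race",),
        "parity": (),
        "pct_black_q": ("race",),
        "pct_urban_q": ("pct_black_q",),
        "pct_poverty_q": ("pct_black_q",),
        "pct_owner_q": ("pct_urban_q",),
        "obgyn_q": ("pct_urban_q",),
        "anemia": ("race",),
        "hdp": ("race",),
        "preexisting_htn": ("age",),
        "prior_cesarean": ("parity",),
        "diabetes": ("age",),
        "obesity": (),
        "mental_health": (),
        OUTCOME: OUTCOME_PARENTS,
    }

    effects = _effects_vector(config)
    base = solve_outcome_base(config)
    outcome_rows = []
    for a, h, c in itertools.product((0, 1), repeat=3):
        p = _sigmoid(
            base
            + a * effects["anemia"]
            + h * effects["hdp"]
            + c * effects["prior_cesarean"]
        )
        outcome_rows.append([1.0 - p, p])

    tables = {
        "race": np.array([[config.race_dist[r] for r in RACES]]),
        "age": np.array([_AGE_DIST]),
        "education": np.array([_EDU_DIST]),
        "insurance": np.array([_INSURANCE_BY_EDU[e] for e in _EDU_LEVELS]),
        "married": _binary_rows(_MARRIED_BY_RACE, RACES),
        "parity": np.array([_PARITY_DIST]),
        "pct_black_q": np.array([_PCT_BLACK_BY_RACE[r] for r in RACES]),
        "pct_urban_q": q,
        "pct_poverty_q": q,
        "pct_owner_q": q,
        "obgyn_q": q,
        "anemia": _binary_rows(config.anemia_by_race, RACES),
        "hdp": _binary_rows(config.hdp_by_race, RACES),
        "preexisting_htn": _binary_rows(config.preexisting_htn_by_age, AGES),
        "prior_cesarean": _binary_rows(config.prior_cesarean_by_parity, PARITIES),
        "diabetes": _binary_rows(config.diabetes_by_age, AGES),
        "obesity": np.array([[1.0 - config.obesity_p, config.obesity_p]]),
        "mental_health": np.array(
            [[1.0 - config.mental_health_p, config.mental_health_p]]
        ),
        OUTCOME: np.array(outcome_rows),
    }

    dag = Dag([s.name for s in specs])
    for child, pa in parents.items():
        for p in pa:
            dag.add_arc(p, child)
    return dag, CptSet(specs, parents, tables)


def exact_outcome_prevalence(config: CohortConfig | None = None) -> float:
    """Exact outcome marginal by closed-form marginalization."""
    config = config or CohortConfig()
    return _prevalence_at(solve_outcome_base(config), config)


def exact_outcome_given_race(config: CohortConfig, race: str) -> float:
    """Exact P(outcome = yes | race) by marginalizing the parent joint."""
    if race not in RACES:
        raise ConfigurationError(f"unknown race level {race!r}")
    effects = _effects_vector(config)
    base = solve_outcome_base(config)
    p_c = sum(
        _PARITY_DIST[i] * config.prior_cesarean_by_parity[PARITIES[i]]
        for i in range(len(PARITIES))
    )
    pa, ph = config.anemia_by_race[race], config.hdp_by_race[race]
    total = 0.0
    for a, h, c in itertools.product((0, 1), repeat=3):
        weight = (
            (pa if a else 1 - pa)
            * (ph if h else 1 - ph)
            * (p_c if c else 1 - p_c)
        )
        total += weight * _sigmoid(
            base
            + a * effects["anemia"]
            + h * effects["hdp"]
            + c * effects["prior_cesarean"]
        )
    return total
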