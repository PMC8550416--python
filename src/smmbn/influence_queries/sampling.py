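"""Likelihood-weighting conditional queries and Monte-Carlo odds ratios.

Likelihood weighting clamps evidence nodes during ancestral simulation and
weights each sample by the product of the evidence CPT entries; the query
estimate is the weighted fraction of samples satisfying the event.  The
network is never mutated by a query.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Mapping

import numpy as np

from ..bn_core.cpt import CptSet, _config_index
from ..bn_core.dataset import DiscreteDataset
from ..bn_core.graph import Dag
from ..exceptions import (
    ContractError,
    DegenerateOddsError,
    UndefinedConditionalError,
)

__all__ = ["QueryResult", "lw_query", "odds_ratio", "OddsRatioResult"]


def _lw_batch(
    dag: Dag,
    cpts: CptSet,
    event: dict[str, int],
    evidence: dict[str, int],
    n: int,
    rng: np.random.Generator,
) -> tuple[float, float]:
    """One weighted batch; returns (sum of event weights, sum of weights)."""
    names = list(cpts.nodes)
    pos = {name: j for j, name in enumerate(names)}
    codes = np.zeros((n, len(names)), dtype=np.int64)
    logw = np.zeros(n)
    for name in dag.topological_order():
        pa = cpts.parents(name)
        cards = [cpts.cardinality(p) for p in pa]
        cfg = _config_index(codes, [pos[p] for p in pa], cards)
        rows = cpts.table(name)[cfg]
        if name in evidence:
            codes[:, pos[name]] = evidence[name]
            with np.errstate(divide="ignore"):
                logw += np.log(rows[:, evidence[name]])
        else:
            cum = np.cumsum(rows, axis=1)
            u = rng.random(n)
            codes[:, pos[name]] = (u[:, None] < cum).argmax(axis=1)
    weights = np.exp(logw)
    hit = np.ones(n, dtype=bool)
    for name, code in event.items():
        hit &= codes[:, pos[name]] == code
    return float(weights[hit].sum()), float(weights.sum())


@dataclasses.dataclass(frozen=True)
class QueryResult:
    """Monte-Carlo conditional probability estimate with replicate spread."""

    event: dict[str, object]
    evidence: dict[str, object]
    estimate: float
    n_samples: int
    replicate_estimates: tuple[float, ...]
    interval: tuple[float, float]

    def __post_init__(self) -> None:
        if not 0.0 <= self.estimate <= 1.0:
            raise ContractError("estimate outside [0, 1]")
        if len(self.replicate_estimates) < 1:
            raise ContractError("at least one replicate required")
        lo, hi = self.interval
        if not lo <= self.estimate <= hi:
            raise ContractError("interval must contain the estimate")


def lw_query(
    dag: Dag,
    cpts: CptSet,
    event: Mapping[str, object],
    evidence: Mapping[str, object] | None = None,
    n_samples: int = 100_000,
    seed: int | np.random.Generator | None = None,
    replicates: int = 10,
) -> QueryResult:
    """Estimate P(event | evidence) by likelihood weighting.

    ``n_samples`` is the total budget, split across ``replicates``
    independent batches; the point estimate pools all batches and the
    interval is the 2.5/97.5 percentile range of the batch estimates
    (widened to contain the pooled estimate if needed).
    """
    evidence = dict(evidence or {})
    event = dict(event)
    if not event:
        raise ContractError("event must be non-empty")
    # an event variable that is also clamped as evidence degenerates to an
    # indicator: 1 at the clamped level, 0 elsewhere (handled naturally by
    # comparing clamped sample codes against the event codes)
    if n_samples < 1 or replicates < 1:
        raise ContractError("n_samples and replicates must be >= 1")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    ev_codes = {n: cpts.resolve(n, v) for n, v in evidence.items()}
    event_codes = {n: cpts.resolve(n, v) for n, v in event.items()}
    per_batch = max(1, n_samples // replicates)
    batch_estimates: list[float] = []
    hit_total = 0.0
    weight_total = 0.0
    for _ in range(replicates):
        hits, weights = _lw_batch(dag, cpts, event_codes, ev_codes, per_batch, rng)
        hit_total += hits
        weight_total += weights
        batch_estimates.append(hits / weights if weights > 0 else np.nan)
    if weight_total <= 0.0:
        raise UndefinedConditionalError(
            "all likelihood weights are zero under the evidence"
        )
    estimate = hit_total / weight_total
    finite = [b for b in batch_estimates if np.isfinite(b)]
    lo, hi = np.percentile(finite, [2.5, 97.5])
    interval = (min(float(lo), estimate), max(float(hi), estimate))
    return QueryResult(
        event=dict(event),
        evidence=dict(evidence),
        estimate=float(estimate),
        n_samples=per_batch * replicates,
        replicate_estimates=tuple(float(b) for b in batch_estimates),
        interval=interval,
    )


@dataclasses.dataclass(frozen=True)
class OddsRatioResult:
    event: dict[str, object]
    group_var: str
    level: object
    ref_level: object
    odds_ratio: float
    interval: tuple[float, float]
    p_level: float
    p_ref: float
    replicate_ors: tuple[float, ...]


def _odds(p: float) -> float:
    if p <= 0.0 or p >= 1.0:
        raise DegenerateOddsError(f"probability {p} has no finite odds")
    return p / (1.0 - p)


def odds_ratio(
    dag: Dag,
    cpts: CptSet,
    event: Mapping[str, object],
    group_var: str,
    level,
    ref_level,
    n_samples: int = 100_000,
    replicates: int = 30,
    seed: int | None = None,
) -> OddsRatioResult:
    """Odds ratio of ``event`` between two levels of ``group_var``.

    Both conditional probabilities are estimated by likelihood weighting
    with ``replicates`` independent replicate pairs; the interval is the
    2.5/97.5 percentile range of the per-replicate odds ratios.
    """
    if level == ref_level:
        raise ContractError("level and ref_level must differ")
    rng = np.random.default_rng(seed)
    res1 = lw_query(
        dag, cpts, event, {group_var: level}, n_samples, rng, replicates
    )
    res0 = lw_query(
        dag, cpts, event, {group_var: ref_level}, n_samples, rng, replicates
    )
    point = _odds(res1.estimate) / _odds(res0.estimate)
    rep_ors = []
    for p1, p0 in zip(res1.replicate_estimates, res0.replicate_estimates):
        if 0.0 < p1 < 1.0 and 0.0 < p0 < 1.0:
            rep_ors.append(_odds(p1) / _odds(p0))
    if not rep_ors:
        raise DegenerateOddsError("no replicate produced finite odds")
    lo, hi = np.percentile(rep_ors, [2.5, 97.5])
    return OddsRatioResult(
        event=dict(event),
        group_var=group_var,
        level=level,
        ref_level=ref_level,
        odds_ratio=float(point),
        interval=(float(lo), float(hi)),
        p_level=res1.estimate,
        p_ref=res0.estimate,
        replicate_ors=tuple(rep_ors),
    )
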