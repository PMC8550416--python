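"""Markov-blanket discovery: Grow-Shrink and the IAMB family.

All variants share the same memoized G^2 oracle.  Conventions:

* GS scans variables in dataset order, growing until stable, then shrinks.
* IAMB grows by maximal association given the current blanket, then runs a
  backward removal pass.
* Fast-IAMB adds speculatively in ranked batches per pass (the batch stops
  when the next test would fall under the data-reliability heuristic), with
  a backward pass after each batch.
* Inter-IAMB interleaves the backward pass after every single addition.
"""

from __future__ import annotations

from ..bn_core.dataset import DiscreteDataset
from ..exceptions import ContractError
from .ci_tests import CiOracle

__all__ = ["learn_markov_blanket", "MB_VARIANTS"]

MB_VARIANTS = ("gs", "iamb", "fast-iamb", "inter-iamb")


def learn_markov_blanket(
    target: str,
    data: DiscreteDataset,
    variant: str = "iamb",
    alpha: float = 0.05,
    min_obs_per_df: float | None = 5.0,
    oracle: CiOracle | None = None,
) -> frozenset[str]:
    """Learn the Markov blanket of ``target`` from data."""
    if variant not in MB_VARIANTS:
        raise ContractError(f"unknown Markov-blanket variant {variant!r}")
    data.index_of(target)
    oracle = oracle or CiOracle(data, alpha, min_obs_per_df)
    grow = {
        "gs": _grow_gs,
        "iamb": _grow_iamb,
        "fast-iamb": _grow_fast_iamb,
        "inter-iamb": _grow_inter_iamb,
    }[variant]
    mb = grow(target, data, oracle)
    mb = _shrink(target, mb, oracle)
    return frozenset(mb)


def _shrink(target, mb, oracle) -> set[str]:
    """Backward pass: drop members independent of target given the rest."""
    mb = set(mb)
    changed = True
    while changed:
        changed = False
        for x in sorted(mb):
            if not oracle.dependent(target, x, mb - {x}):
                mb.discard(x)
                changed = True
    return mb


def _grow_gs(target, data, oracle) -> set[str]:
    mb: set[str] = set()
    changed = True
    while changed:
        changed = False
        for x in data.names:
            if x == target or x in mb:
                continue
            if oracle.dependent(target, x, mb):
                mb.add(x)
                changed = True
    return mb


def _grow_iamb(target, data, oracle) -> set[str]:
    mb: set[str] = set()
    while True:
        best, best_assoc = None, 0.0
        for x in data.names:
            if x == target or x in mb:
                continue
            res = oracle.test(target, x, mb)
            if res.independent:
                continue
            if best is None or res.statistic > best_assoc:
                best, best_assoc = x, res.statistic
        if best is None:
            return mb
        mb.add(best)


def _grow_fast_iamb(target, data, oracle) -> set[str]:
    mb: set[str] = set()
    seen = {frozenset(mb)}
    while True:
        ranked = []
        for x in data.names:
            if x == target or x in mb:
                continue
            res = oracle.test(target, x, mb)
            if not res.independent:
                ranked.append((-res.statistic, x))
        if not ranked:
            return mb
        ranked.sort()
        added = False
        for _, x in ranked:
            if x in mb:
                continue
            res = oracle.test(target, x, mb)
            if res.unreliable:
                break  # speculative batch exhausted the data
            if not res.independent:
                mb.add(x)
                added = True
        if not added:
            return mb
        mb = _shrink(target, mb, oracle)
        if frozenset(mb) in seen:  # grow/shrink fixpoint cycle
            return mb
        seen.add(frozenset(mb))


def _grow_inter_iamb(target, data, oracle) -> set[str]:
    mb: set[str] = set()
    seen = {frozenset(mb)}
    while True:
        best, best_assoc = None, 0.0
        for x in data.names:
            if x == target or x in mb:
                continue
            res = oracle.test(target, x, mb)
            if res.independent:
                continue
            if best is None or res.statistic > best_assoc:
                best, best_assoc = x, res.statistic
        if best is None:
            return mb
        mb.add(best)
        mb = _shrink(target, mb, oracle)
        if frozenset(mb) in seen:  # interleaved add/remove cycle
            return mb
        seen.add(frozenset(mb))
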