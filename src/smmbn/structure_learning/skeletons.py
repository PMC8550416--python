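"""Skeleton-producing phases: MMPC and the Markov-blanket skeleton.

Both return undirected edge sets (frozensets of node pairs).  Edges whose
two directions are both blacklisted are removed; whitelisted arcs are always
kept in the skeleton.
"""

from __future__ import annotations

import itertools

from ..bn_core.dataset import DiscreteDataset
from .blanket import learn_markov_blanket
from .ci_tests import CiOracle
from .config import AlgorithmConfig
from .constraints import EMPTY_CONSTRAINTS, ConstraintSet

__all__ = ["mmpc_skeleton", "iamb_skeleton", "find_separating_set"]


def _subsets(pool, max_size):
    pool = sorted(pool)
    for size in range(0, min(max_size, len(pool)) + 1):
        yield from itertools.combinations(pool, size)


def find_separating_set(x, y, candidates, oracle, max_size):
    """First subset of ``candidates`` rendering x, y independent, or None."""
    for s in _subsets(set(candidates) - {x, y}, max_size):
        if oracle.test(x, y, s).independent:
            return frozenset(s)
    return None


def _apply_edge_constraints(edges, constraints: ConstraintSet):
    out = {e for e in edges if constraints.allows_edge(*sorted(e))}
    out |= {frozenset(a) for a in constraints.whitelist}
    return out


def mmpc_skeleton(
    data: DiscreteDataset,
    config: AlgorithmConfig | None = None,
    constraints: ConstraintSet = EMPTY_CONSTRAINTS,
    oracle: CiOracle | None = None,
) -> set[frozenset[str]]:
    """Max-min candidate parent/children skeleton with the AND rule.

    Forward phase: repeatedly add the candidate whose *weakest* association
    with the target over subsets of the current set is strongest (largest
    minimum G^2, i.e. smallest maximum p-value); stop when no candidate stays
    dependent under every subset.  Backward phase removes false positives.
    An edge is kept only when found from both endpoints.
    """
    config = config or AlgorithmConfig("mmhc")
    oracle = oracle or CiOracle(data, config.alpha, config.min_obs_per_df)
    max_k = config.max_sepset
    cpc: dict[str, set[str]] = {}
    for t in data.names:
        cands = [
            x
            for x in data.names
            if x != t and constraints.allows_edge(t, x)
        ]
        cpc[t] = _mmpc_one(t, cands, oracle, max_k)
    edges = {
        frozenset((t, x))
        for t in data.names
        for x in cpc[t]
        if t in cpc[x]  # AND rule
    }
    return _apply_edge_constraints(edges, constraints)


def _mmpc_one(target, candidates, oracle, max_k) -> set[str]:
    cpc: set[str] = set()
    remaining = [x for x in candidates]
    while True:
        best, best_maxp = None, None
        for x in sorted(remaining):
            max_p = max(
                oracle.test(target, x, s).p_value
                for s in _subsets(cpc, max_k)
            )
            if max_p > oracle.alpha:
                continue  # separable -> not a candidate this round
            if best is None or max_p < best_maxp:
                best, best_maxp = x, max_p
        if best is None:
            break
        cpc.add(best)
        remaining.remove(best)
        # backward: drop members separable given the rest
        for y in sorted(cpc):
            if find_separating_set(target, y, cpc - {y}, oracle, max_k) is not None:
                cpc.discard(y)
    return cpc


def iamb_skeleton(
    data: DiscreteDataset,
    config: AlgorithmConfig | None = None,
    constraints: ConstraintSet = EMPTY_CONSTRAINTS,
    variant: str = "iamb",
    oracle: CiOracle | None = None,
) -> set[frozenset[str]]:
    """Markov-blanket skeleton: symmetric blankets resolved to neighbours.

    Blankets are symmetrized with the AND rule; a blanket member stays a
    neighbour unless some subset of the smaller blanket separates the pair.
    """
    config = config or AlgorithmConfig("iamb")
    oracle = oracle or CiOracle(data, config.alpha, config.min_obs_per_df)
    mbs = {
        t: set(
            learn_markov_blanket(
                t, data, variant, config.alpha, config.min_obs_per_df, oracle
            )
        )
        for t in data.names
    }
    # AND-rule symmetry
    for t in data.names:
        mbs[t] = {x for x in mbs[t] if t in mbs[x]}
    edges: set[frozenset[str]] = set()
    for t, x in itertools.combinations(data.names, 2):
        if x not in mbs[t]:
            continue
        pool = min(mbs[t] - {x}, mbs[x] - {t}, key=len)
        sep = find_separating_set(t, x, pool, oracle, config.max_sepset)
        if sep is None:
            edges.add(frozenset((t, x)))
    return _apply_edge_constraints(edges, constraints)
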