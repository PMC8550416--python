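"""Constraint-based learning: blankets -> skeleton -> colliders -> Meek."""

from __future__ import annotations

import itertools

from ..bn_core.dataset import DiscreteDataset
from ..bn_core.graph import Pdag, _meek_closure
from .blanket import learn_markov_blanket
from .ci_tests import CiOracle
from .config import AlgorithmConfig
from .constraints import EMPTY_CONSTRAINTS, ConstraintSet
from .skeletons import find_separating_set

__all__ = ["constraint_learn", "orient_skeleton"]


def constraint_learn(
    data: DiscreteDataset,
    config: AlgorithmConfig | None = None,
    constraints: ConstraintSet = EMPTY_CONSTRAINTS,
) -> Pdag:
    """Markov-blanket-based structure learning returning a PDAG.

    The blanket variant is taken from ``config.algorithm`` (gs / iamb /
    fast-iamb / inter-iamb).  Blankets are symmetrized (AND rule), resolved
    to neighbours via separating-set search, v-structures oriented from the
    recorded separating sets, constraint directions applied and the Meek
    rules iterated to a fixpoint.
    """
    config = config or AlgorithmConfig("iamb")
    variant = config.algorithm if config.algorithm != "mmhc" else "iamb"
    oracle = CiOracle(data, config.alpha, config.min_obs_per_df)
    mbs = {
        t: set(
            learn_markov_blanket(
                t, data, variant, config.alpha, config.min_obs_per_df, oracle
            )
        )
        for t in data.names
    }
    for t in data.names:
        mbs[t] = {x for x in mbs[t] if t in mbs[x]}

    edges: set[frozenset[str]] = set()
    sepsets: dict[frozenset[str], frozenset[str]] = {}
    for t, x in itertools.combinations(data.names, 2):
        pair = frozenset((t, x))
        if not constraints.allows_edge(t, x) and not constraints.requires(t, x) \
                and not constraints.requires(x, t):
            continue
        if x not in mbs[t]:
            continue
        pool = min(mbs[t] - {x}, mbs[x] - {t}, key=len)
        sep = find_separating_set(t, x, pool, oracle, config.max_sepset)
        if sep is None:
            edges.add(pair)
        else:
            sepsets[pair] = sep
    for u, v in constraints.whitelist:
        edges.add(frozenset((u, v)))
    return orient_skeleton(
        data.names, edges, sepsets, constraints, oracle, config.max_sepset
    )


def orient_skeleton(
    nodes,
    edges: set[frozenset[str]],
    sepsets: dict[frozenset[str], frozenset[str]],
    constraints: ConstraintSet = EMPTY_CONSTRAINTS,
    oracle: CiOracle | None = None,
    max_sepset: int = 3,
) -> Pdag:
    """Collider orientation + constraint directions + Meek closure."""
    pdag = Pdag(nodes)
    adj: dict[str, set[str]] = {n: set() for n in nodes}
    for e in edges:
        u, v = sorted(e)
        pdag.add_undirected(u, v)
        adj[u].add(v)
        adj[v].add(u)

    # forced directions from the blacklist / whitelist
    for e in sorted(edges, key=sorted):
        u, v = sorted(e)
        if constraints.requires(u, v):
            pdag.orient(u, v)
        elif constraints.requires(v, u):
            pdag.orient(v, u)
        else:
            forced = constraints.forced_direction(u, v)
            if forced is not None:
                pdag.orient(*forced)

    # v-structures: x - y - z with x, z non-adjacent and y outside sepset(x, z)
    for y in sorted(nodes):
        for x, z in itertools.combinations(sorted(adj[y]), 2):
            if z in adj[x]:
                continue
            pair = frozenset((x, z))
            sep = sepsets.get(pair)
            if sep is None and oracle is not None:
                sep = find_separating_set(
                    x, z, (adj[x] | adj[z]) - {x, z}, oracle, max_sepset
                )
                if sep is not None:
                    sepsets[pair] = sep
            if sep is None or y in sep:
                continue
            for a in (x, z):
                if (
                    not pdag.has_directed(y, a)
                    and constraints.allows(a, y)
                ):
                    pdag.orient(a, y)
    _meek_closure(pdag)
    return pdag
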