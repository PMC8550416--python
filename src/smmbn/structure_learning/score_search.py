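"""Greedy score-based search: hill climbing and tabu search.

Both searches start from the empty graph plus whitelisted arcs and explore
single-arc moves (add < delete < reverse, then lexicographic on endpoints,
for deterministic tie-breaking).  Family scores are cached so only the moved
child's family is re-scored.
"""

from __future__ import annotations

from collections import deque

from ..bn_core.dataset import DiscreteDataset
from ..bn_core.graph import Dag
from ..exceptions import ConfigurationError
from .config import AlgorithmConfig
from .constraints import EMPTY_CONSTRAINTS, ConstraintSet
from .scores import ScoreCache

__all__ = ["hill_climb", "tabu_search"]

_EPS = 1e-10

# move kinds in deterministic preference order
_ADD, _DELETE, _REVERSE = "add", "delete", "reverse"


def _initial_dag(nodes, constraints: ConstraintSet) -> Dag:
    dag = Dag(nodes)
    for u, v in sorted(constraints.whitelist):
        if u not in dag.nodes or v not in dag.nodes:
            raise ConfigurationError(
                f"whitelisted arc ({u!r}, {v!r}) references unknown variables"
            )
        if not constraints.allows(u, v):
            raise ConfigurationError("whitelist and blacklist conflict")
        dag.add_arc(u, v)
    return dag


def _legal_moves(dag: Dag, constraints: ConstraintSet, skeleton):
    """Yield (kind, u, v) in deterministic order."""
    nodes = dag.nodes
    for u in nodes:
        for v in nodes:
            if u == v or dag.adjacent(u, v):
                continue
            if not constraints.allows(u, v):
                continue
            if skeleton is not None and frozenset((u, v)) not in skeleton:
                continue
            if not dag._reaches(v, u):  # acyclic after addition
                yield (_ADD, u, v)
    for u, v in dag.arcs():
        if not constraints.requires(u, v):
            yield (_DELETE, u, v)
    for u, v in dag.arcs():
        if constraints.requires(u, v) or not constraints.allows(v, u):
            continue
        dag.remove_arc(u, v)
        ok = not dag._reaches(u, v)
        dag.add_arc(u, v)
        if ok:
            yield (_REVERSE, u, v)


def _move_delta(cache: ScoreCache, dag: Dag, move) -> float:
    kind, u, v = move
    if kind == _ADD:
        pa = dag.parents(v)
        return cache.family(v, pa | {u}) - cache.family(v, pa)
    if kind == _DELETE:
        pa = dag.parents(v)
        return cache.family(v, pa - {u}) - cache.family(v, pa)
    pa_v = dag.parents(v)
    pa_u = dag.parents(u)
    return (
        cache.family(v, pa_v - {u})
        - cache.family(v, pa_v)
        + cache.family(u, pa_u | {v})
        - cache.family(u, pa_u)
    )


def _apply(dag: Dag, move) -> None:
    kind, u, v = move
    if kind == _ADD:
        dag.add_arc(u, v)
    elif kind == _DELETE:
        dag.remove_arc(u, v)
    else:
        dag.reverse_arc(u, v)


def _best_move(cache, dag, constraints, skeleton, forbidden=frozenset()):
    """Best-scoring legal move (ties -> first in enumeration order)."""
    best = None
    best_delta = None
    for move in _legal_moves(dag, constraints, skeleton):
        if move in forbidden:
            continue
        delta = _move_delta(cache, dag, move)
        if best_delta is None or delta > best_delta + _EPS:
            best, best_delta = move, delta
    return best, best_delta


def hill_climb(
    data: DiscreteDataset,
    config: AlgorithmConfig | None = None,
    constraints: ConstraintSet = EMPTY_CONSTRAINTS,
    skeleton=None,
    cache: ScoreCache | None = None,
) -> Dag:
    """Greedy hill climbing to a single-move local maximum.

    ``skeleton`` (a set of frozen node pairs) restricts add moves to the
    given undirected edges; used by the hybrid restrict-maximize learners.
    """
    config = config or AlgorithmConfig("hc")
    cache = cache or ScoreCache(data, config.score or "bic")
    dag = _initial_dag(data.names, constraints)
    while True:
        move, delta = _best_move(cache, dag, constraints, skeleton)
        if move is None or delta <= _EPS:
            return dag
        _apply(dag, move)


def _tabu_keys(move):
    """Keys forbidden after applying ``move`` (moves that would undo it)."""
    kind, u, v = move
    if kind == _ADD:
        return ((_DELETE, u, v), (_REVERSE, u, v))
    if kind == _DELETE:
        return ((_ADD, u, v), (_ADD, v, u))
    return ((_REVERSE, v, u), (_DELETE, v, u))


def tabu_search(
    data: DiscreteDataset,
    config: AlgorithmConfig | None = None,
    constraints: ConstraintSet = EMPTY_CONSTRAINTS,
    skeleton=None,
    cache: ScoreCache | None = None,
) -> Dag:
    """Tabu-augmented hill climbing returning the best structure seen.

    When no improving move exists the search takes the best non-tabu
    (possibly worsening) move; a bounded number of consecutive
    non-improving steps is allowed and recently undone arc-moves are kept
    on a fixed-length tabu list.
    """
    config = config or AlgorithmConfig("tabu")
    cache = cache or ScoreCache(data, config.score or "bic")
    dag = _initial_dag(data.names, constraints)
    score = cache.network(dag)
    best_dag, best_score = dag.copy(), score
    tabu: deque = deque(maxlen=max(1, config.tabu_length))
    non_improving = 0
    while True:
        move, delta = _best_move(cache, dag, constraints, skeleton)
        if move is not None and delta > _EPS:
            _apply(dag, move)
            score += delta
            for key in _tabu_keys(move):
                tabu.append(key)
            if score > best_score + _EPS:
                best_dag, best_score = dag.copy(), score
                non_improving = 0
            continue
        non_improving += 1
        if non_improving > config.max_non_improving:
            break
        move, delta = _best_move(
            cache, dag, constraints, skeleton, forbidden=frozenset(tabu)
        )
        if move is None:
            break
        _apply(dag, move)
        score += delta
        for key in _tabu_keys(move):
            tabu.append(key)
        if score > best_score + _EPS:
            best_dag, best_score = dag.copy(), score
            non_improving = 0
    return best_dag
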