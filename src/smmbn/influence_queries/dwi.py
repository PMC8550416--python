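"""Distance-weighted influence (DWI) node ranking.

The influence of a query node X on a target Y is a sum over unblocked simple
paths: ``w ** length`` in constant mode, or the product of bootstrap arc
strengths along the path in strength-weighted mode.  Arc strength is a
property of the stored arc and applies regardless of traversal direction.
"""

from __future__ import annotations

import dataclasses

from ..bn_core.graph import Dag
from ..ensemble_consensus.strength import ArcStrengthTable
from ..exceptions import ConfigurationError, ContractError
from .paths import unblocked_paths

__all__ = ["dwi", "dwi_weighted", "rank_influence", "DwiResult"]


def dwi(dag: Dag, x: str, y: str, w: float, directed_only: bool = False) -> float:
    """Constant-weight influence: sum over unblocked paths of ``w**length``.

    With ``w == 1`` this is the unblocked simple path count; an empty path
    set gives 0.
    """
    if not 0.0 <= w <= 1.0:
        raise ContractError("w must be in [0, 1]")
    return sum(
        w ** p.length for p in unblocked_paths(dag, x, y, directed_only)
    )


def _path_weight(dag: Dag, strengths: ArcStrengthTable, path) -> float:
    weight = 1.0
    for u, v in path.edges():
        if dag.has_arc(u, v):
            arc = (u, v)
        else:
            arc = (v, u)
        if arc not in strengths.strengths:
            raise ConfigurationError(f"no strength recorded for arc {arc}")
        weight *= strengths.strengths[arc]
    return weight


def dwi_weighted(
    dag: Dag,
    strengths: ArcStrengthTable,
    x: str,
    y: str,
    directed_only: bool = False,
) -> float:
    """Strength-weighted influence: sum over unblocked paths of the product
    of traversed arc strengths."""
    return sum(
        _path_weight(dag, strengths, p)
        for p in unblocked_paths(dag, x, y, directed_only)
    )


@dataclasses.dataclass(frozen=True)
class DwiResult:
    """Node -> influence score ranking toward one target."""

    target: str
    scores: dict[str, float]
    ranking: tuple[str, ...]
    mode: str  # "constant-w" | "strength-weighted"
    w: float | None = None

    def top(self, k: int) -> tuple[str, ...]:
        return self.ranking[:k]


def rank_influence(
    dag: Dag,
    target: str,
    strengths: ArcStrengthTable | None = None,
    w: float | None = None,
    exclusions=(),
    directed_only: bool = False,
) -> DwiResult:
    """Rank every other node's influence on ``target``.

    ``exclusions`` are arcs removed (semi-supervised pruning of implausible
    arcs) before scoring.  Exactly one of ``strengths`` (strength-weighted
    mode) or ``w`` (constant mode) must be given.  Ordering: score
    descending, then shortest unblocked path, then node name.
    """
    dag._require(target)
    if (strengths is None) == (w is None):
        raise ConfigurationError("provide exactly one of strengths / w")
    work = dag.copy()
    for u, v in exclusions:
        if work.has_arc(u, v):
            work.remove_arc(u, v)
    scores: dict[str, float] = {}
    min_len: dict[str, float] = {}
    for node in work.nodes:
        if node == target:
            continue
        paths = unblocked_paths(work, node, target, directed_only)
        min_len[node] = paths[0].length if paths else float("inf")
        if strengths is not None:
            scores[node] = sum(
                _path_weight(work, strengths, p) for p in paths
            )
        else:
            scores[node] = sum(w ** p.length for p in paths)
    ranking = tuple(
        sorted(scores, key=lambda n: (-scores[n], min_len[n], n))
    )
    return DwiResult(
        target=target,
        scores=scores,
        ranking=ranking,
        mode="strength-weighted" if strengths is not None else "constant-w",
        w=w,
    )
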