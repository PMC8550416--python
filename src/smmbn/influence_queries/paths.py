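"""Unblocked simple paths over a network skeleton.

A path is *unblocked* (given the empty conditioning set) when it contains no
collider: for every internal node the two incident path edges are not both
directed into it.  An optional directed-only mode restricts enumeration to
directed parent-to-child chains.
"""

from __future__ import annotations

import dataclasses

from ..bn_core.graph import Dag

__all__ = ["InfluencePath", "unblocked_paths"]


@dataclasses.dataclass(frozen=True)
class InfluencePath:
    """Ordered node sequence from a query node to a target."""

    nodes: tuple[str, ...]

    @property
    def length(self) -> int:
        """Number of arcs traversed."""
        return len(self.nodes) - 1

    def edges(self) -> tuple[tuple[str, str], ...]:
        return tuple(zip(self.nodes, self.nodes[1:]))


def unblocked_paths(
    dag: Dag, x: str, y: str, directed_only: bool = False
) -> list[InfluencePath]:
    """All collider-free simple skeleton paths from ``x`` to ``y``.

    Deterministic order: shortest first, then lexicographic on the node
    sequence.
    """
    dag._require(x)
    dag._require(y)
    if x == y:
        from ..exceptions import ContractError

        raise ContractError("x and y must differ")
    found: list[tuple[str, ...]] = []

    def extend(path: list[str]) -> None:
        last = path[-1]
        if directed_only:
            nxt = sorted(dag.children(last))
        else:
            nxt = sorted(dag.neighbours(last))
        for cand in nxt:
            if cand in path:
                continue
            # the previous node becomes internal; reject if it is a collider
            if len(path) >= 2:
                prev2, prev1 = path[-2], path[-1]
                if dag.has_arc(prev2, prev1) and dag.has_arc(cand, prev1):
                    continue
            if cand == y:
                found.append(tuple(path) + (y,))
            else:
                path.append(cand)
                extend(path)
                path.pop()

    extend([x])
    found.sort(key=lambda p: (len(p), p))
    return [InfluencePath(p) for p in found]
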