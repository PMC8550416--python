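"""Arc constraints: blacklists, whitelists and the layering rule.

Layering forbids any arc from a variable in a higher (more downstream) layer
into a lower one, so e.g. the outcome can never become a parent of a
demographic variable.  Arcs within a layer or pointing downstream are free.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Iterable, Sequence

from ..bn_core.dataset import VariableSpec
from ..bn_core.graph import Dag
from ..exceptions import ConfigurationError, CycleError

__all__ = ["ConstraintSet", "EMPTY_CONSTRAINTS"]

Arc = tuple[str, str]


@dataclasses.dataclass(frozen=True)
class ConstraintSet:
    """Forbidden and required ordered arcs for structure learning."""

    blacklist: frozenset[Arc] = frozenset()
    whitelist: frozenset[Arc] = frozenset()
    from_layers: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "blacklist", frozenset(map(tuple, self.blacklist)))
        object.__setattr__(self, "whitelist", frozenset(map(tuple, self.whitelist)))
        if self.blacklist & self.whitelist:
            raise ConfigurationError("whitelist and blacklist must be disjoint")
        nodes = {n for arc in self.whitelist for n in arc}
        probe = Dag(sorted(nodes))
        try:
            for u, v in sorted(self.whitelist):
                probe.add_arc(u, v)
        except CycleError as exc:
            raise ConfigurationError(
                "whitelisted arcs are mutually cyclic"
            ) from exc

    @classmethod
    def from_variable_layers(
        cls,
        variables: Sequence[VariableSpec],
        blacklist: Iterable[Arc] = (),
        whitelist: Iterable[Arc] = (),
    ) -> "ConstraintSet":
        """Blacklist every arc that points from a higher layer to a lower one."""
        layer = {v.name: v.layer for v in variables}
        layered = {
            (u, v)
            for u in layer
            for v in layer
            if u != v and layer[u] > layer[v]
        }
        return cls(
            blacklist=frozenset(layered) | frozenset(map(tuple, blacklist)),
            whitelist=frozenset(map(tuple, whitelist)),
            from_layers=True,
        )

    def allows(self, u: str, v: str) -> bool:
        return (u, v) not in self.blacklist

    def allows_edge(self, u: str, v: str) -> bool:
        """True when at least one direction of the pair is permitted."""
        return self.allows(u, v) or self.allows(v, u)

    def requires(self, u: str, v: str) -> bool:
        return (u, v) in self.whitelist

    def forced_direction(self, u: str, v: str) -> Arc | None:
        """If exactly one direction of the pair is blacklisted, the other."""
        a, b = self.allows(u, v), self.allows(v, u)
        if a and not b:
            return (u, v)
        if b and not a:
            return (v, u)
        return None


EMPTY_CONSTRAINTS = ConstraintSet()
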