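"""Directed and partially directed graph types plus graphical criteria.

The :class:`Dag` carries the parent sets of the network factorization; the
:class:`Pdag` represents equivalence-class output of constraint-based learning
(skeleton + compelled arcs).  d-separation, Markov blankets, the CPDAG map and
a deterministic consistent-extension procedure live here.
"""

from __future__ import annotations

import itertools
from collections import deque
from collections.abc import Iterable

from ..exceptions import CycleError, GraphError, IdentifierError

__all__ = [
    "Dag",
    "Pdag",
    "d_separated",
    "markov_blanket",
    "to_cpdag",
    "consistent_extension",
]

Arc = tuple[str, str]


class Dag:
    """Directed acyclic graph over named nodes.

    Acyclicity and endpoint membership are enforced on construction and on
    every arc mutation.
    """

    def __init__(self, nodes: Iterable[str] = (), arcs: Iterable[Arc] = ()) -> None:
        self._nodes: list[str] = []
        self._parents: dict[str, set[str]] = {}
        self._children: dict[str, set[str]] = {}
        for n in nodes:
            self.add_node(n)
        for u, v in arcs:
            self.add_arc(u, v)

    # -- construction ------------------------------------------------------

    def add_node(self, name: str) -> None:
        if name in self._parents:
            return
        self._nodes.append(name)
        self._parents[name] = set()
        self._children[name] = set()

    def add_arc(self, u: str, v: str) -> None:
        self._require(u)
        self._require(v)
        if u == v:
            raise GraphError(f"self-arc {u!r} -> {v!r}")
        if v in self._parents[u] or self._reaches(v, u):
            # u is already a descendant of v: adding u -> v closes a cycle
            raise CycleError(f"arc {u!r} -> {v!r} would create a directed cycle")
        self._parents[v].add(u)
        self._children[u].add(v)

    def remove_arc(self, u: str, v: str) -> None:
        if not self.has_arc(u, v):
            raise GraphError(f"no arc {u!r} -> {v!r}")
        self._parents[v].discard(u)
        self._children[u].discard(v)

    def reverse_arc(self, u: str, v: str) -> None:
        self.remove_arc(u, v)
        try:
            self.add_arc(v, u)
        except CycleError:
            self.add_arc(u, v)
            raise

    def copy(self) -> "Dag":
        return Dag(self._nodes, self.arcs())

    # -- accessors ---------------------------------------------------------

    @property
    def nodes(self) -> tuple[str, ...]:
        return tuple(self._nodes)

    def __contains__(self, name: str) -> bool:
        return name in self._parents

    def _require(self, name: str) -> None:
        if name not in self._parents:
            raise IdentifierError(f"unknown node {name!r}")

    def has_arc(self, u: str, v: str) -> bool:
        return v in self._parents and u in self._parents[v]

    def arcs(self) -> tuple[Arc, ...]:
        return tuple(
            sorted((u, v) for v in self._nodes for u in self._parents[v])
        )

    def n_arcs(self) -> int:
        return sum(len(p) for p in self._parents.values())

    def parents(self, v: str) -> frozenset[str]:
        self._require(v)
        return frozenset(self._parents[v])

    def children(self, v: str) -> frozenset[str]:
        self._require(v)
        return frozenset(self._children[v])

    def adjacent(self, u: str, v: str) -> bool:
        return self.has_arc(u, v) or self.has_arc(v, u)

    def neighbours(self, v: str) -> frozenset[str]:
        return self.parents(v) | self.children(v)

    def skeleton(self) -> frozenset[frozenset[str]]:
        return frozenset(frozenset(a) for a in self.arcs())

    # -- reachability ------------------------------------------------------

    def _reaches(self, src: str, dst: str) -> bool:
        """True iff a directed path src ~> dst exists."""
        if src == dst:
            return True
        seen = {src}
        stack = [src]
        while stack:
            for c in self._children[stack.pop()]:
                if c == dst:
                    return True
                if c not in seen:
                    seen.add(c)
                    stack.append(c)
        return False

    def descendants(self, v: str) -> frozenset[str]:
        self._require(v)
        seen: set[str] = set()
        stack = [v]
        while stack:
            for c in self._children[stack.pop()]:
                if c not in seen:
                    seen.add(c)
                    stack.append(c)
        return frozenset(seen)

    def ancestors(self, v: str) -> frozenset[str]:
        self._require(v)
        seen: set[str] = set()
        stack = [v]
        while stack:
            for p in self._parents[stack.pop()]:
                if p not in seen:
                    seen.add(p)
                    stack.append(p)
        return frozenset(seen)

    def topological_order(self) -> tuple[str, ...]:
        """Kahn ordering with lexicographic tie-breaking (seed-portable)."""
        indeg = {n: len(self._parents[n]) for n in self._nodes}
        ready = sorted(n for n, d in indeg.items() if d == 0)
        order: list[str] = []
        while ready:
            n = ready.pop(0)
            order.append(n)
            changed = False
            for c in self._children[n]:
                indeg[c] -= 1
                if indeg[c] == 0:
                    ready.append(c)
                    changed = True
            if changed:
                ready.sort()
        if len(order) != len(self._nodes):
            raise CycleError("graph contains a directed cycle")
        return tuple(order)

    def __eq__(self, other) -> bool:
        if not isinstance(other, Dag):
            return NotImplemented
        return set(self._nodes) == set(other._nodes) and self.arcs() == other.arcs()

    def __repr__(self) -> str:
        return f"Dag(nodes={len(self._nodes)}, arcs={self.n_arcs()})"


class Pdag:
    """Partially directed graph: directed arcs plus undirected edges."""

    def __init__(
        self,
        nodes: Iterable[str] = (),
        directed: Iterable[Arc] = (),
        undirected: Iterable[tuple[str, str]] = (),
    ) -> None:
        self._nodes: list[str] = []
        seen: set[str] = set()
        for n in nodes:
            if n not in seen:
                seen.add(n)
                self._nodes.append(n)
        self.directed_arcs: set[Arc] = set()
        self.undirected_edges: set[frozenset[str]] = set()
        for u, v in directed:
            self.orient(u, v)
        for u, v in undirected:
            self.add_undirected(u, v)

    def _require(self, name: str) -> None:
        if name not in self._nodes:
            raise IdentifierError(f"unknown node {name!r}")

    @property
    def nodes(self) -> tuple[str, ...]:
        return tuple(self._nodes)

    def orient(self, u: str, v: str) -> None:
        self._require(u)
        self._require(v)
        if u == v:
            raise GraphError("self-edge")
        self.undirected_edges.discard(frozenset((u, v)))
        self.directed_arcs.discard((v, u))
        self.directed_arcs.add((u, v))

    def add_undirected(self, u: str, v: str) -> None:
        self._require(u)
        self._require(v)
        if u == v:
            raise GraphError("self-edge")
        if (u, v) in self.directed_arcs or (v, u) in self.directed_arcs:
            raise GraphError(f"edge {u!r}-{v!r} already directed")
        self.undirected_edges.add(frozenset((u, v)))

    def has_directed(self, u: str, v: str) -> bool:
        return (u, v) in self.directed_arcs

    def has_undirected(self, u: str, v: str) -> bool:
        return frozenset((u, v)) in self.undirected_edges

    def adjacent(self, u: str, v: str) -> bool:
        return (
            (u, v) in self.directed_arcs
            or (v, u) in self.directed_arcs
            or frozenset((u, v)) in self.undirected_edges
        )

    def neighbours(self, v: str) -> frozenset[str]:
        self._require(v)
        out = {b for a, b in self.directed_arcs if a == v}
        out |= {a for a, b in self.directed_arcs if b == v}
        out |= {next(iter(e - {v})) for e in self.undirected_edges if v in e}
        return frozenset(out)

    def skeleton(self) -> frozenset[frozenset[str]]:
        return frozenset(
            {frozenset(a) for a in self.directed_arcs} | self.undirected_edges
        )

    def copy(self) -> "Pdag":
        return Pdag(
            self._nodes,
            sorted(self.directed_arcs),
            sorted(tuple(sorted(e)) for e in self.undirected_edges),
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, Pdag):
            return NotImplemented
        return (
            set(self._nodes) == set(other._nodes)
            and self.directed_arcs == other.directed_arcs
            and self.undirected_edges == other.undirected_edges
        )

    def __repr__(self) -> str:
        return (
            f"Pdag(nodes={len(self._nodes)}, directed={len(self.directed_arcs)},"
            f" undirected={len(self.undirected_edges)})"
        )


# ---------------------------------------------------------------------------
# graphical criteria
# ---------------------------------------------------------------------------


def d_separated(dag: Dag, x: str, y: str, z: Iterable[str] = ()) -> bool:
    """Standard d-separation of ``x`` and ``y`` given set ``z``.

    Uses the active-trail reachability algorithm: a trail is blocked when a
    non-collider on it is in ``z`` or a collider has no member of ``z`` among
    its descendants-or-self.
    """
    zset = frozenset(z)
    for n in (x, y, *zset):
        dag._require(n)
    if x == y:
        raise GraphError("x and y must differ")
    if x in zset or y in zset:
        raise GraphError("x and y must not be in the conditioning set")

    # nodes having a member of z among descendants-or-self
    anc_of_z: set[str] = set(zset)
    for w in zset:
        anc_of_z |= dag.ancestors(w)

    # states: (node, direction); "up" = trail arrives from a child,
    # "down" = trail arrives from a parent (i.e. node may be a collider).
    visited: set[tuple[str, str]] = set()
    queue: deque[tuple[str, str]] = deque([(x, "up")])
    while queue:
        node, direction = queue.popleft()
        if (node, direction) in visited:
            continue
        visited.add((node, direction))
        if node == y:
            return False
        if direction == "up" and node not in zset:
            for p in dag.parents(node):
                queue.append((p, "up"))
            for c in dag.children(node):
                queue.append((c, "down"))
        elif direction == "down":
            if node not in zset:
                for c in dag.children(node):
                    queue.append((c, "down"))
            if node in anc_of_z:
                for p in dag.parents(node):
                    queue.append((p, "up"))
    return True


def markov_blanket(dag: Dag, x: str) -> frozenset[str]:
    """Parents, children and co-parents of ``x`` (excluding ``x``)."""
    dag._require(x)
    blanket = set(dag.parents(x)) | set(dag.children(x))
    for c in dag.children(x):
        blanket |= dag.parents(c)
    blanket.discard(x)
    return frozenset(blanket)


# ---------------------------------------------------------------------------
# CPDAG map (skeleton + v-structures + Meek closure)
# ---------------------------------------------------------------------------


def _meek_closure(pdag: Pdag) -> None:
    """Iterate orientation rules R1-R4 to a fixpoint, in place."""
    changed = True
    while changed:
        changed = False
        for edge in sorted(pdag.undirected_edges, key=sorted):
            a, b = sorted(edge)
            for u, v in ((a, b), (b, a)):
                if _meek_applies(pdag, u, v):
                    pdag.orient(u, v)
                    changed = True
                    break
            if changed:
                break


def _meek_applies(pdag: Pdag, a: str, b: str) -> bool:
    """Would any of R1-R4 orient the undirected edge a-b as a -> b?"""
    nodes = pdag.nodes
    # R1: c -> a, a - b, c and b non-adjacent  =>  a -> b
    for c in nodes:
        if pdag.has_directed(c, a) and c != b and not pdag.adjacent(c, b):
            return True
    # R2: a -> c -> b and a - b  =>  a -> b
    for c in nodes:
        if pdag.has_directed(a, c) and pdag.has_directed(c, b):
            return True
    # R3: a - c, a - d, c -> b, d -> b, c and d non-adjacent  =>  a -> b
    into_b = [
        c
        for c in nodes
        if pdag.has_directed(c, b) and pdag.has_undirected(a, c)
    ]
    for c, d in itertools.combinations(sorted(into_b), 2):
        if not pdag.adjacent(c, d):
            return True
    # R4: a - c, c -> d, d -> b, c and b non-adjacent  =>  a -> b
    for c in nodes:
        if not pdag.has_undirected(a, c) or c == b or pdag.adjacent(c, b):
            continue
        for d in nodes:
            if pdag.has_directed(c, d) and pdag.has_directed(d, b):
                return True
    return False


def to_cpdag(dag: Dag) -> Pdag:
    """Markov-equivalence-class representative of ``dag``.

    V-structure arcs are directed, the Meek closure adds every further
    compelled orientation and all remaining edges stay undirected.
    """
    pdag = Pdag(dag.nodes)
    compelled: set[Arc] = set()
    for v in dag.nodes:
        for a, b in itertools.combinations(sorted(dag.parents(v)), 2):
            if not dag.adjacent(a, b):
                compelled.add((a, v))
                compelled.add((b, v))
    for u, v in sorted(compelled):
        pdag.orient(u, v)
    for u, v in dag.arcs():
        if (u, v) not in compelled:
            pdag.add_undirected(u, v)
    _meek_closure(pdag)
    return pdag


# ---------------------------------------------------------------------------
# PDAG -> DAG extension
# ---------------------------------------------------------------------------


def consistent_extension(pdag: Pdag) -> Dag:
    """Deterministic Dor-Tarsi extension of a PDAG into a member DAG.

    Repeatedly removes a sink-like node whose undirected neighbours are
    adjacent to all of its other neighbours, orienting its undirected edges
    inward; smallest qualifying node name first.  Falls back to a greedy
    lexicographic acyclic orientation when the PDAG admits no consistent
    extension (possible for learned structures that are not true CPDAGs).
    """
    work = pdag.copy()
    dag = Dag(pdag.nodes, sorted(pdag.directed_arcs))
    remaining = set(pdag.nodes)
    while remaining:
        found = None
        for x in sorted(remaining):
            outgoing = any(
                a == x and b in remaining for a, b in work.directed_arcs
            )
            if outgoing:
                continue
            und = [
                next(iter(e - {x}))
                for e in work.undirected_edges
                if x in e and (e - {x}) <= remaining
            ]
            nbrs = {n for n in work.neighbours(x) if n in remaining}
            if all(
                all(work.adjacent(y, n) for n in nbrs if n != y) for y in und
            ):
                found = x
                break
        if found is None:
            break
        for e in [e for e in work.undirected_edges if found in e]:
            other = next(iter(e - {found}))
            if other in remaining:
                work.orient(other, found)
                dag.add_arc(other, found)
        for arc in [a for a in work.directed_arcs if found in a]:
            work.directed_arcs.discard(arc)
        remaining.discard(found)
    # fallback: orient leftovers greedily without creating cycles
    leftovers = sorted(
        tuple(sorted(e)) for e in work.undirected_edges if set(e) & remaining
    )
    for u, v in leftovers:
        if dag.adjacent(u, v):
            continue
        try:
            dag.add_arc(u, v)
        except CycleError:
            dag.add_arc(v, u)
    return dag
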