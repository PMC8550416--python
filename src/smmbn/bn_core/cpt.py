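"""Network parameters: CPT fitting, joint probabilities, exact inference
and ancestral sampling.

A :class:`CptSet` stores, for every node, one table of shape ``(q, r)`` where
``q`` is the number of parent configurations (row-major over the parent list)
and ``r`` the node cardinality.  Every row is a probability vector.
"""

from __future__ import annotations

import math
from collections.abc import Mapping, Sequence

import numpy as np

from ..exceptions import (
    ContractError,
    IdentifierError,
    UndefinedConditionalError,
)
from .dataset import DiscreteDataset, VariableSpec
from .graph import Dag

__all__ = [
    "CptSet",
    "fit_cpts",
    "joint_probability",
    "exact_query",
    "ancestral_sample",
]

_ATOL = 1e-9
_MAX_ENUM_BITS = 25.0  # guard: <= 25 binary-equivalent nodes for enumeration


def _config_index(codes: np.ndarray, cols: Sequence[int], cards: Sequence[int]):
    """Row-major parent-configuration index for every record."""
    if not cols:
        return np.zeros(codes.shape[0], dtype=np.int64)
    idx = np.zeros(codes.shape[0], dtype=np.int64)
    for c, card in zip(cols, cards):
        idx = idx * card + codes[:, c]
    return idx


class CptSet:
    """Conditional probability tables for every node of a network."""

    def __init__(
        self,
        variables: Sequence[VariableSpec],
        parents: Mapping[str, Sequence[str]],
        tables: Mapping[str, np.ndarray],
    ) -> None:
        self._variables = tuple(variables)
        self._specs = {v.name: v for v in self._variables}
        self._parents = {n: tuple(p) for n, p in parents.items()}
        self._tables: dict[str, np.ndarray] = {}
        for spec in self._variables:
            name = spec.name
            pa = self._parents.get(name, ())
            q = int(np.prod([self._specs[p].cardinality for p in pa], dtype=np.int64)) if pa else 1
            table = np.asarray(tables[name], dtype=float).reshape(q, spec.cardinality)
            if (table < -_ATOL).any():
                raise ContractError(f"negative probability in CPT of {name!r}")
            if not np.allclose(table.sum(axis=1), 1.0, atol=_ATOL):
                raise ContractError(f"CPT rows of {name!r} do not sum to 1")
            table = np.clip(table, 0.0, None)
            table.setflags(write=False)
            self._parents[name] = pa
            self._tables[name] = table

    # -- accessors ---------------------------------------------------------

    @property
    def variables(self) -> tuple[VariableSpec, ...]:
        return self._variables

    @property
    def nodes(self) -> tuple[str, ...]:
        return tuple(v.name for v in self._variables)

    def spec(self, name: str) -> VariableSpec:
        try:
            return self._specs[name]
        except KeyError:
            raise IdentifierError(f"unknown node {name!r}") from None

    def parents(self, name: str) -> tuple[str, ...]:
        self.spec(name)
        return self._parents.get(name, ())

    def table(self, name: str) -> np.ndarray:
        self.spec(name)
        return self._tables[name]

    def cardinality(self, name: str) -> int:
        return self.spec(name).cardinality

    def resolve(self, name: str, value) -> int:
        """Map a level label (or code) to its integer code."""
        spec = self.spec(name)
        if isinstance(value, (int, np.integer)) and not isinstance(value, bool):
            code = int(value)
            if not 0 <= code < spec.cardinality:
                raise ContractError(f"code {code} out of range for {name!r}")
            return code
        return spec.code_of(value)

    def prob(self, name: str, value, parent_values: Mapping[str, object]) -> float:
        """P(name = value | parents) for a single configuration."""
        pa = self.parents(name)
        idx = 0
        for p in pa:
            if p not in parent_values:
                raise ContractError(f"missing parent {p!r} of {name!r}")
            idx = idx * self.cardinality(p) + self.resolve(p, parent_values[p])
        return float(self._tables[name][idx, self.resolve(name, value)])

    def log2_size(self) -> float:
        return float(sum(math.log2(v.cardinality) for v in self._variables))

    # -- whole-network views ----------------------------------------------

    def joint_array(self) -> np.ndarray:
        """Dense joint distribution with one axis per node (variable order).

        Guarded to networks of at most 25 binary-equivalent nodes.
        """
        if self.log2_size() > _MAX_ENUM_BITS:
            raise ContractError(
                "network too large for exhaustive enumeration "
                f"(> {_MAX_ENUM_BITS} binary-equivalent nodes)"
            )
        names = list(self.nodes)
        pos = {n: i for i, n in enumerate(names)}
        shape = [self.cardinality(n) for n in names]
        joint = np.ones(shape, dtype=float)
        for name in names:
            pa = self.parents(name)
            fam_axes = [pos[p] for p in pa] + [pos[name]]
            t = self._tables[name].reshape(
                [self.cardinality(p) for p in pa] + [self.cardinality(name)]
            )
            t = np.transpose(t, np.argsort(fam_axes))
            full = [1] * len(names)
            for ax in fam_axes:
                full[ax] = shape[ax]
            joint = joint * t.reshape(full)
        return joint


def fit_cpts(dag: Dag, data: DiscreteDataset, smoothing: float = 0.0) -> CptSet:
    """Frequency-count parameter fit (+ optional additive smoothing).

    Each entry is ``(N_ijk + s) / (N_ij + s * r_i)``.  With ``s == 0`` an
    unseen parent configuration receives the uniform distribution so that
    downstream prediction never emits zero-probability ties on unobserved
    strata.
    """
    if smoothing < 0:
        raise ContractError("smoothing must be non-negative")
    for n in dag.nodes:
        data.index_of(n)  # raises IdentifierError on mismatch
    specs = [data.spec(n) for n in dag.nodes]
    codes = data.codes
    parents: dict[str, tuple[str, ...]] = {}
    tables: dict[str, np.ndarray] = {}
    for name in dag.nodes:
        pa = tuple(sorted(dag.parents(name)))
        parents[name] = pa
        r = data.cardinality(name)
        cards = [data.cardinality(p) for p in pa]
        q = int(np.prod(cards, dtype=np.int64)) if pa else 1
        cfg = _config_index(codes, [data.index_of(p) for p in pa], cards)
        counts = np.bincount(
            cfg * r + data.column(name), minlength=q * r
        ).reshape(q, r).astype(float)
        counts += smoothing
        row_sums = counts.sum(axis=1, keepdims=True)
        table = np.where(row_sums > 0, counts / np.where(row_sums == 0, 1, row_sums), 1.0 / r)
        tables[name] = table
    return CptSet(specs, parents, tables)


def _full_assignment_codes(cpts: CptSet, assignment: Mapping[str, object]) -> dict[str, int]:
    missing = [n for n in cpts.nodes if n not in assignment]
    if missing:
        raise ContractError(f"assignment misses nodes {missing}")
    return {n: cpts.resolve(n, assignment[n]) for n in cpts.nodes}


def joint_probability(dag: Dag, cpts: CptSet, assignment: Mapping[str, object]) -> float:
    """Chain-rule product of conditional probabilities for a full assignment."""
    codes = _full_assignment_codes(cpts, assignment)
    prob = 1.0
    for name in cpts.nodes:
        prob *= cpts.prob(name, codes[name], codes)
    return prob


def exact_query(
    dag: Dag,
    cpts: CptSet,
    event: Mapping[str, object],
    evidence: Mapping[str, object] | None = None,
) -> float:
    """P(event | evidence) by exhaustive summation of the joint.

    Ground-truth oracle for the Monte-Carlo machinery; guarded to small
    networks.  Raises :class:`UndefinedConditionalError` on zero-probability
    evidence.
    """
    evidence = dict(evidence or {})
    if set(event) & set(evidence):
        raise ContractError("event and evidence variables must be disjoint")
    if not event:
        raise ContractError("event must be non-empty")
    joint = cpts.joint_array()
    pos = {n: i for i, n in enumerate(cpts.nodes)}
    ev_idx: list[object] = [slice(None)] * len(cpts.nodes)
    for n, val in evidence.items():
        ev_idx[pos[n]] = cpts.resolve(n, val)
    p_evidence = float(joint[tuple(ev_idx)].sum())
    if p_evidence <= 0.0:
        raise UndefinedConditionalError("evidence has probability zero")
    both_idx = list(ev_idx)
    for n, val in event.items():
        both_idx[pos[n]] = cpts.resolve(n, val)
    p_both = float(joint[tuple(both_idx)].sum())
    return p_both / p_evidence


def ancestral_sample(
    dag: Dag, cpts: CptSet, n: int, seed: int | np.random.Generator
) -> DiscreteDataset:
    """Draw ``n`` records root-to-leaf in deterministic topological order."""
    if n < 1:
        raise ContractError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    names = list(cpts.nodes)
    pos = {name: j for j, name in enumerate(names)}
    codes = np.zeros((n, len(names)), dtype=np.int64)
    for name in dag.topological_order():
        if name not in pos:
            raise IdentifierError(f"node {name!r} missing from CPT set")
        pa = cpts.parents(name)
        cards = [cpts.cardinality(p) for p in pa]
        cfg = _config_index(codes, [pos[p] for p in pa], cards)
        rows = cpts.table(name)[cfg]  # (n, r)
        cum = np.cumsum(rows, axis=1)
        u = rng.random(n)
        codes[:, pos[name]] = (u[:, None] < cum).argmax(axis=1)
    return DiscreteDataset(cpts.variables, codes)
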