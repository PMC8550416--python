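"""Replicate runs, the 1 / 0.5 / 0 consensus score and algorithm selection.

Per algorithm, ``B`` structures are learned on bootstrap resamples of the
training data.  An unordered pair scores 1 for an algorithm when a single
direction occurs in more than ``threshold`` of its replicates, 0.5 when the
pair is linked (directed either way or undirected) more than ``threshold``
of the time without a dominant direction, and 0 otherwise.  The per-arc row
sum is the arc occurrence; the per-algorithm column sum is its total arcs.
"""

from __future__ import annotations

from collections import Counter
from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd

from ..bn_core.dataset import DiscreteDataset
from ..bn_core.graph import Dag, Pdag, _meek_closure, to_cpdag
from ..exceptions import ContractError
from ..structure_learning import (
    EMPTY_CONSTRAINTS,
    AlgorithmConfig,
    ConstraintSet,
    learn_structure,
)

__all__ = [
    "run_replicates",
    "score_algorithm_arcs",
    "build_consensus",
    "select_algorithms",
    "consensus_skeleton",
    "ConsensusTable",
]

Arc = tuple[str, str]


def constrained_cpdag(dag: Dag, constraints: ConstraintSet) -> Pdag:
    """Equivalence class of ``dag`` under background knowledge.

    Undirected CPDAG edges whose opposite direction is blacklisted (e.g. by
    layering) are re-oriented and the Meek closure is re-run, so constraint
    information is not lost when replicate structures are compared.
    """
    pdag = to_cpdag(dag)
    for edge in sorted(pdag.undirected_edges, key=sorted):
        u, v = sorted(edge)
        forced = constraints.forced_direction(u, v)
        if forced is not None:
            pdag.orient(*forced)
    _meek_closure(pdag)
    return pdag


def run_replicates(
    data: DiscreteDataset,
    config: AlgorithmConfig,
    B: int,
    seed: int,
    constraints: ConstraintSet = EMPTY_CONSTRAINTS,
    m: int | None = None,
    replace: bool = True,
) -> list[Pdag]:
    """Learn ``B`` structures on independent bootstrap resamples.

    Score-based outputs are mapped to their equivalence class
    (:func:`to_cpdag`) so replicate frequencies compare what the data can
    actually identify.  Reproducible for a fixed ``(seed, B)``.
    """
    if B < 1:
        raise ContractError("B must be >= 1")
    rng = np.random.default_rng(seed)
    m = m or data.n_records
    out: list[Pdag] = []
    for _ in range(B):
        if replace:
            rows = rng.integers(0, data.n_records, size=m)
        else:
            rows = rng.choice(
                data.n_records, size=min(m, data.n_records), replace=False
            )
        structure = learn_structure(data.take(rows), config, constraints)
        if isinstance(structure, Dag):
            structure = constrained_cpdag(structure, constraints)
        out.append(structure)
    return out


def score_algorithm_arcs(
    structures: Sequence[Pdag], threshold: float = 0.7
) -> dict[Arc, float]:
    """Fold replicate structures into per-pair scores in {0, 0.5, 1}.

    Returns a map keyed by the majority direction (score 1) or the
    lexicographically ordered pair (score 0.5).  Strict comparison: a
    frequency of exactly ``threshold`` does not qualify.
    """
    if not structures:
        raise ContractError("structures must be non-empty")
    if not 0 < threshold < 1:
        raise ContractError("threshold must be in (0, 1)")
    B = len(structures)
    directed: Counter[Arc] = Counter()
    undirected: Counter[frozenset[str]] = Counter()
    for s in structures:
        if isinstance(s, Dag):  # tolerated: plain DAGs count as directed
            for arc in s.arcs():
                directed[arc] += 1
        else:
            for arc in s.directed_arcs:
                directed[arc] += 1
            for e in s.undirected_edges:
                undirected[e] += 1
    pairs = {frozenset(a) for a in directed} | set(undirected)
    scores: dict[Arc, float] = {}
    for pair in sorted(pairs, key=sorted):
        a, b = sorted(pair)
        f_ab = directed.get((a, b), 0) / B
        f_ba = directed.get((b, a), 0) / B
        f_edge = f_ab + f_ba + undirected.get(pair, 0) / B
        if max(f_ab, f_ba) > threshold:
            winner = (a, b) if f_ab >= f_ba else (b, a)
            scores[winner] = 1.0
        elif f_edge > threshold:
            scores[(a, b)] = 0.5
    return scores


class ConsensusTable:
    """Arcs x algorithms score matrix with occurrence and total-arcs sums."""

    def __init__(self, arcs: Sequence[Arc], algorithms: Sequence[str], matrix) -> None:
        self._arcs = [tuple(a) for a in arcs]
        self._algorithms = list(algorithms)
        mat = np.asarray(matrix, dtype=float).reshape(
            len(self._arcs), len(self._algorithms)
        )
        if not np.isin(mat, (0.0, 0.5, 1.0)).all():
            raise ContractError("consensus entries must be in {0, 0.5, 1}")
        mat.setflags(write=False)
        self.matrix = mat

    @property
    def algorithms(self) -> list[str]:
        return list(self._algorithms)

    @property
    def arcs(self) -> list[Arc]:
        return list(self._arcs)

    @property
    def occurrence(self) -> dict[Arc, float]:
        """Row sums: per-arc occurrence across the roster."""
        sums = self.matrix.sum(axis=1)
        return {arc: float(s) for arc, s in zip(self._arcs, sums)}

    @property
    def total_arcs(self) -> dict[str, float]:
        """Column sums: per-algorithm total arcs."""
        sums = self.matrix.sum(axis=0)
        return {alg: float(s) for alg, s in zip(self._algorithms, sums)}

    def entry(self, arc: Arc, algorithm: str) -> float:
        return float(
            self.matrix[
                self._arcs.index(tuple(arc)), self._algorithms.index(algorithm)
            ]
        )

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            self.matrix,
            index=[f"{u} -> {v}" for u, v in self._arcs],
            columns=self._algorithms,
        )
        frame.index.name = "arc"
        frame["occurrence"] = self.matrix.sum(axis=1)
        total = frame.sum(axis=0)
        total.name = "total_arcs"
        return pd.concat([frame, total.to_frame().T])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)

    def __repr__(self) -> str:
        return (
            f"ConsensusTable(arcs={len(self._arcs)},"
            f" algorithms={len(self._algorithms)})"
        )


def build_consensus(
    scores_by_algorithm: Mapping[str, Mapping[Arc, float]],
    algorithms: Sequence[str] | None = None,
) -> ConsensusTable:
    """Assemble per-algorithm arc scores into a consensus table.

    Rows referring to the same unordered pair are merged; the row label is
    the direction with the most score-1 votes (ties lexicographic).  Rows
    are sorted by occurrence descending, then lexicographically.
    """
    algorithms = list(algorithms or scores_by_algorithm.keys())
    if not algorithms:
        raise ContractError("at least one algorithm required")
    direction_votes: Counter[Arc] = Counter()
    pair_scores: dict[frozenset[str], dict[str, float]] = {}
    for alg in algorithms:
        for arc, score in scores_by_algorithm.get(alg, {}).items():
            pair = frozenset(arc)
            pair_scores.setdefault(pair, {})[alg] = score
            if score == 1.0:
                direction_votes[tuple(arc)] += 1
    labels: list[Arc] = []
    rows: list[list[float]] = []
    for pair in sorted(pair_scores, key=sorted):
        a, b = sorted(pair)
        label = (a, b)
        if direction_votes.get((b, a), 0) > direction_votes.get((a, b), 0):
            label = (b, a)
        labels.append(label)
        rows.append([pair_scores[pair].get(alg, 0.0) for alg in algorithms])
    order = sorted(
        range(len(labels)), key=lambda i: (-sum(rows[i]), labels[i])
    )
    return ConsensusTable(
        [labels[i] for i in order], algorithms, [rows[i] for i in order]
    )


def select_algorithms(table: ConsensusTable, k: int) -> list[str]:
    """Top-``k`` algorithms by total arcs; ties broken by roster order."""
    if k > len(table.algorithms):
        raise ContractError("k exceeds the number of algorithms")
    totals = table.total_arcs
    roster = table.algorithms
    order = sorted(roster, key=lambda alg: (-totals[alg], roster.index(alg)))
    return order[:k]


def consensus_skeleton(
    table: ConsensusTable, min_fraction: float = 0.25
) -> set[frozenset[str]]:
    """Unordered pairs whose occurrence reaches ``min_fraction`` of the
    roster size (an arc scoring 1 with every algorithm has fraction 1).

    The default fraction is deliberately below one half: undirected edges
    contribute at most 0.5 per algorithm and constraint-based learners are
    conservative on small balanced samples, so demanding majority support
    of the raw occurrence would discard genuinely consensual edges.
    """
    n_alg = len(table.algorithms)
    return {
        frozenset(arc)
        for arc, occ in table.occurrence.items()
        if occ >= min_fraction * n_alg
    }
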