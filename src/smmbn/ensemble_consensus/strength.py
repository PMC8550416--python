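"""Bootstrap arc-strength model averaging.

Arc strength is the fraction of replicate learned structures containing a
directed arc; undirected PDAG edges contribute 0.5 to each direction.  The
averaged network keeps pairs whose combined strength clears a threshold and
orients each toward its stronger direction.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from ..bn_core.dataset import DiscreteDataset
from ..bn_core.graph import Dag, Pdag
from ..exceptions import ContractError, CycleError
from ..structure_learning import (
    EMPTY_CONSTRAINTS,
    AlgorithmConfig,
    ConstraintSet,
    learn_structure,
)

__all__ = ["ArcStrengthTable", "bootstrap_arc_strength", "averaged_network"]

Arc = tuple[str, str]


@dataclasses.dataclass(frozen=True)
class ArcStrengthTable:
    """Directed arc -> bootstrap occurrence frequency, plus replicate info."""

    strengths: dict[Arc, float]
    replicates: int
    sample_size: int
    nodes: tuple[str, ...] = ()
    #: disable to wrap external strength maps that are not R-fractions
    check_fractions: bool = True

    def __post_init__(self) -> None:
        for arc, freq in self.strengths.items():
            if not 0.0 <= freq <= 1.0:
                raise ContractError(f"strength of {arc} outside [0, 1]")
            if not self.check_fractions:
                continue
            # occurrences are integral or half-integral counts
            count2 = freq * self.replicates * 2
            if abs(count2 - round(count2)) > 1e-9 * max(1, self.replicates):
                raise ContractError(f"strength of {arc} not a replicate fraction")

    def strength(self, u: str, v: str) -> float:
        return self.strengths.get((u, v), 0.0)

    def pair_strength(self, u: str, v: str) -> float:
        return self.strength(u, v) + self.strength(v, u)

    def items(self):
        return sorted(self.strengths.items())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"from": u, "to": v, "strength": s}
            for (u, v), s in self.items()
        ]
        return pd.DataFrame(rows, columns=["from", "to", "strength"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def bootstrap_arc_strength(
    data: DiscreteDataset,
    config: AlgorithmConfig,
    R: int,
    m: int,
    seed: int,
    constraints: ConstraintSet = EMPTY_CONSTRAINTS,
    replace: bool = True,
) -> ArcStrengthTable:
    """Learn on ``R`` resamples of size ``m`` and tally arc frequencies.

    ``replace=True`` is m-out-of-n bootstrap resampling; ``replace=False``
    switches to without-replacement subsampling.
    """
    if R < 1 or m < 1:
        raise ContractError("R and m must be >= 1")
    rng = np.random.default_rng(seed)
    counts: dict[Arc, float] = {}
    for _ in range(R):
        if replace:
            rows = rng.integers(0, data.n_records, size=m)
        else:
            rows = rng.choice(
                data.n_records, size=min(m, data.n_records), replace=False
            )
        structure = learn_structure(data.take(rows), config, constraints)
        if isinstance(structure, Dag):
            for arc in structure.arcs():
                counts[arc] = counts.get(arc, 0.0) + 1.0
        else:
            for arc in structure.directed_arcs:
                counts[arc] = counts.get(arc, 0.0) + 1.0
            for e in structure.undirected_edges:
                a, b = sorted(e)
                counts[(a, b)] = counts.get((a, b), 0.0) + 0.5
                counts[(b, a)] = counts.get((b, a), 0.0) + 0.5
    strengths = {arc: c / R for arc, c in counts.items()}
    return ArcStrengthTable(strengths, R, m, tuple(data.names))


def averaged_network(table: ArcStrengthTable, threshold: float = 0.5) -> Dag:
    """Model-averaged DAG: pairs with combined strength above ``threshold``,
    each oriented toward its stronger direction (ties lexicographic), added
    in decreasing strength order skipping any arc that would close a cycle."""
    if not table.nodes:
        raise ContractError("table carries no node universe")
    dag = Dag(table.nodes)
    pairs = {frozenset(arc) for arc in table.strengths}
    ranked = []
    for pair in pairs:
        a, b = sorted(pair)
        total = table.pair_strength(a, b)
        if total <= threshold:
            continue
        u, v = (a, b) if table.strength(a, b) >= table.strength(b, a) else (b, a)
        ranked.append((-total, u, v))
    for _, u, v in sorted(ranked):
        try:
            dag.add_arc(u, v)
        except CycleError:
            continue
    return dag
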