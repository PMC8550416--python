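"""Small hand-specified fixture networks used across the test suite.

Catalog:

* ``chain3``    A -> B -> C, binary.  P(C=1 | A=1) = 0.8*0.9 + 0.2*0.1 = 0.74.
* ``collider3`` A -> C <- B, binary; A and B marginally independent.
* ``diamond4``  X -> A -> Y and X -> B -> Y; two unblocked X-Y paths.
* ``mixed7``    seven binary nodes mixing chains, a fork and a collider;
  the unblocked simple paths from ``x`` to ``y`` are exactly
  x-u-y, x-v-y and x-w-y (the x-c1-y path is collider-blocked).
"""

from __future__ import annotations

import numpy as np

from ..bn_core.cpt import CptSet
from ..bn_core.dataset import VariableSpec
from ..bn_core.graph import Dag
from ..exceptions import IdentifierError

__all__ = ["fixture_network", "FIXTURES"]


def _binary(name: str, layer: int = 0) -> VariableSpec:
    return VariableSpec(name, ("0", "1"), layer)


def _chain3():
    specs = [_binary("A"), _binary("B"), _binary("C")]
    parents = {"A": (), "B": ("A",), "C": ("B",)}
    tables = {
        "A": np.array([[0.7, 0.3]]),
        "B": np.array([[0.8, 0.2], [0.2, 0.8]]),  # rows: A=0, A=1
        "C": np.array([[0.9, 0.1], [0.1, 0.9]]),
    }
    dag = Dag(["A", "B", "C"], [("A", "B"), ("B", "C")])
    return dag, CptSet(specs, parents, tables)


def _collider3():
    specs = [_binary("A"), _binary("B"), _binary("C")]
    parents = {"A": (), "B": (), "C": ("A", "B")}
    tables = {
        "A": np.array([[0.5, 0.5]]),
        "B": np.array([[0.6, 0.4]]),
        # rows: (A, B) = (0,0), (0,1), (1,0), (1,1)
        "C": np.array([[0.95, 0.05], [0.4, 0.6], [0.3, 0.7], [0.1, 0.9]]),
    }
    dag = Dag(["A", "B", "C"], [("A", "C"), ("B", "C")])
    return dag, CptSet(specs, parents, tables)


def _diamond4():
    specs = [_binary("X"), _binary("A"), _binary("B"), _binary("Y")]
    parents = {"X": (), "A": ("X",), "B": ("X",), "Y": ("A", "B")}
    tables = {
        "X": np.array([[0.45, 0.55]]),
        "A": np.array([[0.85, 0.15], [0.25, 0.75]]),
        "B": np.array([[0.7, 0.3], [0.35, 0.65]]),
        "Y": np.array([[0.9, 0.1], [0.5, 0.5], [0.45, 0.55], [0.15, 0.85]]),
    }
    dag = Dag(
        ["X", "A", "B", "Y"],
        [("X", "A"), ("X", "B"), ("A", "Y"), ("B", "Y")],
    )
    return dag, CptSet(specs, parents, tables)


def _mixed7():
    names = ["w", "x", "u", "v", "y", "c1", "c2"]
    specs = [_binary(n) for n in names]
    parents = {
        "w": (),
        "x": ("w",),
        "u": ("x",),
        "v": ("x",),
        "y": ("u", "v", "w"),
        "c1": ("x", "y"),
        "c2": ("y",),
    }
    tables = {
        "w": np.array([[0.55, 0.45]]),
        "x": np.array([[0.7, 0.3], [0.3, 0.7]]),
        "u": np.array([[0.8, 0.2], [0.25, 0.75]]),
        "v": np.array([[0.65, 0.35], [0.2, 0.8]]),
        # rows over (u, v, w) in row-major order
        "y": np.array(
            [
                [0.92, 0.08],
                [0.6, 0.4],
                [0.55, 0.45],
                [0.3, 0.7],
                [0.5, 0.5],
                [0.25, 0.75],
                [0.2, 0.8],
                [0.05, 0.95],
            ]
        ),
        "c1": np.array([[0.9, 0.1], [0.45, 0.55], [0.4, 0.6], [0.2, 0.8]]),
        "c2": np.array([[0.75, 0.25], [0.35, 0.65]]),
    }
    dag = Dag(
        names,
        [
            ("w", "x"),
            ("x", "u"),
            ("x", "v"),
            ("u", "y"),
            ("v", "y"),
            ("w", "y"),
            ("x", "c1"),
            ("y", "c1"),
            ("y", "c2"),
        ],
    )
    return dag, CptSet(specs, parents, tables)


FIXTURES = {
    "chain3": _chain3,
    "collider3": _collider3,
    "diamond4": _diamond4,
    "mixed7": _mixed7,
}


def fixture_network(fixture_id: str) -> tuple[Dag, CptSet]:
    """Return a catalog fixture ``(Dag, CptSet)`` by id."""
    try:
        builder = FIXTURES[fixture_id]
    except KeyError:
        raise IdentifierError(
            f"unknown fixture {fixture_id!r}; known: {sorted(FIXTURES)}"
        ) from None
    return builder()
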