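"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately re-derive quantities from first principles
(enumeration over full assignments, manual CPT row indexing) so they stay
independent of the package code paths they are used to check.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from smmbn.bn_core import CptSet, Dag
from smmbn.synthetic_cohort import fixture_network

# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def enumerate_assignments(cpts: CptSet):
    names = list(cpts.nodes)
    cards = [cpts.cardinality(n) for n in names]
    for combo in itertools.product(*(range(c) for c in cards)):
        yield dict(zip(names, combo))


def oracle_joint(cpts: CptSet, assignment: dict[str, int]) -> float:
    """Chain-rule product computed with manual row indexing."""
    prob = 1.0
    for name in cpts.nodes:
        idx = 0
        for p in cpts.parents(name):
            idx = idx * cpts.cardinality(p) + assignment[p]
        prob *= cpts.table(name)[idx, assignment[name]]
    return prob


def oracle_query(cpts: CptSet, event: dict, evidence: dict) -> float:
    """P(event | evidence) by full enumeration."""
    p_both = p_ev = 0.0
    for a in enumerate_assignments(cpts):
        if any(a[k] != v for k, v in evidence.items()):
            continue
        p = oracle_joint(cpts, a)
        p_ev += p
        if all(a[k] == v for k, v in event.items()):
            p_both += p
    return p_both / p_ev


def oracle_conditionally_independent(
    cpts: CptSet, x: str, y: str, z: tuple, tol: float = 1e-9
) -> bool:
    """Exhaustive check of X independent of Y given Z in the joint."""
    znames = list(z)
    zcards = [cpts.cardinality(n) for n in znames]
    for zvals in itertools.product(*(range(c) for c in zcards)):
        zmap = dict(zip(znames, zvals))
        p_z = sum(
            oracle_joint(cpts, a)
            for a in enumerate_assignments(cpts)
            if all(a[k] == v for k, v in zmap.items())
        )
        if p_z <= tol:
            continue
        for xv in range(cpts.cardinality(x)):
            for yv in range(cpts.cardinality(y)):
                p_xyz = p_xz = p_yz = 0.0
                for a in enumerate_assignments(cpts):
                    if any(a[k] != v for k, v in zmap.items()):
                        continue
                    p = oracle_joint(cpts, a)
                    if a[x] == xv:
                        p_xz += p
                    if a[y] == yv:
                        p_yz += p
                    if a[x] == xv and a[y] == yv:
                        p_xyz += p
                if abs(p_xyz / p_z - (p_xz / p_z) * (p_yz / p_z)) > tol:
                    return False
    return True


def random_dag(rng: np.random.Generator, n_nodes: int, p_arc: float = 0.4) -> Dag:
    """Random DAG via a random node ordering."""
    names = [f"n{i}" for i in range(n_nodes)]
    order = list(rng.permutation(names))
    dag = Dag(names)
    for i, j in itertools.combinations(range(n_nodes), 2):
        if rng.random() < p_arc:
            dag.add_arc(order[i], order[j])
    return dag


def random_cpts(rng: np.random.Generator, dag: Dag, cards=2) -> CptSet:
    """Random (generic, hence faithful-in-practice) CPTs for a DAG."""
    from smmbn.bn_core import VariableSpec

    specs = [
        VariableSpec(n, tuple(str(i) for i in range(cards))) for n in dag.nodes
    ]
    parents = {n: tuple(sorted(dag.parents(n))) for n in dag.nodes}
    tables = {}
    for n in dag.nodes:
        q = int(np.prod([cards for _ in parents[n]])) if parents[n] else 1
        raw = rng.uniform(0.1, 0.9, size=(q, cards))
        tables[n] = raw / raw.sum(axis=1, keepdims=True)
    return CptSet(specs, parents, tables)


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------


@pytest.fixture(scope="session")
def chain3():
    return fixture_network("chain3")


@pytest.fixture(scope="session")
def collider3():
    return fixture_network("collider3")


@pytest.fixture(scope="session")
def diamond4():
    return fixture_network("diamond4")


@pytest.fixture(scope="session")
def mixed7():
    return fixture_network("mixed7")
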