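"""Decomposable network scores (log-likelihood, AIC, BIC) for discrete data.

Convention: larger is better.  The BIC penalty is ``(ln N)/2`` per free
parameter and the AIC penalty is 1; a family with parents of joint
cardinality ``q`` over a child with ``r`` levels has ``(r - 1) * q`` free
parameters.  The total network score is the sum of family scores.
"""

from __future__ import annotations

import math

import numpy as np

from ..bn_core.cpt import _config_index
from ..bn_core.dataset import DiscreteDataset
from ..bn_core.graph import Dag
from ..exceptions import ContractError

__all__ = ["ScoreCache", "family_score", "network_score", "SCORES"]

SCORES = ("loglik", "aic", "bic")


class ScoreCache:
    """Caches family scores for one dataset; the workhorse of greedy search."""

    def __init__(self, data: DiscreteDataset, score: str = "bic") -> None:
        if score not in SCORES:
            raise ContractError(f"unknown score {score!r}")
        self.data = data
        self.score = score
        self._cache: dict[tuple[str, tuple[str, ...]], float] = {}

    def family(self, node: str, parents) -> float:
        key = (node, tuple(sorted(parents)))
        if node in key[1]:
            raise ContractError("parents must exclude the node itself")
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        value = _family_score(node, key[1], self.data, self.score)
        self._cache[key] = value
        return value

    def network(self, dag: Dag) -> float:
        return sum(self.family(n, dag.parents(n)) for n in dag.nodes)


def _family_score(node, parents, data: DiscreteDataset, score: str) -> float:
    r = data.cardinality(node)
    cards = [data.cardinality(p) for p in parents]
    q = int(np.prod(cards, dtype=np.int64)) if parents else 1
    cfg = _config_index(
        data.codes, [data.index_of(p) for p in parents], cards
    )
    counts = np.bincount(cfg * r + data.column(node), minlength=q * r)
    counts = counts.reshape(q, r).astype(float)
    row = counts.sum(axis=1, keepdims=True)
    nz = counts > 0
    ll = float(np.sum(counts[nz] * np.log(counts[nz] / np.broadcast_to(row, counts.shape)[nz])))
    n_params = (r - 1) * q
    if score == "bic":
        return ll - 0.5 * math.log(data.n_records) * n_params
    if score == "aic":
        return ll - float(n_params)
    return ll


def family_score(node: str, parents, data: DiscreteDataset, score: str = "bic") -> float:
    """Score of a single (node | parents) family; see module docstring."""
    if node in set(parents):
        raise ContractError("parents must exclude the node itself")
    return _family_score(node, tuple(parents), data, score)


def network_score(dag: Dag, data: DiscreteDataset, score: str = "bic") -> float:
    """Sum of family scores over all nodes (decomposability)."""
    return sum(family_score(n, sorted(dag.parents(n)), data, score) for n in dag.nodes)
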