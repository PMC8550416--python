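"""Hybrid restrict-maximize learning (MMHC and generic rsmax2)."""

from __future__ import annotations

from ..bn_core.dataset import DiscreteDataset
from ..bn_core.graph import Dag
from ..exceptions import ConfigurationError
from .config import AlgorithmConfig
from .constraints import EMPTY_CONSTRAINTS, ConstraintSet
from .score_search import hill_climb, tabu_search
from .skeletons import iamb_skeleton, mmpc_skeleton

__all__ = ["restrict_maximize"]


def restrict_maximize(
    data: DiscreteDataset,
    config: AlgorithmConfig | None = None,
    constraints: ConstraintSet = EMPTY_CONSTRAINTS,
    skeleton=None,
) -> Dag:
    """Score search restricted to a constraint-phase skeleton.

    ``restrict`` picks the skeleton producer (``mmpc`` for MMHC, ``iamb``
    for the generic restricted-maximization), ``maximize`` the score search.
    A pre-computed ``skeleton`` (set of frozen pairs) short-circuits the
    restrict phase.  Every returned arc's unordered pair lies in the
    skeleton (whitelisted arcs are added to it).
    """
    config = config or AlgorithmConfig("mmhc")
    if skeleton is None:
        if config.restrict == "mmpc":
            skeleton = mmpc_skeleton(data, config, constraints)
        elif config.restrict == "iamb":
            skeleton = iamb_skeleton(data, config, constraints)
        else:  # pragma: no cover - guarded by AlgorithmConfig
            raise ConfigurationError(f"unknown restrict {config.restrict!r}")
    skeleton = set(skeleton) | {frozenset(a) for a in constraints.whitelist}
    search = hill_climb if config.maximize == "hc" else tabu_search
    return search(data, config, constraints, skeleton=skeleton)
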