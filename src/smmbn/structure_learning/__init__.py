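"""Structure learning: scores, CI tests, greedy search, Markov-blanket
algorithms, skeleton phases and hybrid restrict-maximize, all under arc
constraints."""

from ..bn_core.dataset import DiscreteDataset
from ..bn_core.graph import Dag, Pdag
from .blanket import MB_VARIANTS, learn_markov_blanket
from .ci_tests import CiOracle, CiTestResult, ci_test_g2
from .config import ALGORITHMS, AlgorithmConfig, default_roster
from .constraint_based import constraint_learn
from .constraints import EMPTY_CONSTRAINTS, ConstraintSet
from .hybrid import restrict_maximize
from .score_search import hill_climb, tabu_search
from .scores import ScoreCache, family_score, network_score
from .skeletons import iamb_skeleton, mmpc_skeleton

__all__ = [
    "ALGORITHMS",
    "AlgorithmConfig",
    "CiOracle",
    "CiTestResult",
    "ConstraintSet",
    "EMPTY_CONSTRAINTS",
    "MB_VARIANTS",
    "ScoreCache",
    "ci_test_g2",
    "constraint_learn",
    "default_roster",
    "family_score",
    "hill_climb",
    "iamb_skeleton",
    "learn_markov_blanket",
    "learn_structure",
    "mmpc_skeleton",
    "network_score",
    "restrict_maximize",
    "tabu_search",
]


def learn_structure(
    data: DiscreteDataset,
    config: AlgorithmConfig,
    constraints: ConstraintSet = EMPTY_CONSTRAINTS,
) -> Dag | Pdag:
    """Dispatch to the learner selected by ``config.algorithm``."""
    if config.algorithm == "hc":
        return hill_climb(data, config, constraints)
    if config.algorithm == "tabu":
        return tabu_search(data, config, constraints)
    if config.algorithm in MB_VARIANTS:
        return constraint_learn(data, config, constraints)
    return restrict_maximize(data, config, constraints)
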