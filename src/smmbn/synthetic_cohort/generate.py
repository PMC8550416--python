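"""Cohort generation by ancestral sampling from the ground truth."""

from __future__ import annotations

from ..bn_core.cpt import ancestral_sample
from ..bn_core.dataset import DiscreteDataset
from .config import CohortConfig
from .ground_truth import default_ground_truth

__all__ = ["generate_cohort"]


def generate_cohort(config: CohortConfig | None = None) -> DiscreteDataset:
    """Draw ``config.n`` complete records; byte-reproducible by seed."""
    config = config or CohortConfig()
    dag, cpts = default_ground_truth(config)
    return ancestral_sample(dag, cpts, config.n, config.seed)
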