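"""Predictive evaluation of a learned structure on held-out data.

Prediction for the target uses exactly the Markov-blanket factors of the
fitted network: the target's own CPT row and the CPTs of its children, with
the target clamped to each candidate level.  Deterministic (no sampling);
argmax ties break toward the first level.
"""

from __future__ import annotations

import numpy as np

from ..bn_core.cpt import CptSet, fit_cpts
from ..bn_core.dataset import DiscreteDataset
from ..bn_core.graph import Dag

__all__ = ["predict_target", "misclassification_rate"]


def predict_target(
    dag: Dag, cpts: CptSet, data: DiscreteDataset, target: str
) -> np.ndarray:
    """Argmax-posterior level codes for ``target`` on every record."""
    names = list(cpts.nodes)
    pos = {n: j for j, n in enumerate(names)}
    codes = np.zeros((data.n_records, len(names)), dtype=np.int64)
    for j, n in enumerate(names):
        codes[:, j] = data.column(n)
    r = cpts.cardinality(target)
    children = sorted(dag.children(target))
    log_post = np.zeros((data.n_records, r))
    tiny = 1e-300
    for t in range(r):
        codes[:, pos[target]] = t
        total = np.zeros(data.n_records)
        for fam in [target, *children]:
            pa = cpts.parents(fam)
            idx = np.zeros(data.n_records, dtype=np.int64)
            for p in pa:
                idx = idx * cpts.cardinality(p) + codes[:, pos[p]]
            level = t if fam == target else codes[:, pos[fam]]
            total += np.log(cpts.table(fam)[idx, level] + tiny)
        log_post[:, t] = total
    return log_post.argmax(axis=1)


def misclassification_rate(
    dag: Dag,
    train: DiscreteDataset,
    test: DiscreteDataset,
    target: str,
    smoothing: float = 1.0,
) -> float:
    """Fraction of test records whose predicted target level is wrong.

    CPTs are fitted on ``train`` (which must be independent of ``test``);
    prediction is the exact Markov-blanket argmax described above.
    """
    train.index_of(target)
    test.index_of(target)
    cpts = fit_cpts(dag, train, smoothing)
    predicted = predict_target(dag, cpts, test, target)
    return float(np.mean(predicted != test.column(target)))
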