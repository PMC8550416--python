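"""Data preparation: quartile discretization, splitting and under-sampling."""

from __future__ import annotations

import numpy as np

from ..bn_core.dataset import DiscreteDataset
from ..exceptions import ContractError, DegenerateClassError

__all__ = ["quartile_discretize", "train_test_split", "undersample"]

QUARTILE_LABELS = ("Q1", "Q2", "Q3", "Q4")


def quartile_discretize(values, labels=QUARTILE_LABELS) -> list[str]:
    """Quartile-code a numeric sequence.

    Cut points are the 25/50/75 empirical percentiles (linear
    interpolation); intervals are left-open/right-closed except the lowest,
    so a value exactly on a cut point takes the lower label.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ContractError("empty input")
    if np.unique(arr).size < 2:
        raise ContractError("constant input cannot be quartile-coded")
    if np.unique(arr).size < 4:
        raise ContractError("need >= 4 distinct values for quartiles")
    q1, q2, q3 = np.percentile(arr, [25, 50, 75], method="linear")
    out = np.full(arr.shape, labels[3], dtype=object)
    out[arr <= q3] = labels[2]
    out[arr <= q2] = labels[1]
    out[arr <= q1] = labels[0]
    return list(out)


def train_test_split(
    data: DiscreteDataset,
    fraction: float,
    seed: int,
    stratify_by: str | None = None,
) -> tuple[DiscreteDataset, DiscreteDataset]:
    """Random disjoint partition; train size is ``round(fraction * N)``.

    In stratified mode the per-level target proportions are preserved
    within rounding.  Both partitions keep the original record order.
    """
    if not 0.0 < fraction < 1.0:
        raise ContractError("fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    n = data.n_records
    n_train = int(round(fraction * n))
    if stratify_by is None:
        perm = rng.permutation(n)
        train_rows = np.sort(perm[:n_train])
        test_rows = np.sort(perm[n_train:])
    else:
        col = data.column(stratify_by)
        train_parts = []
        # largest stratum last so the rounding fix-up lands on it
        strata = sorted(
            np.unique(col), key=lambda lv: (np.sum(col == lv), lv)
        )
        taken = 0
        for i, level in enumerate(strata):
            rows = np.flatnonzero(col == level)
            if i == len(strata) - 1:
                k = n_train - taken
            else:
                k = int(round(fraction * rows.size))
            k = min(max(k, 0), rows.size)
            taken += k
            train_parts.append(rng.permutation(rows)[:k])
        train_rows = np.sort(np.concatenate(train_parts))
        mask = np.zeros(n, dtype=bool)
        mask[train_rows] = True
        test_rows = np.flatnonzero(~mask)
    if train_rows.size == 0 or test_rows.size == 0:
        raise ContractError("split produced an empty partition")
    return data.take(train_rows), data.take(test_rows)


def undersample(data: DiscreteDataset, target: str, seed: int) -> DiscreteDataset:
    """Random under-sampling of the majority class to class equality.

    Keeps every minority record and a uniform without-replacement subset of
    the majority records of the same size; output rows keep the original
    record order.  Requires a binary target with both classes present.
    """
    col = data.column(target)
    if data.cardinality(target) != 2:
        raise ContractError(f"target {target!r} must be binary")
    counts = np.bincount(col, minlength=2)
    if counts.min() == 0:
        raise DegenerateClassError(
            f"target {target!r} has a single class; cannot balance"
        )
    minority = int(np.argmin(counts))  # tie -> first level, harmless
    rng = np.random.default_rng(seed)
    minority_rows = np.flatnonzero(col == minority)
    majority_rows = np.flatnonzero(col != minority)
    keep = rng.choice(majority_rows, size=minority_rows.size, replace=False)
    rows = np.sort(np.concatenate([minority_rows, keep]))
    return data.take(rows)
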