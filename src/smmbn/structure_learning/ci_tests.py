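"""Conditional-independence testing (G-squared / mutual-information test)."""

from __future__ import annotations

import dataclasses
from collections.abc import Sequence

import numpy as np
from scipy import stats

from ..bn_core.cpt import _config_index
from ..bn_core.dataset import DiscreteDataset
from ..exceptions import ContractError

__all__ = ["CiTestResult", "ci_test_g2", "CiOracle"]


@dataclasses.dataclass(frozen=True)
class CiTestResult:
    statistic: float
    df: int
    p_value: float
    independent: bool
    #: True when the N >= 5 * df reliability heuristic failed and the verdict
    #: defaulted to independence.
    unreliable: bool = False


def ci_test_g2(
    x: str,
    y: str,
    z: Sequence[str],
    data: DiscreteDataset,
    alpha: float = 0.05,
    min_obs_per_df: float | None = 5.0,
) -> CiTestResult:
    """G^2 test of ``x`` independent of ``y`` given set ``z``.

    ``G^2 = 2 * sum N_xyz * ln(N_xyz * N_z / (N_xz * N_yz))`` with empty
    strata contributing 0; ``df = (r_x - 1)(r_y - 1) * prod r_z``; the
    p-value is the chi-square upper tail and independence is declared when
    ``p > alpha``.  When ``N < min_obs_per_df * df`` the verdict defaults to
    independent (insufficient data); pass ``min_obs_per_df=None`` to disable.
    """
    if x == y:
        raise ContractError("x and y must differ")
    z = tuple(z)
    if x in z or y in z:
        raise ContractError("x and y must not be in the conditioning set")
    if not 0 < alpha < 1:
        raise ContractError("alpha must be in (0, 1)")

    rx, ry = data.cardinality(x), data.cardinality(y)
    cards_z = [data.cardinality(v) for v in z]
    qz = int(np.prod(cards_z, dtype=np.int64)) if z else 1
    cfg = _config_index(data.codes, [data.index_of(v) for v in z], cards_z)
    combined = (cfg * rx + data.column(x)) * ry + data.column(y)
    n_xyz = np.bincount(combined, minlength=qz * rx * ry).reshape(qz, rx, ry)
    n_xyz = n_xyz.astype(float)
    n_xz = n_xyz.sum(axis=2, keepdims=True)
    n_yz = n_xyz.sum(axis=1, keepdims=True)
    n_z = n_xyz.sum(axis=(1, 2), keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = n_xyz * n_z / (n_xz * n_yz)
        terms = np.where(n_xyz > 0, n_xyz * np.log(ratio), 0.0)
    g2 = float(2.0 * np.nansum(terms))
    df = (rx - 1) * (ry - 1) * qz
    p = float(stats.chi2.sf(g2, df)) if df > 0 else 1.0
    unreliable = (
        min_obs_per_df is not None and data.n_records < min_obs_per_df * df
    )
    independent = True if unreliable else p > alpha
    return CiTestResult(g2, df, p, independent, unreliable)


class CiOracle:
    """Memoizing wrapper used by the constraint-based learners."""

    def __init__(
        self,
        data: DiscreteDataset,
        alpha: float = 0.05,
        min_obs_per_df: float | None = 5.0,
    ) -> None:
        self.data = data
        self.alpha = alpha
        self.min_obs_per_df = min_obs_per_df
        self._cache: dict[tuple, CiTestResult] = {}
        self.n_tests = 0

    def test(self, x: str, y: str, z=()) -> CiTestResult:
        key = (frozenset((x, y)), frozenset(z))
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        res = ci_test_g2(
            x, y, sorted(z), self.data, self.alpha, self.min_obs_per_df
        )
        self.n_tests += 1
        self._cache[key] = res
        return res

    def dependent(self, x: str, y: str, z=()) -> bool:
        return not self.test(x, y, z).independent

    def association(self, x: str, y: str, z=()) -> float:
        """Association strength (the G^2 statistic; larger = stronger)."""
        return self.test(x, y, z).statistic
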