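"""Complete categorical datasets over declared variables.

Records are stored as an ``(N, p)`` integer code matrix; level labels and the
layer tag of each variable live in :class:`VariableSpec`.  Layer 0 is the most
upstream layer (demographics / area variables); larger layers sit downstream.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Iterable, Sequence

import numpy as np
import pandas as pd

from ..exceptions import ContractError, IdentifierError

__all__ = ["VariableSpec", "DiscreteDataset"]


@dataclasses.dataclass(frozen=True)
class VariableSpec:
    """A categorical variable: name, ordered level labels and a layer tag."""

    name: str
    levels: tuple[str, ...]
    layer: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "levels", tuple(str(v) for v in self.levels))
        if len(self.levels) < 2:
            raise ContractError(f"variable {self.name!r} needs >= 2 levels")
        if len(set(self.levels)) != len(self.levels):
            raise ContractError(f"variable {self.name!r} has duplicate levels")
        if self.layer < 0:
            raise ContractError(f"variable {self.name!r} has negative layer")

    @property
    def cardinality(self) -> int:
        return len(self.levels)

    def code_of(self, label: str) -> int:
        try:
            return self.levels.index(str(label))
        except ValueError:
            raise IdentifierError(
                f"{label!r} is not a level of {self.name!r}"
            ) from None


class DiscreteDataset:
    """N complete records over a fixed list of :class:`VariableSpec`.

    Parameters
    ----------
    variables:
        Ordered variable declarations.
    codes:
        Integer array of shape ``(N, p)``; entry ``[i, j]`` is the level index
        of record ``i`` on variable ``j``.  Must be complete and in range.
    """

    def __init__(self, variables: Sequence[VariableSpec], codes) -> None:
        self._variables = tuple(variables)
        if len({v.name for v in self._variables}) != len(self._variables):
            raise ContractError("duplicate variable names")
        arr = np.asarray(codes, dtype=np.int64)
        if arr.ndim != 2 or arr.shape[1] != len(self._variables):
            raise ContractError(
                f"codes must have shape (N, {len(self._variables)})"
            )
        if arr.shape[0] < 1:
            raise ContractError("dataset must contain at least one record")
        for j, spec in enumerate(self._variables):
            col = arr[:, j]
            if col.min() < 0 or col.max() >= spec.cardinality:
                raise ContractError(
                    f"column {spec.name!r} has codes outside "
                    f"[0, {spec.cardinality})"
                )
        arr.setflags(write=False)
        self._codes = arr
        self._index = {v.name: j for j, v in enumerate(self._variables)}

    # -- basic accessors ---------------------------------------------------

    @property
    def variables(self) -> tuple[VariableSpec, ...]:
        return self._variables

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(v.name for v in self._variables)

    @property
    def codes(self) -> np.ndarray:
        return self._codes

    @property
    def n_records(self) -> int:
        return self._codes.shape[0]

    def __len__(self) -> int:
        return self.n_records

    def spec(self, name: str) -> VariableSpec:
        return self._variables[self.index_of(name)]

    def index_of(self, name: str) -> int:
        try:
            return self._index[name]
        except KeyError:
            raise IdentifierError(f"unknown variable {name!r}") from None

    def column(self, name: str) -> np.ndarray:
        return self._codes[:, self.index_of(name)]

    def cardinality(self, name: str) -> int:
        return self.spec(name).cardinality

    # -- derived datasets --------------------------------------------------

    def take(self, rows: Iterable[int]) -> "DiscreteDataset":
        """Row subset / resample (row order follows ``rows``)."""
        idx = np.asarray(list(rows), dtype=np.int64)
        return DiscreteDataset(self._variables, self._codes[idx])

    def __eq__(self, other) -> bool:
        if not isinstance(other, DiscreteDataset):
            return NotImplemented
        return self._variables == other._variables and np.array_equal(
            self._codes, other._codes
        )

    # -- interchange -------------------------------------------------------

    def to_dataframe(self) -> pd.DataFrame:
        data = {
            v.name: pd.Categorical.from_codes(
                self._codes[:, j], categories=list(v.levels)
            )
            for j, v in enumerate(self._variables)
        }
        return pd.DataFrame(data)

    @classmethod
    def from_dataframe(
        cls,
        frame: pd.DataFrame,
        variables: Sequence[VariableSpec] | None = None,
        layers: dict[str, int] | None = None,
    ) -> "DiscreteDataset":
        """Build a dataset from a string/categorical data frame.

        When ``variables`` is omitted, level sets are inferred as the sorted
        distinct values of each column (deterministic) and layers are taken
        from ``layers`` (default 0).
        """
        if frame.isna().any().any():
            raise ContractError("dataset must be complete (no missing values)")
        if variables is None:
            layers = layers or {}
            variables = [
                VariableSpec(
                    str(col),
                    tuple(sorted(frame[col].astype(str).unique())),
                    layers.get(str(col), 0),
                )
                for col in frame.columns
            ]
        variables = tuple(variables)
        codes = np.empty((len(frame), len(variables)), dtype=np.int64)
        for j, spec in enumerate(variables):
            if spec.name not in frame.columns:
                raise IdentifierError(f"column {spec.name!r} missing from frame")
            col = frame[spec.name].astype(str)
            mapping = {lab: i for i, lab in enumerate(spec.levels)}
            mapped = col.map(mapping)
            if mapped.isna().any():
                bad = sorted(set(col[mapped.isna()]))
                raise ContractError(
                    f"column {spec.name!r} contains undeclared levels {bad}"
                )
            codes[:, j] = mapped.to_numpy(dtype=np.int64)
        return cls(variables, codes)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def read_csv(
        cls,
        path,
        variables: Sequence[VariableSpec] | None = None,
        layers: dict[str, int] | None = None,
    ) -> "DiscreteDataset":
        frame = pd.read_csv(path, dtype=str, keep_default_na=False)
        return cls.from_dataframe(frame, variables=variables, layers=layers)
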