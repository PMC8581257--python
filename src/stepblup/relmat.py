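"""Animal-indexed relationship matrices.

A :class:`RelationshipMatrix` couples a symmetric kinship-like matrix with an
explicit ordered list of animal ids, so that every downstream consumer (the
mixed-model solver, the single-step combiner, CSV export) agrees on which row
belongs to which animal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Recognised matrix kinds.
KINDS = frozenset(
    {"A", "A_inverse", "A22", "A22_inverse", "G", "G_inverse", "H", "H_inverse"}
)

SYMMETRY_TOL = 1e-10


@dataclass
class RelationshipMatrix:
    """Symmetric animal × animal matrix with an id ↔ row map.

    Parameters
    ----------
    values
        Symmetric ``(n, n)`` array.
    ids
        Animal ids in row (= column) order; must be unique.
    kind
        One of ``A``, ``A_inverse``, ``A22``, ``A22_inverse``, ``G``,
        ``G_inverse``, ``H_inverse``.
    """

    values: np.ndarray
    ids: list[str]
    kind: str
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.ids = [str(i) for i in self.ids]
        if self.kind not in KINDS:
            raise ValueError(f"unknown relationship-matrix kind {self.kind!r}")
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match {n} ids"
            )
        if len(set(self.ids)) != n:
            raise ValueError("duplicate animal ids in relationship matrix")
        if n and not np.allclose(self.values, self.values.T, atol=SYMMETRY_TOL):
            raise ValueError("relationship matrix is not symmetric")
        self._index = {a: i for i, a in enumerate(self.ids)}

    @property
    def n(self) -> int:
        return len(self.ids)

    def index_of(self, animal_ids) -> np.ndarray:
        """Row indices for ``animal_ids``; raises listing unknown ids."""
        missing = [a for a in animal_ids if str(a) not in self._index]
        if missing:
            raise KeyError(f"ids not in relationship matrix: {missing}")
        return np.asarray([self._index[str(a)] for a in animal_ids], dtype=int)

    def submatrix(self, animal_ids, kind: str | None = None) -> "RelationshipMatrix":
        """Principal submatrix in the order of ``animal_ids``."""
        idx = self.index_of(animal_ids)
        return RelationshipMatrix(
            self.values[np.ix_(idx, idx)],
            [str(a) for a in animal_ids],
            kind or self.kind,
        )

    def to_csv(self, path) -> None:
        pd.DataFrame(self.values, index=self.ids, columns=self.ids).to_csv(path)

    @classmethod
    def from_csv(cls, path, kind: str) -> "RelationshipMatrix":
        df = pd.read_csv(path, index_col=0)
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        if list(df.index) != list(df.columns):
            raise ValueError("row and column ids differ in matrix CSV")
        return cls(df.to_numpy(dtype=float), list(df.index), kind)
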