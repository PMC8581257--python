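"""Pedigree handling and pedigree-based (numerator) relationship matrices.

Builds the additive relationship matrix A by the tabular method, its inverse
by Henderson's rules with inbreeding, and the genotyped-subset block A22.
"""

from __future__ import annotations

import graphlib
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .relmat import RelationshipMatrix

logger = logging.getLogger(__name__)

#: Accepted missing-parent spellings in input files.
MISSING_CODES = {"0", "", "NA", "na", "nan", "None"}
#: Canonical internal sentinel for an unknown parent (index form uses -1).
UNKNOWN = "0"


def _normalize(code) -> str | None:
    if code is None:
        return None
    s = str(code).strip()
    return None if s in MISSING_CODES else s


@dataclass
class PedigreeTable:
    """Topologically ordered pedigree.

    ``ids`` lists every animal (parents of any named animal included, inserted
    as implicit founders) in an order where parents precede offspring.
    ``sire_idx``/``dam_idx`` give the parent's position in ``ids`` or -1 for an
    unknown parent.
    """

    ids: list[str]
    sire_idx: np.ndarray
    dam_idx: np.ndarray

    @classmethod
    def from_records(cls, records) -> "PedigreeTable":
        """Build from (animal, sire, dam) triples.

        Missing parents may be given as ``0``, the empty string or ``NA``.
        Parents without a row of their own are inserted as founders. Raises
        ``ValueError`` on duplicate animal rows or pedigree cycles.
        """
        parents: dict[str, tuple[str | None, str | None]] = {}
        for animal, sire, dam in records:
            a = _normalize(animal)
            if a is None:
                raise ValueError("animal id missing in pedigree row")
            if a in parents:
                raise ValueError(f"duplicate pedigree row for animal {a!r}")
            parents[a] = (_normalize(sire), _normalize(dam))
        n_explicit = len(parents)
        for s, d in list(parents.values()):
            for p in (s, d):
                if p is not None and p not in parents:
                    parents[p] = (None, None)
        if len(parents) > n_explicit:
            logger.info(
                "inserted %d implicit founders", len(parents) - n_explicit
            )

        sorter = graphlib.TopologicalSorter(
            {a: [p for p in ps if p is not None] for a, ps in parents.items()}
        )
        try:
            order = list(sorter.static_order())
        except graphlib.CycleError as exc:
            cycle = exc.args[1] if len(exc.args) > 1 else "?"
            raise ValueError(f"pedigree cycle detected: {cycle}") from None

        index = {a: i for i, a in enumerate(order)}
        sire_idx = np.full(len(order), -1, dtype=int)
        dam_idx = np.full(len(order), -1, dtype=int)
        for a, (s, d) in parents.items():
            i = index[a]
            if s is not None:
                sire_idx[i] = index[s]
            if d is not None:
                dam_idx[i] = index[d]
        return cls(order, sire_idx, dam_idx)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PedigreeTable":
        cols = [c.lower() for c in df.columns]
        df = df.set_axis(cols, axis=1)
        return cls.from_records(
            df[["animal", "sire", "dam"]].itertuples(index=False, name=None)
        )

    @property
    def n(self) -> int:
        return len(self.ids)

    def is_founder(self, i: int) -> bool:
        return self.sire_idx[i] < 0 and self.dam_idx[i] < 0

    def to_frame(self) -> pd.DataFrame:
        """Pedigree as an animal/sire/dam frame, unknown parents as '0'."""
        ids = np.asarray(self.ids, dtype=object)

        def _p(idx):
            return [UNKNOWN if j < 0 else ids[j] for j in idx]

        return pd.DataFrame(
            {"animal": self.ids, "sire": _p(self.sire_idx), "dam": _p(self.dam_idx)}
        )


def build_a_matrix(ped: PedigreeTable) -> RelationshipMatrix:
    """Numerator relationship matrix A by the tabular method.

    ``a(i,i) = 1 + 0.5·a(s,d)``; ``a(i,j) = 0.5·(a(j,s) + a(j,d))`` for j
    processed before i; an unknown parent contributes 0.
    """
    n = ped.n
    A = np.zeros((n, n))
    for i in range(n):
        s, d = ped.sire_idx[i], ped.dam_idx[i]
        row = np.zeros(i)
        if s >= 0:
            row += 0.5 * A[:i, s]
        if d >= 0:
            row += 0.5 * A[:i, d]
        A[i, :i] = row
        A[:i, i] = row
        A[i, i] = 1.0 + (0.5 * A[s, d] if s >= 0 and d >= 0 else 0.0)
    return RelationshipMatrix(A, ped.ids, "A")


def inbreeding_coefficients(ped: PedigreeTable) -> np.ndarray:
    """F_i = a(i,i) − 1 from the tabular A."""
    return np.diag(build_a_matrix(ped).values) - 1.0


def build_a_inverse(
    ped: PedigreeTable, inbreeding: np.ndarray | None = None
) -> RelationshipMatrix:
    """A⁻¹ by Henderson's rules with inbreeding coefficients.

    The Mendelian-sampling variance of animal i is
    ``0.5 − 0.25·(F_s + F_d)`` with both parents known,
    ``0.75 − 0.25·F_p`` with one, and 1 for a founder; its reciprocal is
    scattered over the animal/parent rows and columns.
    """
    F = inbreeding_coefficients(ped) if inbreeding is None else inbreeding
    n = ped.n
    Ainv = np.zeros((n, n))
    for i in range(n):
        s, d = ped.sire_idx[i], ped.dam_idx[i]
        m = 1.0
        if s >= 0:
            m -= 0.25 * (1.0 + F[s])
        if d >= 0:
            m -= 0.25 * (1.0 + F[d])
        alpha = 1.0 / m
        Ainv[i, i] += alpha
        for p in (s, d):
            if p >= 0:
                Ainv[i, p] -= 0.5 * alpha
                Ainv[p, i] -= 0.5 * alpha
        for p in (s, d):
            for q in (s, d):
                if p >= 0 and q >= 0:
                    Ainv[p, q] += 0.25 * alpha
    return RelationshipMatrix(Ainv, ped.ids, "A_inverse")


def extract_a22(A: RelationshipMatrix, genotyped_ids) -> RelationshipMatrix:
    """Principal block of A for the genotyped animals, in their given order."""
    if A.kind != "A":
        raise ValueError(f"expected an A matrix, got kind {A.kind!r}")
    return A.submatrix(genotyped_ids, kind="A22")
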