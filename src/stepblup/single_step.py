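"""Single-step combination of pedigree and genomic relationships.

H⁻¹ equals A⁻¹ plus a correction block ``τ·G⁻¹ − ω·A22⁻¹`` on the rows and
columns of the genotyped animals; ungenotyped animals are touched only through
A⁻¹.
"""

from __future__ import annotations

import numpy as np
from scipy import linalg

from .relmat import RelationshipMatrix


def _inverse_pd(values: np.ndarray, what: str) -> np.ndarray:
    try:
        c, low = linalg.cho_factor(values, check_finite=False)
    except linalg.LinAlgError as exc:
        raise ValueError(
            f"{what} is singular or not positive definite; "
            "blend G toward A22 (blend_weight > 0) before the single-step"
        ) from exc
    inv = linalg.cho_solve((c, low), np.eye(values.shape[0]), check_finite=False)
    return (inv + inv.T) / 2.0


def build_h_inverse(
    Ainv: RelationshipMatrix,
    G: RelationshipMatrix | None,
    A22: RelationshipMatrix | None,
    genotyped_ids,
    tau: float = 1.0,
    omega: float = 1.0,
) -> RelationshipMatrix:
    """Assemble H⁻¹ from A⁻¹ with the genomic correction on genotyped animals.

    ``genotyped_ids`` must be a subset of ``Ainv.ids`` and must index G and
    A22 identically (same order). With no genotyped animals, or with G equal
    to A22 at τ=ω=1, the result is A⁻¹ exactly.
    """
    genotyped_ids = [str(a) for a in genotyped_ids]
    Hinv = Ainv.values.copy()
    if genotyped_ids:
        if G is None or A22 is None:
            raise ValueError("G and A22 are required when genotyped_ids is non-empty")
        if G.ids != genotyped_ids or A22.ids != genotyped_ids:
            raise ValueError("G / A22 id order must match genotyped_ids exactly")
        idx = Ainv.index_of(genotyped_ids)
        correction = tau * _inverse_pd(G.values, "G") - omega * _inverse_pd(
            A22.values, "A22"
        )
        Hinv[np.ix_(idx, idx)] += correction
    return RelationshipMatrix(Hinv, Ainv.ids, "H_inverse")


def assemble_h(
    A: RelationshipMatrix, G: RelationshipMatrix, genotyped_ids
) -> RelationshipMatrix:
    """Explicit H (dense), used as a cross-check oracle for ``build_h_inverse``.

    H22 = G; H12 = A12·A22⁻¹·G; H11 = A11 + A12·A22⁻¹·(G − A22)·A22⁻¹·A21.
    """
    genotyped_ids = [str(a) for a in genotyped_ids]
    if G.ids != genotyped_ids:
        raise ValueError("G id order must match genotyped_ids")
    g_idx = A.index_of(genotyped_ids)
    u_idx = np.asarray(
        [i for i in range(A.n) if i not in set(g_idx)], dtype=int
    )
    A11 = A.values[np.ix_(u_idx, u_idx)]
    A12 = A.values[np.ix_(u_idx, g_idx)]
    A22 = A.values[np.ix_(g_idx, g_idx)]
    A22inv = _inverse_pd(A22, "A22")
    B = A12 @ A22inv
    H = np.zeros_like(A.values)
    H[np.ix_(u_idx, u_idx)] = A11 + B @ (G.values - A22) @ B.T
    H[np.ix_(u_idx, g_idx)] = B @ G.values
    H[np.ix_(g_idx, u_idx)] = (B @ G.values).T
    H[np.ix_(g_idx, g_idx)] = G.values
    return RelationshipMatrix((H + H.T) / 2.0, A.ids, "H")
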