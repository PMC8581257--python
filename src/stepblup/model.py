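"""Repeatability animal model fitted by Henderson's mixed-model equations.

The model for one 305-day record is

    y = mu + breed + lactation_number + HYS + animal + permanent_env + e

with the animal effect correlated through a relationship matrix (pedigree A,
genomic G, or single-step H — the solver is identical, only the supplied
inverse differs) and an independent permanent-environment effect per
phenotyped animal. Variance components are inputs, not estimated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, sparse

from .io import LactationRecord, records_to_frame
from .relmat import RelationshipMatrix

logger = logging.getLogger(__name__)

FIXED_FACTORS = ("breed", "lactation_number", "hys")


@dataclass
class VarianceComponents:
    """Additive, permanent-environment and residual variances."""

    sigma2_a: float
    sigma2_pe: float
    sigma2_e: float

    def __post_init__(self) -> None:
        if self.sigma2_a <= 0 or self.sigma2_e <= 0 or self.sigma2_pe < 0:
            raise ValueError(
                "need sigma2_a > 0, sigma2_e > 0, sigma2_pe >= 0; "
                f"got {self.sigma2_a}, {self.sigma2_pe}, {self.sigma2_e}"
            )

    @classmethod
    def from_ratios(
        cls, h2: float, repeatability: float, sigma2_p: float = 1.0
    ) -> "VarianceComponents":
        if not 0 < h2 <= repeatability < 1:
            raise ValueError("need 0 < h2 <= repeatability < 1")
        return cls(
            sigma2_a=h2 * sigma2_p,
            sigma2_pe=(repeatability - h2) * sigma2_p,
            sigma2_e=(1.0 - repeatability) * sigma2_p,
        )

    @property
    def sigma2_p(self) -> float:
        return self.sigma2_a + self.sigma2_pe + self.sigma2_e

    @property
    def h2(self) -> float:
        return self.sigma2_a / self.sigma2_p

    @property
    def repeatability(self) -> float:
        return (self.sigma2_a + self.sigma2_pe) / self.sigma2_p

    @property
    def lambda_a(self) -> float:
        return self.sigma2_e / self.sigma2_a

    @property
    def lambda_pe(self) -> float:
        return self.sigma2_e / self.sigma2_pe


class FixedEffectsEncoder:
    """Reference-level (drop-first) dummy coding for the fixed factors.

    The first category of each factor (sorted order) is the reference; the
    intercept is retained. Records whose level was unseen at fit time are
    flagged invalid on transform.
    """

    def __init__(self) -> None:
        self.levels: dict[str, list[str]] = {}
        self.columns: list[str] = []

    def fit(self, df: pd.DataFrame) -> "FixedEffectsEncoder":
        self.columns = ["intercept"]
        for factor in FIXED_FACTORS:
            cats = sorted(df[factor].astype(str).unique())
            self.levels[factor] = cats
            self.columns += [f"{factor}[{c}]" for c in cats[1:]]
        return self

    def transform(self, df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
        n = len(df)
        X = np.zeros((n, len(self.columns)))
        X[:, 0] = 1.0
        valid = np.ones(n, dtype=bool)
        col = {name: j for j, name in enumerate(self.columns)}
        for factor in FIXED_FACTORS:
            cats = set(self.levels[factor])
            values = df[factor].astype(str).to_numpy()
            for i, v in enumerate(values):
                if v not in cats:
                    valid[i] = False
                    continue
                name = f"{factor}[{v}]"
                if name in col:
                    X[i, col[name]] = 1.0
        return X, valid


@dataclass
class Design:
    """Design matrices for one model fit."""

    y: np.ndarray
    X: np.ndarray
    Z_a: sparse.csr_matrix
    Z_pe: sparse.csr_matrix
    encoder: FixedEffectsEncoder
    animal_ids: list[str]
    pheno_ids: list[str]


def build_design(records: list[LactationRecord], ids) -> Design:
    """Build y, X, Z_a, Z_pe for the record list against the animal order ``ids``.

    ``Z_a`` maps records to every animal in ``ids`` (so unphenotyped animals
    get breeding values through their relationships); ``Z_pe`` maps records to
    phenotyped animals only.
    """
    ids = [str(a) for a in ids]
    df = records_to_frame(records)
    index = {a: i for i, a in enumerate(ids)}
    unknown = sorted(set(df["animal_id"]) - set(ids))
    if unknown:
        raise ValueError(f"record animals missing from relationship ids: {unknown}")

    encoder = FixedEffectsEncoder().fit(df)
    X, _ = encoder.transform(df)

    pheno_ids = sorted(df["animal_id"].unique())
    pheno_index = {a: i for i, a in enumerate(pheno_ids)}
    rows = np.arange(len(df))
    a_cols = df["animal_id"].map(index).to_numpy()
    p_cols = df["animal_id"].map(pheno_index).to_numpy()
    ones = np.ones(len(df))
    Z_a = sparse.csr_matrix((ones, (rows, a_cols)), shape=(len(df), len(ids)))
    Z_pe = sparse.csr_matrix((ones, (rows, p_cols)), shape=(len(df), len(pheno_ids)))
    return Design(
        y=df["yield_305d"].to_numpy(dtype=float),
        X=X,
        Z_a=Z_a,
        Z_pe=Z_pe,
        encoder=encoder,
        animal_ids=ids,
        pheno_ids=pheno_ids,
    )


@dataclass
class ModelSolution:
    """Fixed-effect and random-effect estimates from one MME solve."""

    beta: pd.Series
    ebv: pd.Series
    pe: pd.Series
    encoder: FixedEffectsEncoder
    kept_columns: np.ndarray
    vc: VarianceComponents
    diagnostics: dict = field(default_factory=dict)

    def fixed_values(self, records: list[LactationRecord]) -> tuple[np.ndarray, np.ndarray]:
        """Fitted fixed part x'b per record plus a validity mask."""
        df = records_to_frame(records)
        X, valid = self.encoder.transform(df)
        fitted = X[:, self.kept_columns] @ self.beta.to_numpy()
        return fitted, valid


def _independent_columns(X: np.ndarray, tol: float) -> np.ndarray:
    """Column indices of a full-rank subset of X (QR with pivoting)."""
    if X.shape[1] == 0:
        return np.arange(0)
    _, R, piv = linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    if diag.size == 0 or diag[0] == 0:
        return np.arange(0)
    rank = int((diag > max(X.shape) * tol * diag[0]).sum())
    return np.sort(piv[:rank])


def solve_mme(
    design: Design,
    Kinv: RelationshipMatrix,
    vc: VarianceComponents,
    tol: float = 1e-10,
) -> ModelSolution:
    """Solve Henderson's mixed-model equations by dense Cholesky.

    Coefficient matrix::

        [ X'X      X'Z_a                X'Z_pe          ]
        [ Z_a'X    Z_a'Z_a + λ_A·K⁻¹    Z_a'Z_pe        ]
        [ Z_pe'X   Z_pe'Z_a             Z_pe'Z_pe + λ_PE·I ]

    against [X'y, Z_a'y, Z_pe'y]. With σ²_PE = 0 the PE block is omitted.
    """
    if design.animal_ids != Kinv.ids:
        raise ValueError("design animal order does not match Kinv ids")
    y, X = design.y, design.X
    Z_a, Z_pe = design.Z_a, design.Z_pe

    kept = _independent_columns(X, tol)
    if len(kept) < X.shape[1]:
        dropped = [
            design.encoder.columns[j]
            for j in range(X.shape[1])
            if j not in set(kept)
        ]
        logger.warning("dropped %d non-estimable fixed columns: %s", len(dropped), dropped)
    X = X[:, kept]

    use_pe = vc.sigma2_pe > 0
    n_f, n_a = X.shape[1], len(design.animal_ids)
    n_p = len(design.pheno_ids) if use_pe else 0
    n_eq = n_f + n_a + n_p

    C = np.zeros((n_eq, n_eq))
    rhs = np.zeros(n_eq)
    sl_f = slice(0, n_f)
    sl_a = slice(n_f, n_f + n_a)
    sl_p = slice(n_f + n_a, n_eq)

    XtZa = Z_a.T.dot(X).T  # n_f × n_a
    C[sl_f, sl_f] = X.T @ X
    C[sl_f, sl_a] = XtZa
    C[sl_a, sl_f] = XtZa.T
    C[sl_a, sl_a] = (Z_a.T @ Z_a).toarray() + vc.lambda_a * Kinv.values
    rhs[sl_f] = X.T @ y
    rhs[sl_a] = Z_a.T @ y
    if use_pe:
        XtZp = Z_pe.T.dot(X).T
        ZaZp = (Z_a.T @ Z_pe).toarray()
        C[sl_f, sl_p] = XtZp
        C[sl_p, sl_f] = XtZp.T
        C[sl_a, sl_p] = ZaZp
        C[sl_p, sl_a] = ZaZp.T
        C[sl_p, sl_p] = (Z_pe.T @ Z_pe).toarray() + vc.lambda_pe * np.eye(n_p)
        rhs[sl_p] = Z_pe.T @ y

    try:
        cf = linalg.cho_factor(C, check_finite=False)
    except linalg.LinAlgError as exc:
        raise ValueError(
            "mixed-model coefficient matrix is not positive definite "
            f"(n_eq={n_eq}, rank(X)={n_f}); check Kinv and variance ratios"
        ) from exc
    sol = linalg.cho_solve(cf, rhs, check_finite=False)

    beta = pd.Series(
        sol[sl_f], index=[design.encoder.columns[j] for j in kept], name="beta"
    )
    ebv = pd.Series(sol[sl_a], index=design.animal_ids, name="ebv")
    if use_pe:
        pe = pd.Series(sol[sl_p], index=design.pheno_ids, name="pe")
    else:
        pe = pd.Series(np.zeros(len(design.pheno_ids)), index=design.pheno_ids, name="pe")
    return ModelSolution(
        beta=beta,
        ebv=ebv,
        pe=pe,
        encoder=design.encoder,
        kept_columns=kept,
        vc=vc,
        diagnostics={
            "n_equations": n_eq,
            "n_records": len(y),
            "rank_X": n_f,
            "kinv_kind": Kinv.kind,
        },
    )


def adjust_phenotypes(
    records: list[LactationRecord], solution: ModelSolution
) -> tuple[pd.Series, int]:
    """Per-animal mean of y − x'b̂ over that animal's records.

    Records whose fixed-effect levels were unseen at fit time are dropped;
    the count of dropped records is returned alongside.
    """
    fitted, valid = solution.fixed_values(records)
    n_dropped = int((~valid).sum())
    if n_dropped:
        logger.info("adjustment dropped %d records with unestimated levels", n_dropped)
    df = records_to_frame(records)
    df = df[valid].assign(adj=df["yield_305d"].to_numpy()[valid] - fitted[valid])
    adj = df.groupby("animal_id")["adj"].mean()
    adj.name = "adj_pheno"
    return adj, n_dropped
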