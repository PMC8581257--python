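"""Lactation-count cross-validation with accuracy and dispersion-bias output.

Animals are split into three test sets by how many lactation records they
have (1, 2 or 3). For each fold the test animals' phenotypes are masked, the
model is refitted on the remainder, and the held-out animals' adjusted
phenotypes are compared with their predicted breeding values:

* accuracy  r = corr(EBV, adj.pheno) / sqrt( h² / (rep + (1−rep)/n) )
  — at n = 1 the denominator reduces to h exactly;
* bias slope = OLS slope of adjusted phenotype on EBV (1 = unbiased,
  < 1 = over-dispersed EBVs).

A trait's reported accuracy/slope is the mean over the three folds; the ±
value is the standard deviation across folds.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import LactationRecord
from .model import VarianceComponents, adjust_phenotypes, build_design, solve_mme
from .relmat import RelationshipMatrix

logger = logging.getLogger(__name__)

FOLD_LABELS = {1: "1-record", 2: "2-record", 3: "3-record"}


@dataclass
class CvFold:
    """One lactation-count test set and its complementary training set."""

    label: str
    n_lactations: int
    test_ids: list[str]
    test_records: list[LactationRecord]
    training_records: list[LactationRecord]


@dataclass
class EvaluationReport:
    """Per-fold and per-trait cross-validation statistics."""

    method: str
    trait: str
    folds: pd.DataFrame
    accuracy_mean: float
    accuracy_sd: float
    slope_mean: float
    slope_sd: float

    def to_frame(self) -> pd.DataFrame:
        df = self.folds.copy()
        df.insert(0, "trait", self.trait)
        df.insert(1, "method", self.method)
        return df


def assign_folds(records: list[LactationRecord]) -> list[CvFold]:
    """Split animals into 1-, 2- and 3-record folds by record count."""
    by_animal: dict[str, list[LactationRecord]] = {}
    for rec in records:
        by_animal.setdefault(rec.animal_id, []).append(rec)
    for animal, recs in by_animal.items():
        if not 1 <= len(recs) <= 3:
            raise ValueError(f"animal {animal} has {len(recs)} records (need 1..3)")
    folds = []
    for n in (1, 2, 3):
        test_ids = sorted(a for a, recs in by_animal.items() if len(recs) == n)
        test_set = set(test_ids)
        folds.append(
            CvFold(
                label=FOLD_LABELS[n],
                n_lactations=n,
                test_ids=test_ids,
                test_records=[r for r in records if r.animal_id in test_set],
                training_records=[r for r in records if r.animal_id not in test_set],
            )
        )
    return folds


def accuracy(correlation: float, h2: float, rep: float, n: int) -> float:
    """Correlation rescaled by the square root of the heritability of an
    n-record mean: r = corr / sqrt(h² / (rep + (1−rep)/n))."""
    if h2 <= 0:
        raise ValueError("h2 must be positive")
    if not h2 <= rep < 1:
        raise ValueError("need h2 <= rep < 1")
    if n < 1:
        raise ValueError("n must be a positive lactation count")
    denominator = math.sqrt(h2 / (rep + (1.0 - rep) / n))
    return correlation / denominator


def bias_slope(adjusted: np.ndarray, ebv: np.ndarray) -> float:
    """OLS slope of adjusted phenotype (response) on EBV (predictor)."""
    adjusted = np.asarray(adjusted, dtype=float)
    ebv = np.asarray(ebv, dtype=float)
    if adjusted.shape != ebv.shape or adjusted.size < 3:
        raise ValueError("need >=3 paired values")
    dev = ebv - ebv.mean()
    ss = float(dev @ dev)
    if ss <= 0:
        logger.warning("zero EBV variance: bias slope undefined")
        return float("nan")
    return float(dev @ (adjusted - adjusted.mean()) / ss)


def run_cross_validation(
    records: list[LactationRecord],
    Kinv: RelationshipMatrix,
    vc: VarianceComponents,
    method: str = "pblup",
    trait: str = "MY",
    min_test_animals: int = 3,
    adjust_with: str = "training",
    solver_tol: float = 1e-10,
) -> EvaluationReport:
    """Threefold lactation-count cross-validation for one method and trait.

    Per fold: mask the test animals' phenotypes, refit on the training
    records, adjust the held-out phenotypes with the training fixed-effect
    estimates (``adjust_with='whole'`` uses an all-record fit instead), and
    compute correlation, accuracy and bias slope on per-animal pairs.
    """
    if adjust_with not in ("training", "whole"):
        raise ValueError("adjust_with must be 'training' or 'whole'")
    h2, rep = vc.h2, vc.repeatability
    whole_fit = None
    if adjust_with == "whole":
        whole_fit = solve_mme(build_design(records, Kinv.ids), Kinv, vc, solver_tol)

    rows = []
    for fold in assign_folds(records):
        fit = solve_mme(
            build_design(fold.training_records, Kinv.ids), Kinv, vc, solver_tol
        )
        adj, _ = adjust_phenotypes(
            fold.test_records, whole_fit if whole_fit is not None else fit
        )
        usable = [a for a in fold.test_ids if a in adj.index]
        if len(usable) < min_test_animals:
            logger.warning(
                "fold %s skipped: only %d usable test animals", fold.label, len(usable)
            )
            continue
        ebv = fit.ebv.loc[usable].to_numpy()
        adj_vals = adj.loc[usable].to_numpy()
        corr = float(np.corrcoef(ebv, adj_vals)[0, 1])
        denom = math.sqrt(h2 / (rep + (1.0 - rep) / fold.n_lactations))
        rows.append(
            {
                "fold": fold.label,
                "n_lactations": fold.n_lactations,
                "n_test": len(usable),
                "corr": corr,
                "denominator": denom,
                "accuracy": accuracy(corr, h2, rep, fold.n_lactations),
                "slope": bias_slope(adj_vals, ebv),
            }
        )
    folds = pd.DataFrame(
        rows,
        columns=[
            "fold",
            "n_lactations",
            "n_test",
            "corr",
            "denominator",
            "accuracy",
            "slope",
        ],
    )
    acc = folds["accuracy"].to_numpy(dtype=float)
    slo = folds["slope"].to_numpy(dtype=float)
    return EvaluationReport(
        method=method,
        trait=trait,
        folds=folds,
        accuracy_mean=float(np.mean(acc)) if len(acc) else float("nan"),
        accuracy_sd=float(np.std(acc, ddof=1)) if len(acc) > 1 else float("nan"),
        slope_mean=float(np.nanmean(slo)) if len(slo) else float("nan"),
        slope_sd=float(np.nanstd(slo, ddof=1)) if len(slo) > 1 else float("nan"),
    )


def combine_reports(reports: list[EvaluationReport]) -> pd.DataFrame:
    """Wide summary: one row per trait, method-prefixed accuracy/slope columns."""
    rows: dict[str, dict[str, float]] = {}
    for rep in reports:
        row = rows.setdefault(rep.trait, {"trait": rep.trait})
        row[f"{rep.method}_accuracy"] = rep.accuracy_mean
        row[f"{rep.method}_accuracy_sd"] = rep.accuracy_sd
        row[f"{rep.method}_slope"] = rep.slope_mean
        row[f"{rep.method}_slope_sd"] = rep.slope_sd
    return pd.DataFrame(list(rows.values()))
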