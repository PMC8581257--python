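"""Glue from raw inputs to a fitted evaluation or a cross-validation report."""

from __future__ import annotations

import logging

import numpy as np
from scipy import linalg

from .genotypes import GenotypeSet, build_grm, impute_missing, qc_filter
from .io import RunConfig
from .model import VarianceComponents, build_design, solve_mme
from .pedigree import PedigreeTable, build_a_inverse, build_a_matrix, extract_a22
from .relmat import RelationshipMatrix
from .single_step import build_h_inverse
from .validation import EvaluationReport, run_cross_validation

logger = logging.getLogger(__name__)


def invert_pd(rel: RelationshipMatrix, kind: str) -> RelationshipMatrix:
    try:
        c, low = linalg.cho_factor(rel.values, check_finite=False)
    except linalg.LinAlgError as exc:
        raise ValueError(f"{rel.kind} matrix is not positive definite") from exc
    inv = linalg.cho_solve((c, low), np.eye(rel.n), check_finite=False)
    return RelationshipMatrix((inv + inv.T) / 2.0, rel.ids, kind)


def prepare_genotypes(geno: GenotypeSet, cfg: RunConfig) -> GenotypeSet:
    """QC then mean-imputation, per the configured thresholds."""
    filtered, report = qc_filter(
        geno,
        maf_min=cfg.maf_min,
        hwe_p_min=cfg.hwe_p_min,
        autosomes=cfg.autosome_range,
    )
    if filtered.n_snps == 0:
        raise ValueError("no SNPs survived quality control")
    logger.info("QC: %d -> %d SNPs", report.snps_in, report.snps_out)
    return impute_missing(filtered)


def build_kinv(
    method: str,
    cfg: RunConfig,
    ped: PedigreeTable | None = None,
    geno: GenotypeSet | None = None,
) -> RelationshipMatrix:
    """Relationship-matrix inverse for the requested method.

    pblup: A⁻¹ over the full pedigree. gblup: blended G⁻¹ over the genotyped
    animals (anchored to their A22 when a pedigree is supplied). ssgblup: the
    single-step H⁻¹ over the full pedigree.
    """
    if method == "pblup":
        if ped is None:
            raise ValueError("pblup needs a pedigree")
        return build_a_inverse(ped)

    if geno is None:
        raise ValueError(f"{method} needs genotypes")
    clean = prepare_genotypes(geno, cfg)

    if method == "gblup":
        A22 = None
        if ped is None:
            logger.info("gblup without pedigree: blending G toward identity")
        else:
            A22 = extract_a22(build_a_matrix(ped), clean.ids)
        G = build_grm(clean, blend_weight=cfg.grm_blend, A22=A22)
        return invert_pd(G, "G_inverse")

    if method == "ssgblup":
        if ped is None:
            raise ValueError("ssgblup needs a pedigree")
        missing = sorted(set(clean.ids) - set(ped.ids))
        if missing:
            raise ValueError(
                f"genotyped animals absent from pedigree: {missing[:10]}"
            )
        A = build_a_matrix(ped)
        Ainv = build_a_inverse(ped)
        A22 = extract_a22(A, clean.ids)
        G = build_grm(clean, blend_weight=cfg.grm_blend, A22=A22)
        return build_h_inverse(
            Ainv, G, A22, clean.ids, tau=cfg.tau, omega=cfg.omega
        )

    raise ValueError(f"unknown method {method!r}")


def evaluate(records, method: str, cfg: RunConfig, ped=None, geno=None):
    """Fit the repeatability model once on all records; returns the solution."""
    Kinv = build_kinv(method, cfg, ped=ped, geno=geno)
    vc = VarianceComponents.from_ratios(cfg.h2, cfg.repeatability)
    design = build_design(records, Kinv.ids)
    return solve_mme(design, Kinv, vc, tol=cfg.solver_tol)


def crossvalidate(
    records, method: str, cfg: RunConfig, ped=None, geno=None
) -> EvaluationReport:
    """Threefold lactation-count cross-validation for one method."""
    Kinv = build_kinv(method, cfg, ped=ped, geno=geno)
    if method == "gblup":
        known = set(Kinv.ids)
        outside = sorted({r.animal_id for r in records} - known)
        if outside:
            raise ValueError(
                "gblup requires every recorded animal to be genotyped; "
                f"ungenotyped: {outside[:10]}"
            )
    vc = VarianceComponents.from_ratios(cfg.h2, cfg.repeatability)
    return run_cross_validation(
        records,
        Kinv,
        vc,
        method=method,
        trait=cfg.trait,
        adjust_with=cfg.adjust_with,
        solver_tol=cfg.solver_tol,
    )
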