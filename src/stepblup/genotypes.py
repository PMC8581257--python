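"""SNP quality control and the genomic relationship matrix.

QC removes, in fixed order, SNPs with no genome location, SNPs outside the
configured autosome set, monomorphic SNPs, SNPs below the minor-allele
frequency threshold, and SNPs failing a chi-square Hardy-Weinberg test.
The genomic relationship matrix follows the observed-frequency centred
cross-product construction (VanRaden method 1), optionally blended toward the
pedigree block A22 for guaranteed invertibility.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .relmat import RelationshipMatrix

logger = logging.getLogger(__name__)

MAP_COLUMNS = ["snp_id", "chromosome", "position"]


@dataclass
class GenotypeSet:
    """Animal × SNP dosage matrix with per-SNP map metadata.

    ``dosages`` holds 0/1/2 allele counts as floats with ``NaN`` for missing.
    ``snp_map`` has columns snp_id, chromosome, position; a missing chromosome
    or position is ``NaN`` (an unplaced SNP).
    """

    dosages: np.ndarray
    ids: list[str]
    snp_map: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.ids = [str(i) for i in self.ids]
        self.snp_map = self.snp_map.reset_index(drop=True)
        n, m = self.dosages.shape
        if n != len(self.ids):
            raise ValueError("row count does not match number of animal ids")
        if m != len(self.snp_map):
            raise ValueError("column count does not match map length")
        if list(self.snp_map.columns[:3]) != MAP_COLUMNS:
            raise ValueError(f"snp_map must have columns {MAP_COLUMNS}")
        if self.snp_map["snp_id"].duplicated().any():
            dupes = self.snp_map.loc[
                self.snp_map["snp_id"].duplicated(), "snp_id"
            ].tolist()
            raise ValueError(f"duplicate snp ids: {dupes}")
        vals = self.dosages[~np.isnan(self.dosages)]
        if vals.size and not np.isin(vals, (0.0, 1.0, 2.0)).all():
            bad = np.unique(vals[~np.isin(vals, (0.0, 1.0, 2.0))])
            raise ValueError(f"dosages must be 0/1/2/NA; found {bad}")

    @property
    def n_animals(self) -> int:
        return len(self.ids)

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def select_snps(self, keep: np.ndarray) -> "GenotypeSet":
        return GenotypeSet(
            self.dosages[:, keep], self.ids, self.snp_map.loc[keep, MAP_COLUMNS]
        )

    def select_animals(self, animal_ids) -> "GenotypeSet":
        index = {a: i for i, a in enumerate(self.ids)}
        missing = [str(a) for a in animal_ids if str(a) not in index]
        if missing:
            raise KeyError(f"animals not in genotype set: {missing}")
        rows = [index[str(a)] for a in animal_ids]
        return GenotypeSet(
            self.dosages[rows], [str(a) for a in animal_ids], self.snp_map
        )


@dataclass
class QcReport:
    """Per-filter SNP removal accounting (first failing filter wins)."""

    snps_in: int = 0
    no_location: int = 0
    non_autosomal: int = 0
    monomorphic: int = 0
    maf: int = 0
    hwe: int = 0
    snps_out: int = 0

    FILTERS = ("no_location", "non_autosomal", "monomorphic", "maf", "hwe")

    def total_removed(self) -> int:
        return sum(getattr(self, f) for f in self.FILTERS)

    def to_frame(self) -> pd.DataFrame:
        rows = [("snps_in", self.snps_in)]
        rows += [(f, getattr(self, f)) for f in self.FILTERS]
        rows.append(("snps_out", self.snps_out))
        return pd.DataFrame(rows, columns=["filter", "count"])


def allele_frequency(dosage_column: np.ndarray) -> float:
    """Frequency p of the counted allele: sum of dosages over 2·(non-missing)."""
    col = np.asarray(dosage_column, dtype=float)
    ok = ~np.isnan(col)
    if not ok.any():
        raise ValueError("allele frequency undefined: all dosages missing")
    return float(col[ok].sum() / (2.0 * ok.sum()))


def minor_allele_frequency(dosage_column: np.ndarray) -> float:
    p = allele_frequency(dosage_column)
    return min(p, 1.0 - p)


def hwe_test(genotype_counts: tuple[int, int, int]) -> float:
    """One-df chi-square Hardy-Weinberg goodness-of-fit p-value.

    ``genotype_counts`` are the (n_AA, n_Aa, n_aa) counts; expected counts are
    (p², 2pq, q²)·n at the observed allele frequency. A monomorphic SNP
    returns 1.0 (no test possible).
    """
    n_aa, n_ab, n_bb = (int(c) for c in genotype_counts)
    n = n_aa + n_ab + n_bb
    if n <= 0:
        raise ValueError("HWE test requires a positive genotype count")
    p = (2 * n_aa + n_ab) / (2 * n)
    q = 1.0 - p
    if p == 0.0 or q == 0.0:
        return 1.0
    expected = np.array([p * p, 2 * p * q, q * q]) * n
    observed = np.array([n_aa, n_ab, n_bb], dtype=float)
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    return float(stats.chi2.sf(chi2, df=1))


def _genotype_counts(col: np.ndarray) -> tuple[int, int, int]:
    ok = col[~np.isnan(col)]
    return int((ok == 0).sum()), int((ok == 1).sum()), int((ok == 2).sum())


def qc_filter(
    geno: GenotypeSet,
    maf_min: float = 0.05,
    hwe_p_min: float = 1e-15,
    autosomes: range | tuple = range(1, 30),
) -> tuple[GenotypeSet, QcReport]:
    """Apply the SNP filters in fixed order and account for each removal once.

    Order: (1) no genome location, (2) chromosome outside ``autosomes``,
    (3) monomorphic, (4) MAF below ``maf_min``, (5) HWE p below ``hwe_p_min``.
    """
    report = QcReport(snps_in=geno.n_snps)
    autoset = set(int(c) for c in autosomes)
    chrom = geno.snp_map["chromosome"].to_numpy(dtype=float)
    pos = geno.snp_map["position"].to_numpy(dtype=float)
    keep = np.ones(geno.n_snps, dtype=bool)
    for j in range(geno.n_snps):
        col = geno.dosages[:, j]
        if np.isnan(chrom[j]) or np.isnan(pos[j]):
            report.no_location += 1
        elif int(chrom[j]) not in autoset:
            report.non_autosomal += 1
        elif np.isnan(col).all() or minor_allele_frequency(col) == 0.0:
            report.monomorphic += 1
        elif minor_allele_frequency(col) < maf_min:
            report.maf += 1
        elif hwe_test(_genotype_counts(col)) < hwe_p_min:
            report.hwe += 1
        else:
            continue
        keep[j] = False
    report.snps_out = int(keep.sum())
    out = geno.select_snps(keep)
    for f in QcReport.FILTERS:
        count = getattr(report, f)
        if count:
            logger.info("qc removed %d SNPs under filter %s", count, f)
    logger.info("qc kept %d of %d SNPs", report.snps_out, report.snps_in)
    return out, report


def impute_missing(geno: GenotypeSet) -> GenotypeSet:
    """Replace missing dosages with the SNP mean (= 2p) of non-missing calls."""
    dos = geno.dosages
    if not np.isnan(dos).any():
        return geno
    dos = dos.copy()
    col_mean = np.nanmean(dos, axis=0)
    missing = np.isnan(dos)
    dos[missing] = np.broadcast_to(col_mean, dos.shape)[missing]
    return GenotypeSet(dos, geno.ids, geno.snp_map)


def build_grm(
    geno: GenotypeSet,
    blend_weight: float = 0.05,
    A22: RelationshipMatrix | None = None,
) -> RelationshipMatrix:
    """Genomic relationship matrix from centred dosages.

    ``G_raw = ZZ' / (2·Σ p(1−p))`` with ``Z`` the dosage matrix centred by
    twice the observed allele frequencies. The returned matrix is
    ``(1−β)·G_raw + β·A22`` (identity if ``A22`` is None), β = blend_weight.
    """
    if not 0.0 <= blend_weight <= 1.0:
        raise ValueError("blend_weight must be in [0, 1]")
    M = geno.dosages
    if np.isnan(M).any():
        raise ValueError("genotypes contain missing dosages; impute first")
    if geno.n_snps < 1:
        raise ValueError("need at least one SNP to build G")
    p = M.mean(axis=0) / 2.0
    denom = 2.0 * float((p * (1.0 - p)).sum())
    if denom <= 0.0:
        raise ValueError("all SNPs monomorphic: G denominator is zero")
    Z = M - 2.0 * p
    G = (Z @ Z.T) / denom
    if blend_weight > 0.0:
        if A22 is not None:
            if A22.ids != geno.ids:
                raise ValueError("A22 id order does not match genotype set")
            anchor = A22.values
        else:
            anchor = np.eye(geno.n_animals)
        G = (1.0 - blend_weight) * G + blend_weight * anchor
    return RelationshipMatrix(G, geno.ids, "G")
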