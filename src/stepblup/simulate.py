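"""Synthetic dairy-herd generator with known truth.

Produces a multi-generation pedigree with breed and herd structure, gene-
dropped SNP genotypes, and repeated 305-day lactation records built from an
additive genetic value, a permanent-environment effect and record-level
noise — so every pipeline stage can be exercised against known breeding
values and variance components.

Calibration defaults target a herd of ~2,642 pedigree animals over six
generations, ~1,975 recorded cows of which ~46% are genotyped, 29 autosomes
of biallelic SNPs, and a milk-yield mean/sd of 1,573.2/505.9 kg.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .genotypes import GenotypeSet
from .io import LactationRecord
from .model import VarianceComponents
from .pedigree import PedigreeTable

logger = logging.getLogger(__name__)


@dataclass
class SimConfig:
    """Knobs of the herd generator; every value is an assumption, not an estimate."""

    n_animals: int = 2642
    n_generations: int = 6
    n_herds: int = 12
    male_fraction: float = 0.10
    founder_breed_probs: dict = field(
        default_factory=lambda: {"BUL": 0.60, "BRA": 0.25, "AME": 0.15}
    )
    # additive shift per breed class, as a fraction of the trait mean
    breed_effect_frac: dict = field(
        default_factory=lambda: {
            "BUL": 0.0,
            "BRA": -0.05,
            "AME": 0.05,
            "XBRA": -0.02,
            "XAME": 0.02,
        }
    )
    lactation_effect_frac: tuple = (0.0, 0.08, 0.10)
    hys_sd_frac: float = 0.15
    n_year_seasons: int = 6

    n_autosomes: int = 29
    n_snps: int = 5000
    frac_no_location: float = 0.05
    frac_non_autosomal: float = 0.02
    frac_low_maf: float = 0.05
    frac_hwe_violation: float = 0.02
    missing_dosage_fraction: float = 0.0

    trait: str = "MY"
    mean_target: float = 1573.2
    sd_target: float = 505.9
    h2: float = 0.19
    repeatability: float = 0.40
    records_p: tuple = (0.35, 0.33, 0.32)
    n_phenotyped: int | None = 1975
    genotyped_fraction: float = 904 / 1975

    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_generations < 1 or self.n_animals < 2:
            raise ValueError("need at least one generation of at least two animals")
        if not 0 < self.genotyped_fraction <= 1:
            raise ValueError("genotyped_fraction must be in (0, 1]")
        if self.sd_target <= 0 or self.mean_target <= 0:
            raise ValueError("mean/sd targets must be positive")
        if abs(sum(self.records_p) - 1.0) > 1e-9:
            raise ValueError("records_p must sum to 1")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class TruthSet:
    """Ground truth behind one simulated data set."""

    tbv: pd.Series
    snp_effects: np.ndarray
    vc: VarianceComponents
    mu: float
    breed_effects: dict
    lactation_effects: dict
    hys_effects: dict


@dataclass
class SimulatedData:
    """Everything one replicate produces."""

    pedigree: PedigreeTable
    meta: pd.DataFrame  # animal_id, generation, sex, breed, herd
    genotypes: GenotypeSet  # every pedigree animal (simulation truth)
    records: list[LactationRecord]
    truth: TruthSet
    phenotyped_ids: list[str]
    genotyped_ids: list[str]  # the revealed subset

    def revealed_genotypes(self) -> GenotypeSet:
        return self.genotypes.select_animals(self.genotyped_ids)


def _offspring_breed(dam_breed: str) -> str:
    # sires are always BUL; crosses keep their dam-side cross class
    return {"BUL": "BUL", "BRA": "XBRA", "AME": "XAME", "XBRA": "XBRA", "XAME": "XAME"}[
        dam_breed
    ]


def simulate_pedigree(
    cfg: SimConfig, rng: np.random.Generator
) -> tuple[PedigreeTable, pd.DataFrame]:
    """Discrete-generation pedigree with herd/breed labels.

    Founder sires are all BUL and sires are reused across herds in every
    generation, linking the herds. Returns the pedigree and a per-animal
    metadata frame (generation, sex, breed, herd).
    """
    gen_size = max(2, round(cfg.n_animals / cfg.n_generations))
    breeds = list(cfg.founder_breed_probs)
    probs = np.array(list(cfg.founder_breed_probs.values()), dtype=float)
    probs = probs / probs.sum()

    rows = []  # (animal, sire, dam)
    meta = []  # dicts
    counter = 0

    def new_id() -> str:
        nonlocal counter
        counter += 1
        return f"A{counter:06d}"

    generation: list[list[dict]] = []
    founders = []
    n_males = max(2, round(cfg.male_fraction * gen_size))
    for i in range(gen_size):
        male = i < n_males
        info = {
            "animal_id": new_id(),
            "generation": 0,
            "sex": "M" if male else "F",
            "breed": "BUL" if male else str(rng.choice(breeds, p=probs)),
            "herd": int(rng.integers(1, cfg.n_herds + 1)),
        }
        rows.append((info["animal_id"], "0", "0"))
        meta.append(info)
        founders.append(info)
    generation.append(founders)

    for g in range(1, cfg.n_generations):
        prev = generation[-1]
        sires = [a for a in prev if a["sex"] == "M" and a["breed"] == "BUL"]
        if not sires:
            sires = [a for a in prev if a["sex"] == "M"]
        dams = [a for a in prev if a["sex"] == "F"]
        if not sires or not dams:
            raise RuntimeError("generation ran out of sires or dams")
        n_off = gen_size if g < cfg.n_generations - 1 else max(
            2, cfg.n_animals - counter
        )
        current = []
        sire_pick = rng.integers(0, len(sires), size=n_off)
        dam_pick = rng.integers(0, len(dams), size=n_off)
        sex_draw = rng.random(n_off) < cfg.male_fraction
        for k in range(n_off):
            sire, dam = sires[sire_pick[k]], dams[dam_pick[k]]
            info = {
                "animal_id": new_id(),
                "generation": g,
                "sex": "M" if sex_draw[k] else "F",
                "breed": _offspring_breed(dam["breed"]),
                "herd": dam["herd"],
            }
            rows.append((info["animal_id"], sire["animal_id"], dam["animal_id"]))
            meta.append(info)
            current.append(info)
        generation.append(current)

    ped = PedigreeTable.from_records(rows)
    meta_df = pd.DataFrame(meta).set_index("animal_id").loc[ped.ids].reset_index()
    return ped, meta_df


def simulate_genotypes(
    ped: PedigreeTable, cfg: SimConfig, rng: np.random.Generator
) -> tuple[GenotypeSet, np.ndarray]:
    """Gene-dropped biallelic genotypes for every pedigree animal.

    Founder haplotypes are drawn from per-SNP Beta(2,2) frequencies; each
    offspring receives one allele per parent per locus; an unknown parent
    contributes a fresh founder gamete. Configured fractions of SNPs are
    engineered to fail each QC rule. Returns the genotype set and a boolean
    mask of the clean (causal-eligible) SNPs.
    """
    n, m = ped.n, cfg.n_snps
    freqs = rng.beta(2.0, 2.0, size=m)

    n_loc = round(cfg.frac_no_location * m)
    n_auto = round(cfg.frac_non_autosomal * m)
    n_maf = round(cfg.frac_low_maf * m)
    n_hwe = round(cfg.frac_hwe_violation * m)
    flagged = rng.permutation(m)
    s_loc = flagged[:n_loc]
    s_auto = flagged[n_loc : n_loc + n_auto]
    s_maf = flagged[n_loc + n_auto : n_loc + n_auto + n_maf]
    s_hwe = flagged[n_loc + n_auto + n_maf : n_loc + n_auto + n_maf + n_hwe]
    freqs[s_maf] = rng.uniform(0.001, 0.02, size=n_maf)

    haps = np.zeros((n, 2, m), dtype=np.uint8)
    cols = np.arange(m)
    for i in range(n):
        s, d = ped.sire_idx[i], ped.dam_idx[i]
        for h, parent in enumerate((s, d)):
            if parent < 0:
                haps[i, h] = rng.random(m) < freqs
            else:
                haps[i, h] = haps[parent, rng.integers(0, 2, size=m), cols]
    dosages = haps.sum(axis=1).astype(float)

    if n_hwe:
        # heterozygote-free columns: maximal HWE violation at moderate MAF
        dosages[:, s_hwe] = 2.0 * (rng.random((n, n_hwe)) < 0.5)

    chrom = rng.integers(1, cfg.n_autosomes + 1, size=m).astype(float)
    position = rng.integers(1, 120_000_000, size=m).astype(float)
    chrom[s_auto] = cfg.n_autosomes + 1
    chrom[s_loc] = np.nan
    position[s_loc] = np.nan

    if cfg.missing_dosage_fraction > 0:
        mask = rng.random(dosages.shape) < cfg.missing_dosage_fraction
        dosages[mask] = np.nan

    clean = np.ones(m, dtype=bool)
    clean[np.concatenate([s_loc, s_auto, s_maf, s_hwe])] = False

    snp_map = pd.DataFrame(
        {
            "snp_id": [f"snp{j + 1:06d}" for j in range(m)],
            "chromosome": chrom,
            "position": position,
        }
    )
    return GenotypeSet(dosages, ped.ids, snp_map), clean


def simulate_phenotypes(
    ped: PedigreeTable,
    meta: pd.DataFrame,
    geno: GenotypeSet,
    cfg: SimConfig,
    rng: np.random.Generator,
    clean_snps: np.ndarray | None = None,
) -> tuple[list[LactationRecord], TruthSet, list[str]]:
    """Repeated lactation records with known breeding values.

    True breeding values are sums of SNP effects over the clean SNPs, scaled
    so the additive variance matches the configured h² of the non-fixed part
    of the phenotypic variance; fixed effects (breed, lactation number, HYS)
    are added on top and centred so the record mean hits the target.
    """
    if geno.ids != ped.ids:
        raise ValueError("genotypes must cover every pedigree animal, in order")
    m = geno.n_snps
    clean = np.ones(m, dtype=bool) if clean_snps is None else clean_snps

    cows = meta[(meta["sex"] == "F") & (meta["generation"] > 0)]
    cow_ids = cows["animal_id"].tolist()
    if cfg.n_phenotyped is not None and cfg.n_phenotyped < len(cow_ids):
        cow_ids = sorted(
            rng.choice(cow_ids, size=cfg.n_phenotyped, replace=False).tolist()
        )
    if not cow_ids:
        raise RuntimeError("no eligible cows to phenotype")
    cow_meta = meta.set_index("animal_id").loc[cow_ids]

    # record skeleton: per cow, 1-3 distinct lactation numbers, herd-linked HYS
    n_rec_per_cow = rng.choice([1, 2, 3], size=len(cow_ids), p=list(cfg.records_p))
    skeleton = []
    for cow, n_rec in zip(cow_ids, n_rec_per_cow):
        lacts = sorted(rng.choice([1, 2, 3], size=n_rec, replace=False).tolist())
        herd = cow_meta.loc[cow, "herd"]
        for lact in lacts:
            ys = int(rng.integers(1, cfg.n_year_seasons + 1))
            skeleton.append((cow, int(lact), f"H{herd:02d}_S{ys}"))
    rec_df = pd.DataFrame(skeleton, columns=["animal_id", "lactation_number", "hys"])
    rec_df["breed"] = cow_meta.loc[rec_df["animal_id"], "breed"].to_numpy()

    mean, sd = cfg.mean_target, cfg.sd_target
    breed_eff = {b: f * mean for b, f in cfg.breed_effect_frac.items()}
    lact_eff = {i + 1: f * mean for i, f in enumerate(cfg.lactation_effect_frac)}
    hys_levels = sorted(rec_df["hys"].unique())
    hys_eff = {
        h: float(rng.normal(0.0, cfg.hys_sd_frac * mean)) for h in hys_levels
    }
    fixed_part = (
        rec_df["breed"].map(breed_eff).to_numpy()
        + rec_df["lactation_number"].map(lact_eff).to_numpy()
        + rec_df["hys"].map(hys_eff).to_numpy()
    )
    fixed_part = fixed_part - fixed_part.mean()

    # back-solve the random variances from the target phenotypic sd
    var_fixed = float(np.var(fixed_part))
    sigma2_p = max(sd**2 - var_fixed, 0.3 * sd**2)
    vc = VarianceComponents.from_ratios(cfg.h2, cfg.repeatability, sigma2_p)

    founder_rows = [i for i in range(ped.n) if ped.is_founder(i)]
    dos = geno.dosages
    if np.isnan(dos).any():
        dos = np.where(np.isnan(dos), 0.0, dos)  # truth uses pre-missingness calls
    p_founder = dos[founder_rows][:, clean].mean(axis=0) / 2.0
    het = float((p_founder * (1.0 - p_founder)).sum())
    if het <= 0:
        raise RuntimeError("no segregating clean SNPs; cannot place genetic effects")
    effects = np.zeros(m)
    if vc.sigma2_a > 0:
        effects[clean] = rng.normal(
            0.0, np.sqrt(vc.sigma2_a / (2.0 * het)), size=int(clean.sum())
        )
    centered = dos[:, clean] - 2.0 * p_founder
    tbv = pd.Series(centered @ effects[clean], index=ped.ids, name="tbv")

    pe = pd.Series(
        rng.normal(0.0, np.sqrt(vc.sigma2_pe), size=len(cow_ids)), index=cow_ids
    )
    resid = rng.normal(0.0, np.sqrt(vc.sigma2_e), size=len(rec_df))
    mu = mean
    y = (
        mu
        + fixed_part
        + tbv.loc[rec_df["animal_id"]].to_numpy()
        + pe.loc[rec_df["animal_id"]].to_numpy()
        + resid
    )
    if (y <= 0).any():
        y = np.clip(y, 1.0, None)  # yields must stay positive at desk scale

    records = [
        LactationRecord(
            animal_id=str(row.animal_id),
            breed=str(row.breed),
            lactation_number=int(row.lactation_number),
            hys=str(row.hys),
            yield_305d=float(val),
            trait=cfg.trait,
        )
        for row, val in zip(rec_df.itertuples(index=False), y)
    ]
    truth = TruthSet(
        tbv=tbv,
        snp_effects=effects,
        vc=vc,
        mu=mu,
        breed_effects=breed_eff,
        lactation_effects=lact_eff,
        hys_effects=hys_eff,
    )
    return records, truth, cow_ids


def simulate_dataset(cfg: SimConfig, seed: int | None = None) -> SimulatedData:
    """One full replicate: pedigree, genotypes, phenotypes, revealed subset."""
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    ped, meta = simulate_pedigree(cfg, rng)
    geno, clean = simulate_genotypes(ped, cfg, rng)
    records, truth, cow_ids = simulate_phenotypes(ped, meta, geno, cfg, rng, clean)
    n_geno = max(1, round(cfg.genotyped_fraction * len(cow_ids)))
    genotyped = sorted(rng.choice(cow_ids, size=n_geno, replace=False).tolist())
    logger.info(
        "simulated %d animals, %d cows with %d records, %d genotyped",
        ped.n,
        len(cow_ids),
        len(records),
        len(genotyped),
    )
    return SimulatedData(
        pedigree=ped,
        meta=meta,
        genotypes=geno,
        records=records,
        truth=truth,
        phenotyped_ids=cow_ids,
        genotyped_ids=genotyped,
    )
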