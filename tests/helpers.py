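"""Shared test utilities: independent oracles and fixture builders.

The GLS/BLUP oracle here deliberately avoids the mixed-model-equation path in
the package: it predicts breeding values through the dense phenotypic
covariance matrix V, so it can arbitrate the MME solver.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

import stepblup as sb
from stepblup.model import Design, VarianceComponents


def gls_ebv(design: Design, K: np.ndarray, vc: VarianceComponents) -> np.ndarray:
    """BLUP via dense V inversion: u = sigma2_a * K * Za' * Vinv * (y - X*beta_gls)."""
    y = design.y
    X = design.X
    Za = design.Z_a.toarray()
    Zpe = design.Z_pe.toarray()
    V = (
        vc.sigma2_a * Za @ K @ Za.T
        + vc.sigma2_pe * Zpe @ Zpe.T
        + vc.sigma2_e * np.eye(len(y))
    )
    Vinv = np.linalg.inv(V)
    XtVinv = X.T @ Vinv
    beta, *_ = np.linalg.lstsq(XtVinv @ X, XtVinv @ y, rcond=None)
    return vc.sigma2_a * K @ Za.T @ Vinv @ (y - X @ beta)


def random_pedigree(rng: np.random.Generator, n: int) -> sb.PedigreeTable:
    """Random acyclic pedigree: each animal's parents (if any) come earlier."""
    rows = []
    for i in range(n):
        if i < 4 or rng.random() < 0.2:
            rows.append((str(i + 1), "0", "0"))
        else:
            s = str(int(rng.integers(1, i + 1)))
            d = str(int(rng.integers(1, i + 1)))
            if s == d:
                d = "0"
            if rng.random() < 0.1:
                s = "0"
            rows.append((str(i + 1), s, d))
    return sb.PedigreeTable.from_records(rows)


def random_records(
    rng: np.random.Generator, animal_ids, n_breeds=2, n_hys=3, mean=100.0, sd=10.0
) -> list:
    """1-3 records per animal with small random fixed-effect structure."""
    records = []
    for a in animal_ids:
        n_rec = int(rng.integers(1, 4))
        lacts = sorted(rng.choice([1, 2, 3], size=n_rec, replace=False).tolist())
        breed = f"B{int(rng.integers(1, n_breeds + 1))}"
        for lact in lacts:
            records.append(
                sb.LactationRecord(
                    animal_id=str(a),
                    breed=breed,
                    lactation_number=int(lact),
                    hys=f"H{int(rng.integers(1, n_hys + 1))}",
                    yield_305d=float(max(1.0, rng.normal(mean, sd))),
                )
            )
    return records


def random_kinship(
    rng: np.random.Generator, ped: sb.PedigreeTable, kind: str
) -> tuple[sb.RelationshipMatrix, np.ndarray]:
    """(Kinv, K) pair of the requested relationship flavour for ``ped``."""
    if kind == "A":
        A = sb.build_a_matrix(ped)
        Kinv = sb.build_a_inverse(ped)
        return Kinv, A.values
    if kind == "G":
        dos = rng.integers(0, 3, size=(ped.n, 300)).astype(float)
        snp_map = pd.DataFrame(
            {
                "snp_id": [f"s{j}" for j in range(300)],
                "chromosome": np.ones(300),
                "position": np.arange(1, 301, dtype=float),
            }
        )
        geno = sb.GenotypeSet(dos, ped.ids, snp_map)
        G = sb.build_grm(geno, blend_weight=0.10)
        K = G.values
        Kinv = sb.RelationshipMatrix(np.linalg.inv(K), ped.ids, "G_inverse")
        return Kinv, K
    if kind == "H":
        A = sb.build_a_matrix(ped)
        Ainv = sb.build_a_inverse(ped)
        n_gen = max(2, ped.n // 3)
        genotyped = [str(i) for i in rng.choice(ped.ids, size=n_gen, replace=False)]
        A22 = sb.extract_a22(A, genotyped)
        # a perturbed, PD "genomic" matrix anchored on A22
        noise = rng.normal(0.0, 0.05, size=(n_gen, n_gen))
        G = sb.RelationshipMatrix(
            0.8 * A22.values + 0.2 * np.eye(n_gen) + 0.5 * (noise + noise.T), A22.ids, "G"
        )
        Hinv = sb.build_h_inverse(Ainv, G, A22, genotyped)
        K = np.linalg.inv(Hinv.values)
        return Hinv, K
    raise ValueError(kind)


def qc_fixture() -> tuple[sb.GenotypeSet, dict]:
    """100 animals x 10 SNPs with hand-tallied QC outcomes.

    snp01 missing chromosome, snp02 missing position (no_location);
    snp03 on chromosome 30 (non_autosomal); snp04-06 MAF 0.025 (maf);
    snp07 no heterozygotes at p=0.5 (chi-square 100, hwe);
    snp08-10 exact HWE proportions at p=0.5 (clean).
    """
    n = 100
    dos = np.zeros((n, 10))
    hwe_ok = np.concatenate([np.zeros(25), np.ones(50), 2 * np.ones(25)])
    for j in (0, 1, 2, 7, 8, 9):
        dos[:, j] = hwe_ok
    for j in (3, 4, 5):  # five het carriers -> allele count 5/200
        dos[:5, j] = 1.0
    dos[:50, 6] = 0.0
    dos[50:, 6] = 2.0
    snp_map = pd.DataFrame(
        {
            "snp_id": [f"snp{j + 1:02d}" for j in range(10)],
            "chromosome": [np.nan, 5.0, 30.0, 1, 2, 3, 4, 5, 6, 7],
            "position": [100.0, np.nan, 100, 100, 100, 100, 100, 100, 100, 100],
        }
    )
    geno = sb.GenotypeSet(dos, [f"a{i}" for i in range(n)], snp_map)
    expected = {
        "no_location": 2,
        "non_autosomal": 1,
        "monomorphic": 0,
        "maf": 3,
        "hwe": 1,
        "snps_out": 3,
    }
    return geno, expected


def directional_replicate(seed: int, n_phenotyped=2000, n_snps=5000):
    """One simulation replicate evaluated four ways (the two-dataset design).

    Returns mean cross-validated accuracies for pBLUP and ssGBLUP on the full
    data and pBLUP and GBLUP on the genotyped subset, reusing the pedigree
    matrices across methods.
    """
    from stepblup.pipeline import invert_pd, prepare_genotypes

    cfg = sb.SimConfig(
        n_animals=2642,
        n_generations=6,
        n_snps=n_snps,
        n_phenotyped=n_phenotyped,
        genotyped_fraction=0.46,
        h2=0.19,
        repeatability=0.40,
        seed=seed,
    )
    data = sb.simulate_dataset(cfg)
    rc = sb.RunConfig(trait="MY", h2=0.19, repeatability=0.40)
    vc = VarianceComponents.from_ratios(0.19, 0.40)

    ped = data.pedigree
    A = sb.build_a_matrix(ped)
    Ainv = sb.build_a_inverse(ped)
    clean = prepare_genotypes(data.revealed_genotypes(), rc)
    A22 = sb.extract_a22(A, clean.ids)
    G = sb.build_grm(clean, blend_weight=rc.grm_blend, A22=A22)
    Ginv = invert_pd(G, "G_inverse")
    Hinv = sb.build_h_inverse(Ainv, G, A22, clean.ids)

    gset = set(data.genotyped_ids)
    geno_records = [r for r in data.records if r.animal_id in gset]

    out = {}
    out["pblup_all"] = sb.run_cross_validation(
        data.records, Ainv, vc, method="pblup"
    ).accuracy_mean
    out["ssgblup"] = sb.run_cross_validation(
        data.records, Hinv, vc, method="ssgblup"
    ).accuracy_mean
    out["pblup_geno"] = sb.run_cross_validation(
        geno_records, Ainv, vc, method="pblup"
    ).accuracy_mean
    out["gblup"] = sb.run_cross_validation(
        geno_records, Ginv, vc, method="gblup"
    ).accuracy_mean
    out["truth"] = data.truth
    out["data"] = data
    return out
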