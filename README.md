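# stepblup

Genetic evaluation of repeated 305-day lactation records with three
relationship structures — pedigree BLUP (**pBLUP**), genomic BLUP (**GBLUP**)
and single-step GBLUP (**ssGBLUP**) — plus the SNP quality control,
lactation-count cross-validation, and accuracy / dispersion-bias statistics
used to compare them. A synthetic dairy-herd generator with known true
breeding values makes the whole pipeline testable end to end.

## What it does

* **Pedigree kinship** — numerator relationship matrix `A` by the tabular
  method, its inverse by Henderson's rules with inbreeding, and the
  genotyped-subset block `A22`.
* **Genomic kinship** — SNP QC (genome location, autosome set 1–29,
  MAF < 0.05, Hardy-Weinberg chi-square p < 1e-15), mean imputation, and the
  observed-frequency centred GRM (`ZZ'/2Σp(1−p)`), blended toward `A22` for
  invertibility.
* **Single-step** — `H⁻¹ = A⁻¹ + [0, 0; 0, τG⁻¹ − ωA22⁻¹]` on the genotyped
  block.
* **Repeatability animal model** — `y = μ + breed + lactation + HYS + animal
  + permanent_env + e`, solved by Henderson's mixed-model equations with any
  of the three relationship inverses; variance components are inputs
  (`h²`, repeatability), not estimated.
* **Validation** — threefold cross-validation by lactation count (1/2/3
  records per cow), adjusted phenotypes from the training fit,
  accuracy `r = corr(EBV, adj.pheno) / sqrt(h²/(rep + (1−rep)/n))`, and the
  bias slope of adjusted phenotype on EBV.
* **Simulation** — discrete-generation pedigree with breed classes and
  herd-linking sires, gene-dropped genotypes (with QC-failing SNPs engineered
  in), and records with configurable mean/sd/h²/repeatability targets.

## CLI

```sh
stepblup simulate --seed 1 --out sim/                 # synthetic herd
stepblup qc --raw sim/genotypes.raw --map sim/genotypes.map --out qc/
stepblup evaluate --ped sim/pedigree.csv --pheno sim/phenotypes.csv \
    --raw sim/genotypes.raw --map sim/genotypes.map \
    --method ssgblup --trait MY --out eval/           # EBVs for all animals
stepblup crossvalidate --ped sim/pedigree.csv --pheno sim/phenotypes.csv \
    --method pblup --trait MY --out cv/               # fold + summary CSVs
stepblup report --summary cv/cv_summary_pblup_MY.csv --out report.csv
```

All subcommands accept `--config <yaml>` (see `stepblup.io.RunConfig` /
`stepblup.simulate.SimConfig` for keys) and `--seed`. File formats: CSV for
pedigree (`animal,sire,dam`; `0`/empty/`NA` = unknown parent), phenotypes
(`animal_id,breed,lactation_number,hys,my_305/fy_305/py_305`, or
herd/year/season columns), PLINK-style `.raw` dosages with a
`snp_id,chromosome,position` map (4-column PLINK `.map` also accepted).

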