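"""File formats, run configuration and record types.

Pedigrees and phenotypes travel as CSV; genotypes as a PLINK-style ``.raw``
dosage table (or plain CSV) plus a map file. All animal ids are strings and
are never recoded on the way in or out.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
import yaml

from .genotypes import GenotypeSet, MAP_COLUMNS
from .pedigree import PedigreeTable

logger = logging.getLogger(__name__)

TRAITS = ("MY", "FY", "PY")
TRAIT_COLUMNS = {"MY": "my_305", "FY": "fy_305", "PY": "py_305"}
METHODS = ("pblup", "gblup", "ssgblup")

#: Default heritabilities per trait (milk, fat, protein 305-day yields).
DEFAULT_H2 = {"MY": 0.19, "FY": 0.17, "PY": 0.19}
#: Default repeatability (not reported with the h² defaults; configurable).
DEFAULT_REPEATABILITY = 0.40


@dataclass
class RunConfig:
    """Evaluation settings for one trait/method run."""

    trait: str = "MY"
    h2: float | None = None
    repeatability: float = DEFAULT_REPEATABILITY
    method: str = "pblup"
    maf_min: float = 0.05
    hwe_p_min: float = 1e-15
    autosomes: tuple[int, int] = (1, 29)
    grm_blend: float = 0.05
    tau: float = 1.0
    omega: float = 1.0
    solver_tol: float = 1e-10
    adjust_with: str = "training"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.trait not in TRAITS:
            raise ValueError(f"trait must be one of {TRAITS}, got {self.trait!r}")
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}, got {self.method!r}")
        if self.h2 is None:
            self.h2 = DEFAULT_H2[self.trait]
        if not 0.0 < self.h2 <= self.repeatability < 1.0:
            raise ValueError(
                "variance ratios must satisfy 0 < h2 <= repeatability < 1; "
                f"got h2={self.h2}, repeatability={self.repeatability}"
            )
        if not 0.0 <= self.grm_blend <= 1.0:
            raise ValueError("grm_blend must be in [0, 1]")
        if self.adjust_with not in ("training", "whole"):
            raise ValueError("adjust_with must be 'training' or 'whole'")
        self.autosomes = (int(self.autosomes[0]), int(self.autosomes[1]))

    @property
    def autosome_range(self) -> range:
        lo, hi = self.autosomes
        return range(lo, hi + 1)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "autosomes" in raw:
            raw["autosomes"] = tuple(raw["autosomes"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["autosomes"] = list(self.autosomes)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


@dataclass(frozen=True)
class LactationRecord:
    """One 305-day yield record with its fixed-effect levels."""

    animal_id: str
    breed: str
    lactation_number: int
    hys: str
    yield_305d: float
    trait: str = "MY"

    def __post_init__(self) -> None:
        if self.lactation_number not in (1, 2, 3):
            raise ValueError(
                f"lactation_number must be 1..3, got {self.lactation_number}"
            )
        if not self.yield_305d > 0:
            raise ValueError(f"yield must be positive, got {self.yield_305d}")


def records_to_frame(records) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "animal_id": [r.animal_id for r in records],
            "breed": [r.breed for r in records],
            "lactation_number": [r.lactation_number for r in records],
            "hys": [r.hys for r in records],
            "yield_305d": [r.yield_305d for r in records],
        }
    )


# ---------------------------------------------------------------------------
# pedigree


def read_pedigree(path) -> PedigreeTable:
    """Read an animal,sire,dam CSV; '0'/''/NA mean unknown parent."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    df.columns = [c.strip().lower() for c in df.columns]
    required = {"animal", "sire", "dam"}
    if not required.issubset(df.columns):
        raise ValueError(f"pedigree CSV needs columns {sorted(required)}")
    return PedigreeTable.from_frame(df)


def write_pedigree(ped: PedigreeTable, path) -> None:
    ped.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# phenotypes


def read_phenotypes(path, trait: str = "MY") -> list[LactationRecord]:
    """Read lactation records for one trait.

    Accepts either a pre-built ``hys`` column or separate herd/year/season
    columns (joined with '_'). Rows missing the requested yield are dropped
    with a logged count.
    """
    if trait not in TRAITS:
        raise ValueError(f"trait must be one of {TRAITS}")
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    ycol = TRAIT_COLUMNS[trait]
    if ycol not in df.columns:
        raise ValueError(f"phenotype CSV lacks column {ycol!r} for trait {trait}")
    if "hys" not in df.columns:
        triplet = {"herd", "year", "season"}
        if not triplet.issubset(df.columns):
            raise ValueError("phenotype CSV needs 'hys' or herd/year/season columns")
        df["hys"] = (
            df["herd"].astype(str)
            + "_"
            + df["year"].astype(str)
            + "_"
            + df["season"].astype(str)
        )
    for col in ("animal_id", "breed", "lactation_number"):
        if col not in df.columns:
            raise ValueError(f"phenotype CSV lacks column {col!r}")

    n_in = len(df)
    df = df[pd.to_numeric(df[ycol], errors="coerce").notna()].copy()
    dropped = n_in - len(df)
    if dropped:
        logger.info("dropped %d rows with missing %s yield", dropped, trait)
    if df.empty:
        logger.warning("phenotype file %s yielded no %s records", path, trait)
        return []

    lact = pd.to_numeric(df["lactation_number"], errors="raise").astype(int)
    bad = ~lact.isin([1, 2, 3])
    if bad.any():
        raise ValueError(
            f"lactation_number outside 1..3 in rows {df.index[bad].tolist()}"
        )
    dup = df.assign(_l=lact).duplicated(subset=["animal_id", "_l"], keep=False)
    if dup.any():
        offenders = sorted(df.loc[dup, "animal_id"].astype(str).unique())
        raise ValueError(f"duplicate lactation numbers for animals: {offenders}")

    return [
        LactationRecord(
            animal_id=str(row.animal_id),
            breed=str(row.breed),
            lactation_number=int(row.lactation_number),
            hys=str(row.hys),
            yield_305d=float(getattr(row, ycol)),
            trait=trait,
        )
        for row in df.itertuples(index=False)
    ]


def write_phenotypes(records, path, trait: str | None = None) -> None:
    if not records and trait is None:
        trait = "MY"
    trait = trait or records[0].trait
    df = records_to_frame(records)
    df[TRAIT_COLUMNS[trait]] = df.pop("yield_305d")
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# genotypes

_RAW_META = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]


def _read_map(map_path) -> pd.DataFrame:
    """Map file: CSV with snp_id,chromosome,position header, or 4-column
    whitespace PLINK .map (chrom, id, cM, pos). Chromosome 0/NA = unplaced."""
    with open(map_path) as fh:
        first = fh.readline()
    if "snp_id" in first:
        df = pd.read_csv(map_path)
        df.columns = [c.strip().lower() for c in df.columns]
        missing = set(MAP_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"map file lacks columns {sorted(missing)}")
        df = df[MAP_COLUMNS]
    else:
        df = pd.read_csv(map_path, sep=r"\s+", header=None)
        if df.shape[1] < 4:
            raise ValueError("PLINK .map needs 4 columns: chrom id cM pos")
        df = df.iloc[:, [1, 0, 3]]
        df.columns = MAP_COLUMNS
    df["snp_id"] = df["snp_id"].astype(str)
    for col in ("chromosome", "position"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    # chromosome 0 is the PLINK spelling for "unknown location"
    df.loc[df["chromosome"] == 0, ["chromosome", "position"]] = np.nan
    return df.reset_index(drop=True)


def _strip_allele_suffix(name: str) -> str:
    if len(name) > 2 and name[-2] == "_" and name[-1] in "ACGT":
        return name[:-2]
    return name


def read_genotypes(path, map_path) -> GenotypeSet:
    """Read a dosage matrix (.raw or CSV) and its map.

    Columns are reordered to map order; a matrix SNP absent from the map is an
    error; map rows without a matrix column are dropped with a logged count.
    """
    path = str(path)
    if path.endswith(".raw"):
        df = pd.read_csv(path, sep=r"\s+")
        ids = df["IID"].astype(str).tolist()
        dose = df.drop(columns=[c for c in _RAW_META if c in df.columns])
    else:
        df = pd.read_csv(path)
        ids = df.iloc[:, 0].astype(str).tolist()
        dose = df.iloc[:, 1:]
    dose.columns = [_strip_allele_suffix(str(c)) for c in dose.columns]

    snp_map = _read_map(map_path)
    mapped = set(snp_map["snp_id"])
    orphans = [c for c in dose.columns if c not in mapped]
    if orphans:
        raise ValueError(f"SNPs in matrix but absent from map: {orphans[:10]}")
    in_matrix = snp_map["snp_id"].isin(set(dose.columns))
    if (~in_matrix).any():
        logger.info(
            "dropped %d map rows without a matrix column", int((~in_matrix).sum())
        )
        snp_map = snp_map[in_matrix].reset_index(drop=True)

    dose = dose[snp_map["snp_id"].tolist()]
    values = dose.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    # distinguish true NA spellings from garbage tokens
    raw_na = dose.isna() | dose.astype(str).isin(["NA", "nan", ""])
    if (np.isnan(values) & ~raw_na.to_numpy()).any():
        raise ValueError("non-numeric dosage values that are not NA")
    return GenotypeSet(values, ids, snp_map)


def write_genotypes(geno: GenotypeSet, raw_path, map_path) -> None:
    """Write a PLINK-style .raw dosage table and a snp_id,chromosome,position map."""
    header = _RAW_META + geno.snp_map["snp_id"].tolist()
    with open(raw_path, "w") as fh:
        fh.write(" ".join(header) + "\n")
        for i, animal in enumerate(geno.ids):
            row = geno.dosages[i]
            cells = ["NA" if np.isnan(v) else str(int(v)) for v in row]
            fh.write(" ".join([animal, animal, "0", "0", "0", "-9"] + cells) + "\n")
    out_map = geno.snp_map.copy()
    for col in ("chromosome", "position"):
        out_map[col] = out_map[col].astype("Int64")
    out_map.to_csv(map_path, index=False)


def write_ebvs(solution_ebv: pd.Series, path, method: str, trait: str) -> None:
    pd.DataFrame(
        {
            "animal_id": solution_ebv.index,
            "ebv": solution_ebv.to_numpy(),
            "method": method,
            "trait": trait,
        }
    ).to_csv(path, index=False)
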