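"""Readers and writers for every external representation the pipeline touches.

Genotypes travel as PLINK 1.9 binary triples (bed/bim/fam, SNP-major), the
cohort as a TSV with one row per subject (subject_id, ptau, age, gender, cds),
gene annotation as BED4, AD-related genes as a one-symbol-per-line list, and
protein-protein interactions as a two-column edge TSV.

Conventions fixed here and used everywhere downstream:

* additive genotype coding counts copies of allele1 (the bim A1 allele),
  matching PLINK; missing genotypes carry the sentinel :data:`MISSING`;
* genomic coordinates are 1-based inclusive internally (the bim convention);
  BED's 0-based half-open intervals are converted at this boundary and nowhere
  else;
* subject and SNP order are never changed relative to fam/bim.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: Sentinel for a missing genotype call (int8-compatible).
MISSING: int = -1

#: Clinical diagnostic status levels, in severity order; CN is the reference.
CDS_LEVELS: tuple[str, ...] = ("CN", "SMC", "EMCI", "LMCI", "AD")

_COHORT_COLUMNS = ("subject_id", "ptau", "age", "gender", "cds")

_BED_MAGIC = b"\x6c\x1b"
_BED_SNP_MAJOR = b"\x01"


class PlinkFormatError(ValueError):
    """Raised when a bed/bim/fam triple violates the PLINK 1.9 binary format."""


class CohortFormatError(ValueError):
    """Raised when the cohort TSV is malformed (columns, labels, duplicates)."""


class GeneBedFormatError(ValueError):
    """Raised when the gene annotation BED file is malformed."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SnpInfo:
    """Identity of one biallelic SNP as read from a bim file."""

    snp_id: str
    chromosome: int
    position_bp: int
    allele1: str
    allele2: str

    def __post_init__(self) -> None:
        if self.position_bp < 1:
            raise ValueError(f"{self.snp_id}: position_bp must be >= 1")


@dataclass
class GenotypeMatrix:
    """Subjects x SNPs additive-coded genotypes with per-SNP metadata.

    ``values[i, j]`` counts copies of ``snps[j].allele1`` carried by subject
    ``subject_ids[i]`` and is one of {0, 1, 2, MISSING}.
    """

    values: np.ndarray
    subject_ids: list[str]
    snps: list[SnpInfo]
    #: Optional per-SNP population allele1 frequencies (set by the simulator).
    population_maf: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.values.ndim != 2:
            raise ValueError("genotype values must be a 2-D array")
        n, m = self.values.shape
        if n != len(self.subject_ids):
            raise ValueError("row count does not match subject_ids")
        if m != len(self.snps):
            raise ValueError("column count does not match snps")
        if len(set(self.subject_ids)) != n:
            raise ValueError("duplicate subject ids")
        ids = [s.snp_id for s in self.snps]
        if len(set(ids)) != m:
            raise ValueError("duplicate SNP ids")
        bad = ~np.isin(self.values, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("genotype codes must be 0, 1, 2 or MISSING")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def m_snps(self) -> int:
        return self.values.shape[1]

    @property
    def snp_ids(self) -> list[str]:
        return [s.snp_id for s in self.snps]

    def select_snps(self, index: np.ndarray) -> "GenotypeMatrix":
        """New matrix restricted to SNP columns ``index`` (order preserved)."""
        index = np.asarray(index)
        maf = None if self.population_maf is None else self.population_maf[index]
        return GenotypeMatrix(
            self.values[:, index],
            list(self.subject_ids),
            [self.snps[j] for j in np.atleast_1d(index)],
            population_maf=maf,
        )

    def select_subjects(self, index: np.ndarray) -> "GenotypeMatrix":
        """New matrix restricted to subject rows ``index`` (order preserved)."""
        index = np.asarray(index)
        return GenotypeMatrix(
            self.values[index, :],
            [self.subject_ids[i] for i in np.atleast_1d(index)],
            list(self.snps),
            population_maf=self.population_maf,
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.subject_ids == other.subject_ids
            and self.snps == other.snps
            and np.array_equal(self.values, other.values)
        )


@dataclass
class CohortTable:
    """Per-subject phenotype (CSF P-tau, pg/mL) and covariates.

    Rows with a missing phenotype or covariate are retained here and only
    excluded by the QC module, so exclusion counts stay auditable.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(_COHORT_COLUMNS) - set(self.data.columns)
        if missing:
            raise CohortFormatError(f"cohort table lacks columns: {sorted(missing)}")
        ids = self.data["subject_id"]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise CohortFormatError(f"duplicate subject_id: {dup!r}")
        self.data = self.data.reset_index(drop=True)

    @property
    def n_subjects(self) -> int:
        return len(self.data)

    @property
    def subject_ids(self) -> list[str]:
        return self.data["subject_id"].tolist()

    @property
    def missing_phenotype(self) -> pd.Series:
        return self.data["ptau"].isna()

    @property
    def missing_covariates(self) -> pd.Series:
        return (
            self.data["age"].isna()
            | self.data["gender"].isna()
            | self.data["cds"].isna()
        )

    def subset(self, subject_ids: list[str]) -> "CohortTable":
        """Rows for ``subject_ids`` in the order given."""
        idx = self.data.set_index("subject_id").loc[subject_ids].reset_index()
        return CohortTable(idx)


@dataclass(frozen=True)
class GeneAnnotationRecord:
    """One gene body; coordinates 1-based inclusive."""

    gene_symbol: str
    chromosome: int
    start_bp: int
    end_bp: int

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise ValueError(
                f"{self.gene_symbol}: start_bp {self.start_bp} > end_bp {self.end_bp}"
            )


@dataclass(frozen=True)
class PpiEdge:
    """An unordered protein-protein interaction edge between two gene symbols."""

    gene_a: str
    gene_b: str

    def __post_init__(self) -> None:
        if self.gene_a == self.gene_b:
            raise ValueError(f"self-edge not allowed: {self.gene_a}")

    def key(self) -> frozenset:
        return frozenset((self.gene_a, self.gene_b))


# ---------------------------------------------------------------------------
# PLINK binary genotypes
# ---------------------------------------------------------------------------

# 2-bit code -> additive genotype: 00 -> 2 copies of A1, 10 -> 1, 11 -> 0,
# 01 -> missing.  The lookup table expands one packed byte into 4 genotypes.
_CODE_TO_GENO = np.array([2, MISSING, 1, 0], dtype=np.int8)
_GENO_TO_CODE = {2: 0b00, MISSING: 0b01, 1: 0b10, 0: 0b11}

_BYTE_LUT = np.empty((256, 4), dtype=np.int8)
for _b in range(256):
    for _k in range(4):
        _BYTE_LUT[_b, _k] = _CODE_TO_GENO[(_b >> (2 * _k)) & 0b11]


def read_plink(bed_path, bim_path, fam_path) -> GenotypeMatrix:
    """Read a PLINK 1.9 SNP-major bed/bim/fam triple.

    Subject order follows the fam file, SNP order the bim file; neither is
    ever reordered.
    """
    bim = pd.read_csv(
        bim_path,
        sep=r"\s+",
        header=None,
        names=["chromosome", "snp_id", "cm", "position_bp", "allele1", "allele2"],
        dtype={"snp_id": str, "allele1": str, "allele2": str},
    )
    fam = pd.read_csv(
        fam_path,
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "pid", "mid", "sex", "pheno"],
        dtype=str,
    )
    snps = [
        SnpInfo(r.snp_id, int(r.chromosome), int(r.position_bp), r.allele1, r.allele2)
        for r in bim.itertuples()
    ]
    subject_ids = fam["iid"].tolist()
    n, m = len(subject_ids), len(snps)

    raw = Path(bed_path).read_bytes()
    if raw[:2] != _BED_MAGIC:
        raise PlinkFormatError(f"{bed_path}: bad magic bytes {raw[:2]!r}")
    if raw[2:3] != _BED_SNP_MAJOR:
        raise PlinkFormatError(
            f"{bed_path}: mode byte {raw[2:3]!r}; only SNP-major (0x01) supported"
        )
    bytes_per_snp = math.ceil(n / 4)
    expected = 3 + m * bytes_per_snp
    if len(raw) != expected:
        raise PlinkFormatError(
            f"{bed_path}: payload is {len(raw) - 3} bytes, expected "
            f"{m} SNPs x {bytes_per_snp} bytes = {expected - 3}"
        )
    packed = np.frombuffer(raw, dtype=np.uint8, offset=3).reshape(m, bytes_per_snp)
    genos = _BYTE_LUT[packed].reshape(m, bytes_per_snp * 4)[:, :n]
    return GenotypeMatrix(np.ascontiguousarray(genos.T), subject_ids, snps)


def write_plink(genotypes: GenotypeMatrix, out_prefix) -> dict[str, Path]:
    """Write a bed/bim/fam triple; lossless round-trip with :func:`read_plink`."""
    n, m = genotypes.values.shape
    if n == 0 or m == 0:
        raise ValueError("refusing to write a genotype matrix with no subjects or no SNPs")
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)

    bytes_per_snp = math.ceil(n / 4)
    codes = np.zeros((m, bytes_per_snp * 4), dtype=np.uint8)
    col_codes = np.empty((n, m), dtype=np.uint8)
    for geno, code in _GENO_TO_CODE.items():
        col_codes[genotypes.values == geno] = code
    codes[:, :n] = col_codes.T
    packed = (
        codes[:, 0::4]
        | (codes[:, 1::4] << 2)
        | (codes[:, 2::4] << 4)
        | (codes[:, 3::4] << 6)
    ).astype(np.uint8)

    bed = out_prefix.with_suffix(".bed")
    bim = out_prefix.with_suffix(".bim")
    fam = out_prefix.with_suffix(".fam")
    bed.write_bytes(_BED_MAGIC + _BED_SNP_MAJOR + packed.tobytes())
    with open(bim, "w") as fh:
        for s in genotypes.snps:
            fh.write(
                f"{s.chromosome}\t{s.snp_id}\t0\t{s.position_bp}\t{s.allele1}\t{s.allele2}\n"
            )
    with open(fam, "w") as fh:
        for sid in genotypes.subject_ids:
            fh.write(f"{sid}\t{sid}\t0\t0\t0\t-9\n")
    return {"bed": bed, "bim": bim, "fam": fam}


# ---------------------------------------------------------------------------
# Cohort table
# ---------------------------------------------------------------------------

def read_cohort(tsv_path) -> CohortTable:
    """Read the phenotype+covariate TSV.

    Unknown cds labels and duplicate subjects are errors; rows with a missing
    phenotype or covariate are kept (flagged via :class:`CohortTable`
    properties) — dropping them is the QC module's job.
    """
    df = pd.read_csv(tsv_path, sep="\t", dtype={"subject_id": str})
    missing = set(_COHORT_COLUMNS) - set(df.columns)
    if missing:
        raise CohortFormatError(f"{tsv_path}: missing required columns {sorted(missing)}")

    for col in ("ptau", "age", "gender"):
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            raise CohortFormatError(f"{tsv_path}: non-numeric value in {col!r}") from exc

    bad_gender = df["gender"].dropna()
    if not bad_gender.isin((0, 1)).all():
        raise CohortFormatError(f"{tsv_path}: gender must be coded 0/1")
    nonpos = df["ptau"].dropna() <= 0
    if nonpos.any():
        raise CohortFormatError(f"{tsv_path}: ptau must be positive (pg/mL)")

    cds = df["cds"].astype("string").str.strip()
    unknown = cds.notna() & ~cds.isin(CDS_LEVELS)
    if unknown.any():
        row = int(np.flatnonzero(unknown)[0])
        raise CohortFormatError(
            f"{tsv_path}: row {row + 2} has cds={cds.iloc[row]!r}; "
            f"allowed levels are {CDS_LEVELS}"
        )
    df["cds"] = cds
    return CohortTable(df[list(_COHORT_COLUMNS)].copy())


def write_cohort(cohort: CohortTable, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cohort.data.to_csv(path, sep="\t", index=False, float_format="%.12g")
    return path


# ---------------------------------------------------------------------------
# Gene annotation, gene lists, PPI edges
# ---------------------------------------------------------------------------

def _parse_chromosome(token: str) -> int:
    tok = token.lower().removeprefix("chr")
    try:
        return int(tok)
    except ValueError as exc:
        raise GeneBedFormatError(f"non-numeric chromosome {token!r}") from exc


def read_gene_bed(bed_path) -> list[GeneAnnotationRecord]:
    """Read BED4 gene annotation (0-based half-open) into 1-based inclusive records."""
    records: list[GeneAnnotationRecord] = []
    with open(bed_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 4:
                raise GeneBedFormatError(
                    f"{bed_path}:{lineno}: gene symbol required (BED4), got {len(parts)} columns"
                )
            chrom = _parse_chromosome(parts[0])
            try:
                start0, end0 = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise GeneBedFormatError(
                    f"{bed_path}:{lineno}: non-numeric coordinates"
                ) from exc
            start_bp, end_bp = start0 + 1, end0
            if start_bp > end_bp:
                raise GeneBedFormatError(
                    f"{bed_path}:{lineno}: empty or inverted interval [{start0}, {end0})"
                )
            records.append(GeneAnnotationRecord(parts[3], chrom, start_bp, end_bp))
    return records


def read_gene_list(path) -> list[str]:
    """One gene symbol per line; blank lines and '#' comments ignored."""
    out: list[str] = []
    with open(path) as fh:
        for line in fh:
            sym = line.strip()
            if sym and not sym.startswith("#"):
                out.append(sym)
    return out


def read_ppi_edges(path) -> list[PpiEdge]:
    """Two-column PPI edge TSV (header ``gene_a<TAB>gene_b`` optional).

    Symbols are whitespace-trimmed; self-edges are dropped with a warning.
    """
    edges: list[PpiEdge] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected two columns")
            a, b = parts[0].strip(), parts[1].strip()
            if lineno == 1 and (a, b) == ("gene_a", "gene_b"):
                continue
            if a == b:
                warnings.warn(f"{path}:{lineno}: dropping self-edge {a!r}")
                continue
            edges.append(PpiEdge(a, b))
    return edges


# ---------------------------------------------------------------------------
# Result tables
# ---------------------------------------------------------------------------

PAIR_RESULT_COLUMNS = (
    "snp1", "snp2", "chr1", "chr2",
    "alpha1", "alpha2", "alpha12", "F", "p", "n_used",
)


def write_pair_results(results, path) -> Path:
    """Write scan results as TSV, sorted by ascending p (ties: snp1, snp2).

    ``results`` is an iterable of objects with the PairResult attributes
    (duck-typed so the scan module stays import-independent of this writer).
    Floats are written with 12 significant digits, enough for a lossless
    practical round-trip. Genotype coding note: alpha1/alpha2/alpha12 refer to
    counted copies of the bim A1 allele.
    """
    rows = [
        {
            "snp1": r.snp1_id,
            "snp2": r.snp2_id,
            "chr1": r.chr1,
            "chr2": r.chr2,
            "alpha1": r.alpha1,
            "alpha2": r.alpha2,
            "alpha12": r.alpha12,
            "F": r.f_stat,
            "p": r.p_value,
            "n_used": r.n_used,
        }
        for r in results
    ]
    df = pd.DataFrame(rows, columns=list(PAIR_RESULT_COLUMNS))
    if len(df):
        df = df.sort_values(["p", "snp1", "snp2"], kind="mergesort").reset_index(drop=True)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")
    return path


def read_pair_results(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"snp1": str, "snp2": str})
    missing = set(PAIR_RESULT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing pair-result columns {sorted(missing)}")
    return df
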