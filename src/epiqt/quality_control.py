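"""Variant, subject and phenotype quality control with auditable counts.

Variant filters, applied in order: autosomal chromosome (1-22), SNP call rate
>= 0.95, minor allele frequency >= 0.05, Hardy-Weinberg exact test p >= 1e-6.
Subject filters: optional exclusion list, per-subject call rate >= 0.90,
phenotype present, all covariates present.  All thresholds are inclusive, and
every stage is recorded in a chained :class:`QcReport`.

The HWE test is the conditional exact (Levene-Haldane) test: given the allele
counts, each feasible heterozygote count h receives weight

    w(h) = C(n, n_hom1) * C(n - n_hom1, h) * 2**h

(the number of ways to realize the table), and the two-sided p-value is the
probability mass of all h whose weight does not exceed the observed one.
Weights are exact integers, so tail membership is decided without rounding;
only the final ratio is converted to float.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import MISSING, CohortTable, GenotypeMatrix

AUTOSOMES = frozenset(range(1, 23))

PHENOTYPE_TRANSFORMS = ("none", "log", "rank-inverse-normal")


class AllMissingError(ValueError):
    """A per-SNP statistic was requested on a column with no observed calls."""


@dataclass(frozen=True)
class QcThresholds:
    """Inclusive QC thresholds (defaults follow the standard GWAS protocol)."""

    snp_call_rate: float = 0.95
    subject_call_rate: float = 0.90
    maf: float = 0.05
    hwe_p: float = 1e-6


@dataclass(frozen=True)
class FilterStage:
    name: str
    n_before: int
    n_removed: int
    n_after: int

    def __post_init__(self) -> None:
        if self.n_after != self.n_before - self.n_removed or self.n_after < 0:
            raise ValueError(f"inconsistent filter stage {self}")


@dataclass
class QcReport:
    """Ordered, chained record of applied filters."""

    stages: list[FilterStage] = field(default_factory=list)

    def add(self, name: str, n_before: int, n_after: int) -> None:
        if self.stages and self.stages[-1].n_after != n_before:
            raise ValueError("filter stages must chain: n_before != previous n_after")
        self.stages.append(FilterStage(name, n_before, n_before - n_after, n_after))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(s.name, s.n_before, s.n_removed, s.n_after) for s in self.stages],
            columns=["filter", "n_before", "n_removed", "n_after"],
        )


# ---------------------------------------------------------------------------
# Per-SNP statistics
# ---------------------------------------------------------------------------

def snp_call_rate(genotypes: np.ndarray) -> float:
    """Fraction of non-missing calls in one genotype column."""
    g = np.asarray(genotypes)
    if g.size == 0:
        raise ValueError("empty genotype column")
    return float(np.count_nonzero(g != MISSING) / g.size)


def minor_allele_frequency(genotypes: np.ndarray) -> float:
    """MAF of one genotype column, ignoring missing calls."""
    g = np.asarray(genotypes)
    obs = g[g != MISSING]
    if obs.size == 0:
        raise AllMissingError("MAF undefined: all genotypes missing")
    freq = float(obs.sum()) / (2.0 * obs.size)
    return min(freq, 1.0 - freq)


def hwe_exact_test(n_hom1: int, n_het: int, n_hom2: int) -> float:
    """Two-sided exact Hardy-Weinberg p-value for one genotype table.

    Exact integer enumeration over all heterozygote counts compatible with the
    observed allele counts; see the module docstring for the weight formula.
    Monomorphic tables admit a single configuration and return 1.0.
    """
    counts = (n_hom1, n_het, n_hom2)
    if any(c < 0 for c in counts):
        raise ValueError(f"negative genotype count in {counts}")
    if any(int(c) != c for c in counts):
        raise ValueError(f"genotype counts must be integers, got {counts}")
    n = int(sum(counts))
    if n < 1:
        raise ValueError("at least one genotyped subject required")

    na = 2 * int(n_hom1) + int(n_het)  # allele1 count
    h_max = min(na, 2 * n - na)
    h_min = na % 2
    w_obs = None
    total = 0
    weights: list[tuple[int, int]] = []
    for h in range(h_min, h_max + 1, 2):
        hom1 = (na - h) // 2
        w = math.comb(n, hom1) * math.comb(n - hom1, h) * (1 << h)
        weights.append((h, w))
        total += w
        if h == n_het:
            w_obs = w
    assert w_obs is not None
    tail = sum(w for _, w in weights if w <= w_obs)
    return tail / total


def genotype_counts(genotypes: np.ndarray) -> tuple[int, int, int]:
    """(hom allele1, het, hom allele2) counts of one column, missing excluded."""
    g = np.asarray(genotypes)
    return (
        int(np.count_nonzero(g == 2)),
        int(np.count_nonzero(g == 1)),
        int(np.count_nonzero(g == 0)),
    )


# ---------------------------------------------------------------------------
# Matrix-level filters
# ---------------------------------------------------------------------------

def apply_variant_qc(
    genotypes: GenotypeMatrix,
    thresholds: QcThresholds | None = None,
) -> tuple[GenotypeMatrix, QcReport]:
    """Apply the four variant filters in order, recording per-stage counts.

    MAF and HWE are computed on the subjects present in ``genotypes``; run
    subject QC first so variant statistics reflect the analysis cohort.
    """
    th = thresholds or QcThresholds()
    report = QcReport()
    gm = genotypes

    chrom = np.array([s.chromosome in AUTOSOMES for s in gm.snps])
    before = gm.m_snps
    gm = gm.select_snps(np.flatnonzero(chrom))
    report.add("chromosome_1_22", before, gm.m_snps)

    if gm.m_snps:
        rates = np.array([snp_call_rate(gm.values[:, j]) for j in range(gm.m_snps)])
        keep = rates >= th.snp_call_rate
    else:
        keep = np.zeros(0, dtype=bool)
    before = gm.m_snps
    gm = gm.select_snps(np.flatnonzero(keep))
    report.add(f"snp_call_rate>={th.snp_call_rate}", before, gm.m_snps)

    keep_idx = []
    for j in range(gm.m_snps):
        try:
            ok = minor_allele_frequency(gm.values[:, j]) >= th.maf
        except AllMissingError:  # unreachable after the call-rate stage unless it is 0
            ok = False
        if ok:
            keep_idx.append(j)
    before = gm.m_snps
    gm = gm.select_snps(np.array(keep_idx, dtype=int))
    report.add(f"maf>={th.maf}", before, gm.m_snps)

    keep_idx = [
        j
        for j in range(gm.m_snps)
        if hwe_exact_test(*genotype_counts(gm.values[:, j])) >= th.hwe_p
    ]
    before = gm.m_snps
    gm = gm.select_snps(np.array(keep_idx, dtype=int))
    report.add(f"hwe_p>={th.hwe_p}", before, gm.m_snps)

    return gm, report


def apply_subject_qc(
    genotypes: GenotypeMatrix,
    cohort: CohortTable,
    thresholds: QcThresholds | None = None,
    exclude_subjects: list[str] | None = None,
) -> tuple[GenotypeMatrix, CohortTable, QcReport]:
    """Remove subjects failing call rate, lacking phenotype, or lacking covariates.

    Subjects absent from the cohort table count as "no phenotype".  The
    optional exclusion list lets externally derived removals (e.g. population
    stratification outliers) be injected as the first stage.  Output tables
    are re-aligned to the surviving intersection in original genotype order.
    """
    th = thresholds or QcThresholds()
    report = QcReport()
    ids = genotypes.subject_ids
    if not set(ids) & set(cohort.subject_ids):
        raise ValueError("no overlap between genotype and cohort subject ids")

    keep = np.ones(len(ids), dtype=bool)

    if exclude_subjects:
        excl = set(exclude_subjects)
        before = int(keep.sum())
        keep &= np.array([sid not in excl for sid in ids])
        report.add("exclusion_list", before, int(keep.sum()))

    # per-subject call rate across SNPs
    if genotypes.m_snps:
        rates = np.count_nonzero(genotypes.values != MISSING, axis=1) / genotypes.m_snps
    else:
        rates = np.ones(len(ids))
    before = int(keep.sum())
    keep &= rates >= th.subject_call_rate
    report.add(f"subject_call_rate>={th.subject_call_rate}", before, int(keep.sum()))

    pheno = cohort.data.set_index("subject_id")["ptau"]
    has_pheno = np.array([sid in pheno.index and pd.notna(pheno[sid]) for sid in ids])
    before = int(keep.sum())
    keep &= has_pheno
    report.add("has_phenotype", before, int(keep.sum()))

    cov_missing = cohort.missing_covariates
    cov_ok = cohort.data.loc[~cov_missing, "subject_id"]
    ok_set = set(cov_ok)
    before = int(keep.sum())
    keep &= np.array([sid in ok_set for sid in ids])
    report.add("has_covariates", before, int(keep.sum()))

    if not keep.any():
        raise ValueError("subject QC removed every subject")
    gm = genotypes.select_subjects(np.flatnonzero(keep))
    cohort_out = cohort.subset(gm.subject_ids)
    return gm, cohort_out, report


# ---------------------------------------------------------------------------
# Phenotype normalization
# ---------------------------------------------------------------------------

def normalize_phenotype(values: np.ndarray, mode: str = "log") -> np.ndarray:
    """Transform P-tau levels before regression.

    Modes: ``none`` (identity), ``log`` (natural log; default, since CSF
    P-tau concentrations are positive and right-skewed), and
    ``rank-inverse-normal`` (Blom-style scores, robust to any monotone
    departure from normality).
    """
    mode = mode.replace("_", "-")
    if mode not in PHENOTYPE_TRANSFORMS:
        raise ValueError(f"unknown transform {mode!r}; choose from {PHENOTYPE_TRANSFORMS}")
    y = np.asarray(values, dtype=float)
    if mode == "none":
        return y.copy()
    if mode == "log":
        if np.any(y <= 0):
            raise ValueError("log transform requires strictly positive phenotype values")
        return np.log(y)
    ranks = stats.rankdata(y, method="average")
    return stats.norm.ppf((ranks - 0.5) / y.size)


def check_baseline_uniqueness(cohort: CohortTable) -> None:
    """One baseline record per subject; duplicate ids violate the assumption.

    CohortTable construction already enforces unique subject ids; this hook
    exists so pipelines state the check explicitly in their manifest.
    """
    ids = cohort.data["subject_id"]
    if ids.duplicated().any():  # pragma: no cover - unreachable via CohortTable
        raise ValueError("multiple rows per subject: baseline consistency violated")
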