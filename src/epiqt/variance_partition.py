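"""Hierarchical R-squared decomposition for SNP pairs.

Three nested least-squares models are fit on the pair's complete-case subset:
covariates only; plus the two main effects; plus the interaction term.  With
R2 = 1 - RSS/TSS for each, the successive differences give

    r2_cov        variance in the trait explained by age, gender and cds
    delta_r2_main additional variance from the two SNP main effects
    delta_r2_int  additional variance from the SNP1 x SNP2 interaction

and r2_full is their sum by construction (telescoping differences).  The
interaction F statistic of the scan equals
delta_r2_int / ((1 - r2_full) / (n - 10)); this identity is used as a
cross-check between the two modules.  R2 is unadjusted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .epistasis_scan import N_FULL_PARAMS, gwas_main_effect
from .io_formats import MISSING, GenotypeMatrix

# deltas more negative than this indicate a real numerical problem, not noise
_NEG_TOL = 1e-12


@dataclass
class VariancePartition:
    """Variance-explained components for one pair; components sum to r2_full."""

    r2_cov: float
    delta_r2_main: float
    delta_r2_int: float
    r2_full: float
    n_used: int


def _rss(y: np.ndarray, X: np.ndarray) -> float:
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


def _clamp(delta: float, label: str) -> float:
    if delta < 0.0:
        if delta < -_NEG_TOL:
            warnings.warn(
                f"{label} = {delta:.3e} is negative beyond round-off; clamping to 0"
            )
        return 0.0
    return delta


def hierarchical_r2(
    g1: np.ndarray,
    g2: np.ndarray,
    y: np.ndarray,
    covariates: np.ndarray,
) -> VariancePartition:
    """Partition trait variance over the nested covariate/mains/interaction models.

    Complete-case rules match the interaction scan.  A trait with zero total
    variance has no variance to partition and raises ``ValueError``.
    """
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    y = np.asarray(y, dtype=float)
    C = np.asarray(covariates, dtype=float)
    mask = (
        (g1 != MISSING)
        & (g2 != MISSING)
        & np.isfinite(y)
        & np.all(np.isfinite(C), axis=1)
    )
    n = int(mask.sum())
    if n <= N_FULL_PARAMS:
        raise ValueError(f"need more than {N_FULL_PARAMS} complete cases, have {n}")
    g1m, g2m, ym, Cm = g1[mask], g2[mask], y[mask], C[mask]

    tss = float(np.sum((ym - ym.mean()) ** 2))
    if tss == 0.0:
        raise ValueError("phenotype has zero variance on the complete-case subset")

    ones = np.ones(n)
    X_cov = np.column_stack([ones, Cm])
    X_main = np.column_stack([ones, g1m, g2m, Cm])
    X_full = np.column_stack([ones, g1m, g2m, g1m * g2m, Cm])

    r2_cov = 1.0 - _rss(ym, X_cov) / tss
    r2_main = 1.0 - _rss(ym, X_main) / tss
    r2_full = 1.0 - _rss(ym, X_full) / tss

    d_main = _clamp(r2_main - r2_cov, "delta_r2_main")
    d_int = _clamp(r2_full - r2_main, "delta_r2_int")
    return VariancePartition(r2_cov, d_main, d_int, r2_cov + d_main + d_int, n)


def partition_top_pairs(
    pair_results,
    genotypes: GenotypeMatrix,
    y: np.ndarray,
    covariates: np.ndarray,
    top_n: int = 10,
) -> pd.DataFrame:
    """Recompute partitions for scan results and keep the top pairs.

    Ranking: delta_r2_int descending, ties broken by interaction p ascending.
    Alongside the partition the table carries each SNP's marginal (single-SNP
    GWAS) p-value, mirroring the usual top-pairs summary.  If ``top_n``
    exceeds the number of pairs, all are returned.
    """
    col = {sid: j for j, sid in enumerate(genotypes.snp_ids)}
    rows = []
    for r in pair_results:
        j1, j2 = col[r.snp1_id], col[r.snp2_id]
        part = hierarchical_r2(
            genotypes.values[:, j1], genotypes.values[:, j2], y, covariates
        )
        _, p1 = gwas_main_effect(genotypes.values[:, j1], y, covariates)
        _, p2 = gwas_main_effect(genotypes.values[:, j2], y, covariates)
        rows.append(
            {
                "snp1": r.snp1_id,
                "snp2": r.snp2_id,
                "gwas_p1": p1,
                "gwas_p2": p2,
                "interaction_p": r.p_value,
                "r2_cov": part.r2_cov,
                "delta_r2_main": part.delta_r2_main,
                "delta_r2_int": part.delta_r2_int,
                "r2_full": part.r2_full,
                "n_used": part.n_used,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "snp1", "snp2", "gwas_p1", "gwas_p2", "interaction_p",
            "r2_cov", "delta_r2_main", "delta_r2_int", "r2_full", "n_used",
        ],
    )
    if len(df):
        df = (
            df.sort_values(
                ["delta_r2_int", "interaction_p", "snp1", "snp2"],
                ascending=[False, True, True, True],
                kind="mergesort",
            )
            .head(top_n)
            .reset_index(drop=True)
        )
    return df
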