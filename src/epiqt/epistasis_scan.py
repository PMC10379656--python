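"""Exhaustive covariate-adjusted two-locus interaction scan.

For every unordered SNP pair (j, k) the trait y (here log CSF P-tau) is fit by
two nested least-squares models,

    reduced:  y = a0 + a1*g_j + a2*g_k           + age + gender + cds + e
    full:     y = a0 + a1*g_j + a2*g_k + a12*g_j*g_k + age + gender + cds + e

and the interaction term is judged by the partial F test

    F = (RSS_reduced - RSS_full) / (RSS_full / (n - 10)),   F ~ F(1, n - 10)

under the null a12 = 0 (10 = intercept + 2 mains + interaction + age + gender
+ 4 cds indicators).  Equivalently F is the squared t of a12.

The scan evaluates every pair exactly once.  When neither genotype column has
missing calls it uses a blocked Frisch-Waugh-Lovell path: the covariate block
is QR-factorized once, genotypes and trait are residualized against it, and
each pair reduces to a 3x3 (full) and 2x2 (reduced) solve, batched over a
block of pairs.  Pairs with missing genotypes, or whose small Gram systems are
near-singular, fall back to a per-pair full-design fit.  Block size never
changes any reported statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy import stats
from scipy.linalg import solve_triangular

from .io_formats import CDS_LEVELS, MISSING, CohortTable, GenotypeMatrix

#: Columns of the full model: intercept, g1, g2, g1*g2, age, gender, 4 cds.
N_FULL_PARAMS = 10
#: Columns of the single-SNP GWAS model: intercept, g, age, gender, 4 cds.
N_GWAS_PARAMS = 8

# relative tolerance below which a batched Gram determinant is treated as
# singular and the pair is re-fit on the careful per-pair path
_DET_RTOL = 1e-9


class CollinearityWarning(UserWarning):
    """A design column is constant or collinear with the intercept."""


class DegenerateFlag(str, Enum):
    OK = "ok"
    RANK_DEFICIENT = "rank_deficient"
    INSUFFICIENT_DF = "insufficient_df"


@dataclass(frozen=True)
class DesignSpec:
    """Covariate encoding plan: age numeric, gender 0/1, cds indicator-coded.

    cds uses 4 indicator columns with the first level (CN) as reference, so
    the full pair model has exactly ``N_FULL_PARAMS`` columns.
    """

    cds_levels: tuple[str, ...] = CDS_LEVELS
    reference: str = CDS_LEVELS[0]

    @property
    def covariate_labels(self) -> list[str]:
        return ["age", "gender"] + [
            f"cds_{lv}" for lv in self.cds_levels if lv != self.reference
        ]


@dataclass
class PairResult:
    """Fitted interaction model for one SNP pair."""

    snp1_id: str
    snp2_id: str
    alpha0: float
    alpha1: float
    alpha2: float
    alpha12: float
    f_stat: float
    p_value: float
    n_used: int
    sigma2: float = float("nan")  # residual variance of the full model
    chr1: int = 0
    chr2: int = 0
    degenerate_flag: DegenerateFlag = DegenerateFlag.OK


@dataclass
class ScanConfig:
    """Scan settings.

    ``p_threshold=None`` means Bonferroni: 0.05 / (number of pairs tested).
    A threshold >= 1 keeps every pair (useful for full dumps and oracles).
    ``block_size`` only affects runtime, never results.
    """

    p_threshold: float | None = None
    block_size: int = 512
    missing_policy: str = "complete_case"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.p_threshold is not None and not (0.0 < self.p_threshold <= 1.0):
            raise ValueError("p_threshold must be in (0, 1]")
        if self.block_size < 1:
            raise ValueError("block_size must be positive")
        if self.missing_policy != "complete_case":
            raise ValueError("only complete_case missingness is supported")


def bonferroni_threshold(m_snps: int, alpha: float = 0.05) -> float:
    n_tests = m_snps * (m_snps - 1) // 2
    return alpha / max(n_tests, 1)


# ---------------------------------------------------------------------------
# Design construction
# ---------------------------------------------------------------------------

def build_design(cohort: CohortTable, spec: DesignSpec | None = None) -> tuple[np.ndarray, list[str]]:
    """Covariate block (n x 6): age, gender, indicator columns for cds.

    Requires complete covariates (subject QC guarantees this).  Constant
    columns trigger a :class:`CollinearityWarning` — they are collinear with
    the intercept added by the model fits.
    """
    spec = spec or DesignSpec()
    df = cohort.data
    if cohort.missing_covariates.any():
        raise ValueError("cohort has missing covariates; run subject QC first")
    unseen = set(df["cds"]) - set(spec.cds_levels)
    if unseen:
        raise ValueError(f"unseen cds levels: {sorted(unseen)}")

    cols = [df["age"].to_numpy(float), df["gender"].to_numpy(float)]
    for lv in spec.cds_levels:
        if lv == spec.reference:
            continue
        cols.append((df["cds"] == lv).to_numpy(float))
    X = np.column_stack(cols)
    labels = spec.covariate_labels
    for j, lab in enumerate(labels):
        if np.ptp(X[:, j]) == 0:
            warnings.warn(
                f"covariate column {lab!r} is constant (collinear with intercept)",
                CollinearityWarning,
            )
    return X, labels


# ---------------------------------------------------------------------------
# Per-pair test (reference path)
# ---------------------------------------------------------------------------

def _rss(y: np.ndarray, X: np.ndarray, beta: np.ndarray) -> float:
    r = y - X @ beta
    return float(r @ r)


def pair_interaction_test(
    g1: np.ndarray,
    g2: np.ndarray,
    y: np.ndarray,
    covariates: np.ndarray,
    snp1_id: str = "snp1",
    snp2_id: str = "snp2",
) -> PairResult:
    """Fit the nested pair models on the complete-case subset and F-test a12.

    Degenerate cases follow fixed conventions: if the complete-case subset has
    n_used <= 10 the result is flagged ``insufficient_df``; if the interaction
    column is collinear with the remaining columns the result is flagged
    ``rank_deficient``; both report F = 0 and p = 1.
    """
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    y = np.asarray(y, dtype=float)
    C = np.asarray(covariates, dtype=float)

    mask = (
        (np.asarray(g1) != MISSING)
        & (np.asarray(g2) != MISSING)
        & np.isfinite(y)
        & np.all(np.isfinite(C), axis=1)
    )
    n_used = int(mask.sum())
    if n_used <= N_FULL_PARAMS:
        return PairResult(
            snp1_id, snp2_id, *(float("nan"),) * 4, 0.0, 1.0, n_used,
            degenerate_flag=DegenerateFlag.INSUFFICIENT_DF,
        )

    g1m, g2m, ym, Cm = g1[mask], g2[mask], y[mask], C[mask]
    ones = np.ones(n_used)
    X_red = np.column_stack([ones, g1m, g2m, Cm])
    X_full = np.column_stack([ones, g1m, g2m, g1m * g2m, Cm])

    beta_full, _, rank_full, _ = np.linalg.lstsq(X_full, ym, rcond=None)
    beta_red, _, rank_red, _ = np.linalg.lstsq(X_red, ym, rcond=None)
    rss_full = _rss(ym, X_full, beta_full)
    rss_red = _rss(ym, X_red, beta_red)

    alpha0, alpha1, alpha2, alpha12 = (float(b) for b in beta_full[:4])
    df_den = n_used - N_FULL_PARAMS
    sigma2 = rss_full / df_den

    if rank_full == rank_red:  # interaction adds no rank: collinear
        return PairResult(
            snp1_id, snp2_id, alpha0, alpha1, alpha2, alpha12,
            0.0, 1.0, n_used, sigma2,
            degenerate_flag=DegenerateFlag.RANK_DEFICIENT,
        )

    if rss_full <= 0.0:
        f_stat, p = float("inf"), 0.0
    else:
        f_stat = max(rss_red - rss_full, 0.0) / (rss_full / df_den)
        p = float(stats.f.sf(f_stat, 1, df_den))
    flag = DegenerateFlag.OK if rank_full == N_FULL_PARAMS else DegenerateFlag.RANK_DEFICIENT
    return PairResult(
        snp1_id, snp2_id, alpha0, alpha1, alpha2, alpha12,
        float(f_stat), p, n_used, sigma2, degenerate_flag=flag,
    )


# ---------------------------------------------------------------------------
# Blocked exhaustive scan
# ---------------------------------------------------------------------------

def _iter_pair_blocks(m: int, block_size: int):
    """Yield (i_idx, j_idx) arrays covering all i < j pairs in canonical order."""
    buf_i: list[int] = []
    buf_j: list[int] = []
    for i in range(m - 1):
        for j in range(i + 1, m):
            buf_i.append(i)
            buf_j.append(j)
            if len(buf_i) == block_size:
                yield np.array(buf_i), np.array(buf_j)
                buf_i, buf_j = [], []
    if buf_i:
        yield np.array(buf_i), np.array(buf_j)


def scan_all_pairs(
    genotypes: GenotypeMatrix,
    y: np.ndarray,
    covariates: np.ndarray,
    config: ScanConfig | None = None,
) -> list[PairResult]:
    """Evaluate every unordered SNP pair once; return pairs passing the threshold.

    Results are canonicalized to bim order (snp1 precedes snp2) and are
    identical, pair by pair, to :func:`pair_interaction_test` run singly.
    With fewer than two SNPs the result is empty.
    """
    config = config or ScanConfig()
    m = genotypes.m_snps
    if m < 2:
        return []
    threshold = (
        config.p_threshold
        if config.p_threshold is not None
        else bonferroni_threshold(m)
    )
    keep_all = threshold >= 1.0

    y = np.asarray(y, dtype=float)
    C = np.asarray(covariates, dtype=float)
    base_mask = np.isfinite(y) & np.all(np.isfinite(C), axis=1)
    G_raw = genotypes.values
    chroms = [s.chromosome for s in genotypes.snps]
    ids = genotypes.snp_ids

    Gb = G_raw[base_mask]
    yb = y[base_mask]
    Cb = np.column_stack([np.ones(int(base_mask.sum())), C[base_mask]])
    n_b = Gb.shape[0]

    # fast path needs a full-rank covariate block and pair columns w/o missing
    Q, R = np.linalg.qr(Cb)
    cov_full_rank = np.min(np.abs(np.diag(R))) > 1e-10 * max(np.max(np.abs(R)), 1.0)
    col_missing = (Gb == MISSING).any(axis=0)

    if cov_full_rank and n_b > N_FULL_PARAMS:
        Gf = Gb.astype(np.float64)
        QtG = Q.T @ Gf
        G_res = Gf - Q @ QtG
        Qty = Q.T @ yb
        y_res = yb - Q @ Qty
        yy = float(y_res @ y_res)
    else:
        col_missing = np.ones(m, dtype=bool)  # force everything to the slow path

    df_den = n_b - N_FULL_PARAMS
    results: list[PairResult] = []

    def slow(i: int, j: int) -> PairResult:
        r = pair_interaction_test(
            G_raw[:, i], G_raw[:, j], y, C, snp1_id=ids[i], snp2_id=ids[j]
        )
        r.chr1, r.chr2 = chroms[i], chroms[j]
        return r

    for I, J in _iter_pair_blocks(m, config.block_size):
        fast = ~(col_missing[I] | col_missing[J])
        for i, j in zip(I[~fast], J[~fast]):
            r = slow(int(i), int(j))
            if keep_all or r.p_value < threshold:
                results.append(r)
        if not fast.any():
            continue
        Ii, Jj = I[fast], J[fast]

        X1, X2 = G_res[:, Ii], G_res[:, Jj]
        P = Gf[:, Ii] * Gf[:, Jj]
        QtP = Q.T @ P
        P_res = P - Q @ QtP

        a11 = np.einsum("ij,ij->j", X1, X1)
        a12_ = np.einsum("ij,ij->j", X1, X2)
        a13 = np.einsum("ij,ij->j", X1, P_res)
        a22 = np.einsum("ij,ij->j", X2, X2)
        a23 = np.einsum("ij,ij->j", X2, P_res)
        a33 = np.einsum("ij,ij->j", P_res, P_res)
        b1 = X1.T @ y_res
        b2 = X2.T @ y_res
        b3 = P_res.T @ y_res

        det2 = a11 * a22 - a12_ * a12_
        M3 = np.empty((len(Ii), 3, 3))
        M3[:, 0, 0], M3[:, 0, 1], M3[:, 0, 2] = a11, a12_, a13
        M3[:, 1, 0], M3[:, 1, 1], M3[:, 1, 2] = a12_, a22, a23
        M3[:, 2, 0], M3[:, 2, 1], M3[:, 2, 2] = a13, a23, a33
        det3 = np.linalg.det(M3)
        scale3 = np.maximum(a11 * a22 * a33, np.finfo(float).tiny)
        scale2 = np.maximum(a11 * a22, np.finfo(float).tiny)
        bad = (
            ~np.isfinite(det3)
            | (det3 <= _DET_RTOL * scale3)
            | (det2 <= _DET_RTOL * scale2)
        )

        good = np.flatnonzero(~bad)
        for k in np.flatnonzero(bad):
            r = slow(int(Ii[k]), int(Jj[k]))
            if keep_all or r.p_value < threshold:
                results.append(r)
        if good.size == 0:
            continue

        g = good
        rhs3 = np.stack([b1[g], b2[g], b3[g]], axis=1)
        beta3 = np.linalg.solve(M3[g], rhs3[..., None])[..., 0]
        rss_full = yy - np.einsum("bk,bk->b", rhs3, beta3)

        # reduced model: 2x2 solve in closed form
        num1 = b1[g] * a22[g] - b2[g] * a12_[g]
        num2 = b2[g] * a11[g] - b1[g] * a12_[g]
        rss_red = yy - (b1[g] * num1 + b2[g] * num2) / det2[g]

        rss_full = np.maximum(rss_full, 0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            f_stat = np.maximum(rss_red - rss_full, 0.0) / (rss_full / df_den)
        f_stat = np.where(rss_full > 0.0, f_stat, np.inf)
        p_vals = stats.f.sf(f_stat, 1, df_den)

        hits = np.arange(g.size) if keep_all else np.flatnonzero(p_vals < threshold)
        if hits.size == 0:
            continue

        # back-substitute covariate coefficients for reported pairs only
        gi, gj = Ii[g[hits]], Jj[g[hits]]
        rhs_cov = (
            Qty[:, None]
            - QtG[:, gi] * beta3[hits, 0]
            - QtG[:, gj] * beta3[hits, 1]
            - QtP[:, g[hits]] * beta3[hits, 2]
        )
        gamma = solve_triangular(R, rhs_cov)
        for t, k in enumerate(hits):
            i, j = int(gi[t]), int(gj[t])
            rf = float(rss_full[k])
            results.append(
                PairResult(
                    ids[i], ids[j],
                    float(gamma[0, t]),
                    float(beta3[k, 0]), float(beta3[k, 1]), float(beta3[k, 2]),
                    float(f_stat[k]), float(p_vals[k]), n_b,
                    sigma2=rf / df_den,
                    chr1=chroms[i], chr2=chroms[j],
                )
            )
    return results


# ---------------------------------------------------------------------------
# Single-SNP (marginal main effect) GWAS model
# ---------------------------------------------------------------------------

def gwas_main_effect(
    g: np.ndarray,
    y: np.ndarray,
    covariates: np.ndarray,
) -> tuple[float, float]:
    """Additive single-SNP model y ~ 1 + g + age + gender + cds.

    Returns (beta, p) for the genotype coefficient; p is the two-sided t-test,
    equivalent to F(1, n-8).  Monomorphic or rank-deficient designs return
    (nan, nan).
    """
    g = np.asarray(g, dtype=float)
    y = np.asarray(y, dtype=float)
    C = np.asarray(covariates, dtype=float)
    mask = (g != MISSING) & np.isfinite(y) & np.all(np.isfinite(C), axis=1)
    n = int(mask.sum())
    if n <= N_GWAS_PARAMS:
        raise ValueError(f"need more than {N_GWAS_PARAMS} complete cases, have {n}")
    gm, ym, Cm = g[mask], y[mask], C[mask]
    if np.ptp(gm) == 0:
        return float("nan"), float("nan")
    X = np.column_stack([np.ones(n), gm, Cm])
    beta, _, rank, _ = np.linalg.lstsq(X, ym, rcond=None)
    if rank < N_GWAS_PARAMS:
        return float("nan"), float("nan")
    resid = ym - X @ beta
    sigma2 = float(resid @ resid) / (n - N_GWAS_PARAMS)
    xtx_inv = np.linalg.inv(X.T @ X)
    se = float(np.sqrt(sigma2 * xtx_inv[1, 1]))
    if se == 0.0:
        return float(beta[1]), 0.0
    t = float(beta[1]) / se
    p = float(2.0 * stats.t.sf(abs(t), n - N_GWAS_PARAMS))
    return float(beta[1]), p
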