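"""Synthetic genotype/phenotype cohorts with the structure the analysis assumes.

The generator emulates a post-QC quantitative-trait epistasis cohort: biallelic
autosomal SNPs in Hardy-Weinberg proportions with MAF >= 0.05, an ADNI-like
covariate mix (age, gender, five-level clinical diagnostic status), covariates
explaining a configurable share of trait variance (default 9.3%), and planted
SNP pairs whose interaction explains a configurable additional share.

Phenotype construction.  The latent trait is built additively on a total
population variance of 1:

    latent = cov_component + sum(main_components) + sum(int_components) + noise

Each component's coefficient is solved from analytic population variances.
For a SNP with allele1 frequency p, the genotype g ~ Binomial(2, p) has mean
mu = 2p and variance v = 2p(1-p).  A main effect planting fraction f uses
beta = sqrt(f / v) on the centered genotype.  An interaction of independent
SNPs i, j is planted on the doubly centered product
(g_i - mu_i) * (g_j - mu_j), which is orthogonal to both mains and the
intercept and has population variance v_i * v_j, so

    alpha12 = sqrt(f / (v_i * v_j))

plants exactly fraction f of incremental (beyond-mains) variance.  The doubly
centered product lies in span{1, g_i, g_j, g_i*g_j}, and its coefficient on
the raw product is alpha12, so the scan's full model recovers it with the
interaction coefficient alpha12 and delta_r2_int ~= f while the main-effect
delta stays near zero — mirroring the marginal-main-effect pairs the method
targets.  Noise variance absorbs the rest of the unit budget.

The stored P-tau value is 25 * exp(latent) pg/mL — a positive, right-skewed
concentration whose default log transform recovers the latent trait exactly
(F tests and R-squared are affine-invariant).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .epistasis_scan import build_design, pair_interaction_test
from .io_formats import CDS_LEVELS, CohortTable, GenotypeMatrix, SnpInfo

#: Clinical diagnostic status composition of the emulated cohort
#: (CN, SMC, EMCI, LMCI, AD) out of 860 subjects.
CDS_COUNTS = (201, 84, 251, 209, 115)

#: Additive severity scores used to give cds its share of the covariate effect.
_CDS_SCORES = np.array([0.0, 0.2, 0.5, 0.8, 1.2])

# relative weights of (age, gender, cds) within the covariate effect
_COV_WEIGHTS = (1.0, 0.5, 1.5)

_PTAU_SCALE = 25.0  # pg/mL; median-scale anchor for the lognormal phenotype


@dataclass
class SimulationConfig:
    """Study conditions for one simulated cohort.

    Defaults mirror the emulated study: 860 subjects, covariates explaining
    9.3% of trait variance, genotypes in HWE with MAF uniform on
    [0.05, 0.5].  ``planted_pairs`` entries are (i, j, fraction): the
    incremental trait-variance fraction of the i-j interaction beyond the
    mains.  ``planted_mains`` entries are (i, fraction).  ``ld_block_size``
    > 1 switches on a Gaussian-copula autoregressive allele correlation of
    strength ``ld_rho`` within consecutive SNP blocks (used to exercise
    collinearity handling; off by default, as independent SNPs are the
    reference condition).
    """

    n_subjects: int = 860
    n_snps: int = 100
    maf_range: tuple[float, float] = (0.05, 0.5)
    covariate_r2: float = 0.093
    planted_pairs: list[tuple[int, int, float]] = field(default_factory=list)
    planted_mains: list[tuple[int, float]] = field(default_factory=list)
    age_range: tuple[float, float] = (55.0, 90.0)
    cds_probs: tuple[float, ...] = tuple(c / sum(CDS_COUNTS) for c in CDS_COUNTS)
    ld_block_size: int = 1
    ld_rho: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < low <= high <= 0.5")
        if self.n_subjects < 1 or self.n_snps < 1:
            raise ValueError("n_subjects and n_snps must be positive")
        idx = [i for i, _ in self.planted_mains]
        idx += [k for i, j, _ in self.planted_pairs for k in (i, j)]
        if any(i < 0 or i >= self.n_snps for i in idx):
            raise ValueError("planted SNP index out of range")
        pair_idx = [(i, j) for i, j, _ in self.planted_pairs]
        if any(i == j for i, j in pair_idx):
            raise ValueError("planted pair must use two distinct SNPs")
        budget = (
            self.covariate_r2
            + sum(f for _, f in self.planted_mains)
            + sum(f for _, _, f in self.planted_pairs)
        )
        if not (0.0 <= budget < 1.0):
            raise ValueError(
                f"variance budget {budget:.3f} must be in [0, 1) "
                "(covariate_r2 + planted fractions)"
            )
        if abs(sum(self.cds_probs) - 1.0) > 1e-9:
            raise ValueError("cds_probs must sum to 1")


def _rng_for(config: SimulationConfig, stream: int) -> np.random.Generator:
    # independent, reproducible streams per stage from one user seed
    return np.random.default_rng(np.random.SeedSequence([config.seed, stream]))


def simulate_genotypes(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> GenotypeMatrix:
    """Draw a genotype panel in Hardy-Weinberg proportions.

    Per SNP the allele1 (minor) frequency is uniform on ``maf_range`` and
    genotypes are i.i.d. Binomial(2, p) across subjects — the HWE proportions
    (q^2, 2pq, p^2).  SNPs are assigned to chromosomes 1-22 in contiguous
    blocks with positions 250 kb apart.  The drawn frequencies are attached
    as ``population_maf`` for downstream coefficient solving.
    """
    rng = rng or _rng_for(config, 0)
    n, m = config.n_subjects, config.n_snps
    mafs = rng.uniform(*config.maf_range, size=m)

    if config.ld_block_size > 1 and config.ld_rho != 0.0:
        values = _genotypes_with_block_ld(rng, mafs, n, config)
    else:
        values = rng.binomial(2, mafs, size=(n, m)).astype(np.int8)

    snps = []
    per_chrom: dict[int, int] = {}
    for k in range(m):
        chrom = 1 + (k * 22) // m
        idx = per_chrom.get(chrom, 0)
        per_chrom[chrom] = idx + 1
        snps.append(
            SnpInfo(f"snp{k + 1:06d}", chrom, 1_000_000 + idx * 250_000, "A", "B")
        )
    subject_ids = [f"subj{i + 1:05d}" for i in range(n)]
    return GenotypeMatrix(values, subject_ids, snps, population_maf=mafs)


def _genotypes_with_block_ld(
    rng: np.random.Generator,
    mafs: np.ndarray,
    n: int,
    config: SimulationConfig,
) -> np.ndarray:
    """Gaussian-copula AR(1) allele correlation within consecutive SNP blocks."""
    from scipy import stats

    m = mafs.size
    rho = config.ld_rho
    values = np.zeros((n, m), dtype=np.int8)
    thresholds = stats.norm.ppf(mafs)  # allele carries allele1 iff z < threshold
    for _hap in range(2):
        z = np.empty((n, m))
        for k in range(m):
            eps = rng.standard_normal(n)
            if k % config.ld_block_size == 0:
                z[:, k] = eps
            else:
                z[:, k] = rho * z[:, k - 1] + math.sqrt(1.0 - rho**2) * eps
        values += (z < thresholds).astype(np.int8)
    return values


def simulate_cohort(
    config: SimulationConfig,
    genotypes: GenotypeMatrix,
    rng: np.random.Generator | None = None,
) -> tuple[CohortTable, dict]:
    """Draw covariates and build the phenotype; return the cohort and the truth.

    The truth dict records every planted coefficient and variance component so
    recovery can be checked against it.
    """
    rng = rng or _rng_for(config, 1)
    n = genotypes.n_subjects
    if n != config.n_subjects:
        raise ValueError("genotype matrix does not match config.n_subjects")
    mafs = genotypes.population_maf
    if mafs is None:
        # fall back to sample frequencies when genotypes came from elsewhere
        obs = np.ma.masked_equal(genotypes.values, -1)
        mafs = obs.mean(axis=0).filled(np.nan) / 2.0

    age = rng.uniform(*config.age_range, size=n)
    gender = rng.integers(0, 2, size=n)
    cds_idx = rng.choice(len(CDS_LEVELS), size=n, p=config.cds_probs)
    cds = np.array(CDS_LEVELS, dtype=object)[cds_idx]

    # covariate effect scaled to an exact *population* variance of covariate_r2
    lo, hi = config.age_range
    sd_age = (hi - lo) / math.sqrt(12.0)
    probs = np.asarray(config.cds_probs)
    mean_score = float(probs @ _CDS_SCORES)
    sd_score = math.sqrt(float(probs @ (_CDS_SCORES - mean_score) ** 2))
    w_age, w_gen, w_cds = _COV_WEIGHTS
    u = (
        w_age * (age - (lo + hi) / 2.0) / sd_age
        + w_gen * (gender - 0.5) / 0.5
        + w_cds * (_CDS_SCORES[cds_idx] - mean_score) / sd_score
    )
    w_norm = math.sqrt(w_age**2 + w_gen**2 + w_cds**2)
    cov_scale = math.sqrt(config.covariate_r2) / w_norm
    cov_component = cov_scale * u

    G = genotypes.values.astype(float)
    mains_component = np.zeros(n)
    betas: dict[int, float] = {}
    for i, f in config.planted_mains:
        p = float(mafs[i])
        v = 2.0 * p * (1.0 - p)
        beta = math.sqrt(f / v)
        betas[i] = beta
        mains_component += beta * (G[:, i] - 2.0 * p)

    int_component = np.zeros(n)
    alphas: dict[tuple[int, int], float] = {}
    total_int_var = 0.0
    for i, j, f in config.planted_pairs:
        p_i, p_j = float(mafs[i]), float(mafs[j])
        v_i, v_j = 2.0 * p_i * (1.0 - p_i), 2.0 * p_j * (1.0 - p_j)
        mu_i, mu_j = 2.0 * p_i, 2.0 * p_j
        alpha12 = math.sqrt(f / (v_i * v_j))
        alphas[(i, j)] = alpha12
        total_int_var += f
        int_component += alpha12 * (G[:, i] - mu_i) * (G[:, j] - mu_j)

    planted_main_var = sum(f for _, f in config.planted_mains)
    noise_var = 1.0 - config.covariate_r2 - planted_main_var - total_int_var
    if noise_var <= 0.0:
        raise ValueError(
            f"infeasible variance budget: noise variance {noise_var:.4f} <= 0"
        )
    noise = rng.normal(0.0, math.sqrt(noise_var), size=n)

    latent = cov_component + mains_component + int_component + noise
    ptau = _PTAU_SCALE * np.exp(latent)

    cohort = CohortTable(
        pd.DataFrame(
            {
                "subject_id": genotypes.subject_ids,
                "ptau": ptau,
                "age": age,
                "gender": gender,
                "cds": cds,
            }
        )
    )
    truth = {
        "population_maf": np.asarray(mafs),
        "covariate_r2": config.covariate_r2,
        "cov_scale": cov_scale,
        "main_betas": betas,
        "interaction_alphas": alphas,
        "planted_main_var": planted_main_var,
        "interaction_var": total_int_var,
        "noise_var": noise_var,
        "latent": latent,
        "ptau_scale": _PTAU_SCALE,
    }
    return cohort, truth


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[GenotypeMatrix, CohortTable, dict]:
    """Genotypes and cohort from one config (independent seeded streams)."""
    gm = simulate_genotypes(config)
    cohort, truth = simulate_cohort(config, gm)
    return gm, cohort, truth


def estimate_power_and_type1(
    config: SimulationConfig,
    p_threshold: float,
    alpha: float = 0.05,
    n_reps: int = 100,
    n_null_pairs: int = 20,
) -> pd.DataFrame:
    """Monte-Carlo power for each planted pair and empirical type-I rate.

    Per replicate a fresh cohort is drawn; power is the fraction of replicates
    in which the planted pair's interaction p falls below ``p_threshold``.
    The type-I rate pools ``n_null_pairs`` pairs of SNPs untouched by any
    planted effect and counts p < ``alpha``.  Binomial standard errors are
    attached.  Returns a table with one row per planted pair plus one
    ``type1`` row.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    planted_idx = {i for i, _ in config.planted_mains}
    planted_idx |= {k for i, j, _ in config.planted_pairs for k in (i, j)}
    free = [k for k in range(config.n_snps) if k not in planted_idx]
    null_pairs = [(free[2 * t], free[2 * t + 1]) for t in range(min(n_null_pairs, len(free) // 2))]

    seed_rng = _rng_for(config, 2)
    hits = {pair[:2]: 0 for pair in [(i, j) for i, j, _ in config.planted_pairs]}
    null_hits = 0
    null_total = 0
    for _ in range(n_reps):
        rep_seed = int(seed_rng.integers(2**31))
        cfg = replace(config, seed=rep_seed)
        gm, cohort, _ = simulate_dataset(cfg)
        y = np.log(cohort.data["ptau"].to_numpy())
        C, _ = build_design(cohort)
        for i, j, _f in config.planted_pairs:
            r = pair_interaction_test(gm.values[:, i], gm.values[:, j], y, C)
            if r.p_value < p_threshold:
                hits[(i, j)] += 1
        for i, j in null_pairs:
            r = pair_interaction_test(gm.values[:, i], gm.values[:, j], y, C)
            null_total += 1
            null_hits += r.p_value < alpha

    rows = []
    for (i, j), h in hits.items():
        est = h / n_reps
        rows.append(
            {
                "label": f"power[{i},{j}]",
                "estimate": est,
                "se": math.sqrt(est * (1.0 - est) / n_reps),
                "n": n_reps,
            }
        )
    if null_total:
        est = null_hits / null_total
        rows.append(
            {
                "label": "type1",
                "estimate": est,
                "se": math.sqrt(est * (1.0 - est) / null_total),
                "n": null_total,
            }
        )
    return pd.DataFrame(rows, columns=["label", "estimate", "se", "n"])
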