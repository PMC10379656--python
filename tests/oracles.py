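"""Independent oracles used to validate the implementation.

Each oracle is deliberately naive and shares no code with the package:
explicit normal equations for the nested-model F test, exact rational
(Fraction) factorial enumeration for the Hardy-Weinberg test.
"""

from __future__ import annotations

from fractions import Fraction
from math import factorial

import numpy as np
from scipy import stats


def naive_interaction_f_test(g1, g2, y, covariates):
    """Nested-model F test by explicit normal-equation solves.

    Returns (F, p, n_used) for the interaction term of the model
    y ~ 1 + g1 + g2 + g1*g2 + covariates, complete cases only (missing
    genotype coded -1).  Raises on rank-deficient designs.
    """
    g1 = np.asarray(g1, float)
    g2 = np.asarray(g2, float)
    y = np.asarray(y, float)
    C = np.asarray(covariates, float)
    keep = (g1 != -1) & (g2 != -1) & np.isfinite(y) & np.all(np.isfinite(C), axis=1)
    g1, g2, y, C = g1[keep], g2[keep], y[keep], C[keep]
    n = int(keep.sum())

    ones = np.ones(n)
    X_full = np.column_stack([ones, g1, g2, g1 * g2, C])
    X_red = np.column_stack([ones, g1, g2, C])
    for X in (X_full, X_red):
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise np.linalg.LinAlgError("rank-deficient design")

    def rss(X):
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        r = y - X @ beta
        return float(r @ r)

    rss_full, rss_red = rss(X_full), rss(X_red)
    df_den = n - X_full.shape[1]
    f = (rss_red - rss_full) / (rss_full / df_den)
    p = float(stats.f.sf(f, 1, df_den))
    return f, p, n


def naive_full_model_coefs(g1, g2, y, covariates):
    """Full-model coefficients (a0, a1, a2, a12) by normal equations."""
    g1 = np.asarray(g1, float)
    g2 = np.asarray(g2, float)
    y = np.asarray(y, float)
    C = np.asarray(covariates, float)
    ones = np.ones(len(y))
    X = np.column_stack([ones, g1, g2, g1 * g2, C])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    return tuple(float(b) for b in beta[:4])


def hwe_exact_fraction(n_hom1: int, n_het: int, n_hom2: int) -> Fraction:
    """Exact rational two-sided HWE p by brute-force factorial enumeration.

    Conditional on the allele counts, P(het = h) is proportional to
    n! / (hom1! h! hom2!) * 2**h; the p-value sums the probabilities of all
    heterozygote counts no more probable than the observed one.
    """
    n = n_hom1 + n_het + n_hom2
    na = 2 * n_hom1 + n_het

    def prob_weight(h: int) -> Fraction:
        hom1 = (na - h) // 2
        hom2 = n - hom1 - h
        return Fraction(
            factorial(n) * 2**h, factorial(hom1) * factorial(h) * factorial(hom2)
        )

    feasible = [h for h in range(na % 2, min(na, 2 * n - na) + 1, 2)]
    weights = {h: prob_weight(h) for h in feasible}
    total = sum(weights.values())
    obs = weights[n_het]
    tail = sum(w for w in weights.values() if w <= obs)
    return Fraction(tail, total)
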