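import numpy as np
import pandas as pd
import pytest
from scipy import stats

from epiqt import (
    MISSING,
    CohortTable,
    ScanConfig,
    SimulationConfig,
    bonferroni_threshold,
    build_design,
    gwas_main_effect,
    pair_interaction_test,
    scan_all_pairs,
    simulate_dataset,
)
from epiqt.epistasis_scan import CollinearityWarning, DegenerateFlag
from oracles import naive_full_model_coefs, naive_interaction_f_test


def _cohort_frame(n, rng):
    return CohortTable(
        pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(n)],
                "ptau": rng.lognormal(3, 0.5, n),
                "age": rng.uniform(55, 90, n),
                "gender": rng.integers(0, 2, n),
                "cds": rng.choice(["CN", "SMC", "EMCI", "LMCI", "AD"], n),
            }
        )
    )


class TestBuildDesign:
    def test_all_cn_reference_gives_zero_indicators(self):
        rng = np.random.default_rng(1)
        ct = _cohort_frame(10, rng)
        ct.data["cds"] = "CN"
        with pytest.warns(CollinearityWarning):  # constant indicator columns
            X, labels = build_design(ct)
        assert X.shape == (10, 6)
        assert labels == ["age", "gender", "cds_SMC", "cds_EMCI", "cds_LMCI", "cds_AD"]
        assert np.all(X[:, 2:] == 0)

    def test_one_subject_per_level_indicator_sums(self):
        ct = CohortTable(
            pd.DataFrame(
                {
                    "subject_id": [f"s{i}" for i in range(5)],
                    "ptau": [20.0] * 5,
                    "age": [60, 65, 70, 75, 80],
                    "gender": [0, 1, 0, 1, 0],
                    "cds": ["CN", "SMC", "EMCI", "LMCI", "AD"],
                }
            )
        )
        X, _ = build_design(ct)
        assert X[:, 2:].sum(axis=0).tolist() == [1, 1, 1, 1]

    def test_constant_age_warns_collinear(self):
        rng = np.random.default_rng(2)
        ct = _cohort_frame(10, rng)
        ct.data["age"] = 70.0
        with pytest.warns(CollinearityWarning, match="age"):
            build_design(ct)

    def test_missing_covariates_rejected(self):
        rng = np.random.default_rng(3)
        ct = _cohort_frame(6, rng)
        ct.data.loc[2, "age"] = np.nan
        with pytest.raises(ValueError, match="missing covariates"):
            build_design(ct)


class TestPairInteractionTest:
    def test_matches_naive_normal_equation_oracle(self, small_panel):
        gm, _, _, y, C = small_panel
        for i, j in [(0, 1), (5, 9), (20, 41)]:
            r = pair_interaction_test(gm.values[:, i], gm.values[:, j], y, C)
            f_ref, p_ref, n_ref = naive_interaction_f_test(
                gm.values[:, i], gm.values[:, j], y, C
            )
            assert r.n_used == n_ref
            assert r.f_stat == pytest.approx(f_ref, rel=1e-8)
            assert r.p_value == pytest.approx(p_ref, abs=1e-10)
            coefs = naive_full_model_coefs(gm.values[:, i], gm.values[:, j], y, C)
            got = (r.alpha0, r.alpha1, r.alpha2, r.alpha12)
            assert got == pytest.approx(coefs, rel=1e-7, abs=1e-10)

    def test_matches_statsmodels_nested_f_test(self, small_panel):
        """Cross-check against statsmodels' compare_f_test on the same pair."""
        import statsmodels.api as sm

        gm, _, _, y, C = small_panel
        g1, g2 = gm.values[:, 0].astype(float), gm.values[:, 1].astype(float)
        X_red = sm.add_constant(np.column_stack([g1, g2, C]))
        X_full = sm.add_constant(np.column_stack([g1, g2, g1 * g2, C]))
        fit_red = sm.OLS(y, X_red).fit()
        fit_full = sm.OLS(y, X_full).fit()
        f_ref, p_ref, _ = fit_full.compare_f_test(fit_red)

        r = pair_interaction_test(g1, g2, y, C)
        assert r.f_stat == pytest.approx(float(f_ref), rel=1e-8)
        assert r.p_value == pytest.approx(float(p_ref), abs=1e-10)
        assert r.alpha12 == pytest.approx(float(fit_full.params[3]), rel=1e-8)

    def test_constant_genotype_flags_rank_deficient(self, small_panel):
        gm, _, _, y, C = small_panel
        g1 = np.zeros(gm.n_subjects, dtype=np.int8)
        r = pair_interaction_test(g1, gm.values[:, 3], y, C)
        assert r.degenerate_flag == DegenerateFlag.RANK_DEFICIENT
        assert (r.f_stat, r.p_value) == (0.0, 1.0)

    def test_residual_orthogonal_to_interaction_gives_f_zero(self, small_panel):
        """If y already equals its own reduced-model projection, adding the
        interaction explains nothing: F = 0, p = 1."""
        gm, _, _, y, C = small_panel
        g1, g2 = gm.values[:, 7].astype(float), gm.values[:, 8].astype(float)
        X_red = np.column_stack([np.ones(len(y)), g1, g2, C])
        beta, *_ = np.linalg.lstsq(X_red, y, rcond=None)
        y_fit = X_red @ beta
        r = pair_interaction_test(g1, g2, y_fit, C)
        assert r.f_stat == pytest.approx(0.0, abs=1e-6)
        assert r.p_value == pytest.approx(1.0, abs=1e-6)

    def test_insufficient_complete_cases_flagged(self, small_panel):
        gm, _, _, y, C = small_panel
        g1 = np.full(gm.n_subjects, MISSING, dtype=np.int8)
        g1[:10] = 1
        r = pair_interaction_test(g1, gm.values[:, 1], y, C)
        assert r.degenerate_flag == DegenerateFlag.INSUFFICIENT_DF
        assert r.n_used == 10

    def test_complete_case_excludes_missing_genotypes(self, small_panel):
        gm, _, _, y, C = small_panel
        g1 = gm.values[:, 4].copy()
        g1[:7] = MISSING
        r = pair_interaction_test(g1, gm.values[:, 5], y, C)
        assert r.n_used == gm.n_subjects - 7
        f_ref, p_ref, _ = naive_interaction_f_test(g1, gm.values[:, 5], y, C)
        assert r.f_stat == pytest.approx(f_ref, rel=1e-8)


class TestScanAllPairs:
    def test_single_snp_yields_empty(self, small_panel, full_scan_config):
        gm, _, _, y, C = small_panel
        one = gm.select_snps(np.array([0]))
        assert scan_all_pairs(one, y, C, full_scan_config) == []

    def test_every_pair_evaluated_once_and_matches_per_pair(self, small_panel, full_scan_config):
        gm, _, _, y, C = small_panel
        res = scan_all_pairs(gm, y, C, full_scan_config)
        assert len(res) == 60 * 59 // 2
        seen = {(r.snp1_id, r.snp2_id) for r in res}
        assert len(seen) == len(res)
        rng = np.random.default_rng(0)
        ids = gm.snp_ids
        for r in rng.choice(len(res), 40, replace=False):
            rr = res[r]
            i, j = ids.index(rr.snp1_id), ids.index(rr.snp2_id)
            single = pair_interaction_test(gm.values[:, i], gm.values[:, j], y, C)
            assert rr.f_stat == pytest.approx(single.f_stat, rel=1e-8)
            assert rr.p_value == pytest.approx(single.p_value, abs=1e-10)
            assert rr.alpha12 == pytest.approx(single.alpha12, rel=1e-7, abs=1e-10)
            assert rr.alpha0 == pytest.approx(single.alpha0, rel=1e-7, abs=1e-10)

    @pytest.mark.parametrize("block_size", [1, 7, 100, 10_000])
    def test_block_size_never_changes_results(self, small_panel, block_size):
        gm, _, _, y, C = small_panel
        sub = gm.select_snps(np.arange(12))
        ref = scan_all_pairs(sub, y, C, ScanConfig(p_threshold=1.0, block_size=512))
        got = scan_all_pairs(sub, y, C, ScanConfig(p_threshold=1.0, block_size=block_size))
        assert [(r.snp1_id, r.snp2_id) for r in got] == [
            (r.snp1_id, r.snp2_id) for r in ref
        ]
        # statistics agree to floating-point associativity of the blocked products
        for a, b in zip(got, ref):
            assert a.f_stat == pytest.approx(b.f_stat, rel=1e-12)
            assert a.p_value == pytest.approx(b.p_value, rel=1e-10, abs=1e-300)
            assert a.n_used == b.n_used

    def test_symmetry_under_column_swap(self, small_panel):
        gm, _, _, y, C = small_panel
        r_ij = pair_interaction_test(gm.values[:, 2], gm.values[:, 3], y, C)
        r_ji = pair_interaction_test(gm.values[:, 3], gm.values[:, 2], y, C)
        assert r_ij.f_stat == pytest.approx(r_ji.f_stat, rel=1e-10)
        assert r_ij.alpha1 == pytest.approx(r_ji.alpha2, rel=1e-8)
        assert r_ij.alpha12 == pytest.approx(r_ji.alpha12, rel=1e-8)

    def test_affine_invariance_of_f_and_p(self, small_panel, full_scan_config):
        gm, _, _, y, C = small_panel
        sub = gm.select_snps(np.arange(8))
        ref = scan_all_pairs(sub, y, C, full_scan_config)
        shifted = scan_all_pairs(sub, 3.5 * y + 11.0, C, full_scan_config)
        for a, b in zip(ref, shifted):
            assert a.f_stat == pytest.approx(b.f_stat, rel=1e-8)
            assert a.p_value == pytest.approx(b.p_value, abs=1e-10)

    def test_missing_genotypes_fall_back_to_complete_case(self, small_panel, full_scan_config):
        gm, _, _, y, C = small_panel
        vals = gm.values.copy()
        vals[:5, 2] = MISSING
        gm2 = gm.select_snps(np.arange(6))
        gm2.values = vals[:, :6]
        res = scan_all_pairs(gm2, y, C, full_scan_config)
        assert len(res) == 15
        with_missing = [r for r in res if "snp000003" in (r.snp1_id, r.snp2_id)]
        assert all(r.n_used == gm.n_subjects - 5 for r in with_missing)

    def test_threshold_filters_results(self, small_panel):
        gm, _, _, y, C = small_panel
        res = scan_all_pairs(gm, y, C, ScanConfig(p_threshold=1e-4))
        assert all(r.p_value < 1e-4 for r in res)
        planted = {"snp000001", "snp000002"}
        assert any({r.snp1_id, r.snp2_id} == planted for r in res)

    def test_bonferroni_default_threshold(self):
        assert bonferroni_threshold(60) == pytest.approx(0.05 / 1770)

    def test_perfect_ld_pair_flagged_not_dropped(self, small_panel, full_scan_config):
        gm, _, _, y, C = small_panel
        dup = gm.select_snps(np.array([0, 1]))
        vals = dup.values.copy()
        vals[:, 1] = vals[:, 0]  # identical columns: interaction collinear
        dup.values = vals
        res = scan_all_pairs(dup, y, C, full_scan_config)
        assert len(res) == 1
        assert res[0].degenerate_flag == DegenerateFlag.RANK_DEFICIENT


class TestGwasMainEffect:
    def test_planted_main_effect_recovered(self):
        cfg = SimulationConfig(
            n_subjects=500, n_snps=3, planted_mains=[(0, 0.05)], seed=42
        )
        gm, cohort, truth = simulate_dataset(cfg)
        y = np.log(cohort.data["ptau"].to_numpy())
        C, _ = build_design(cohort)
        beta, p = gwas_main_effect(gm.values[:, 0], y, C)
        true_beta = truth["main_betas"][0]
        X = np.column_stack([np.ones(500), gm.values[:, 0], C])
        sigma2 = (1 - 0.093 - 0.05)
        se_approx = np.sqrt(sigma2 * np.linalg.inv(X.T @ X)[1, 1])
        assert abs(beta - true_beta) < 3 * se_approx
        assert p < 1e-3

    def test_null_calibration(self):
        rng = np.random.default_rng(7)
        n, reps = 120, 400
        C = np.column_stack(
            [rng.uniform(55, 90, n), rng.integers(0, 2, n),
             *(rng.integers(0, 2, n) for _ in range(4))]
        ).astype(float)
        hits = 0
        for _ in range(reps):
            g = rng.binomial(2, 0.3, n)
            y = rng.standard_normal(n)
            _, p = gwas_main_effect(g, y, C)
            hits += p < 0.05
        lo, hi = stats.binom.ppf([0.005, 0.995], reps, 0.05)
        assert lo <= hits <= hi

    def test_perfect_fit_gives_p_zero(self):
        rng = np.random.default_rng(1)
        n = 80
        g = rng.binomial(2, 0.4, n).astype(float)
        C = rng.standard_normal((n, 6))
        # orthogonalize g against [1, C] so y = g is exactly the g coefficient
        Q, _ = np.linalg.qr(np.column_stack([np.ones(n), C]))
        g_perp = g - Q @ (Q.T @ g)
        _, p = gwas_main_effect(g, g_perp, C)
        assert p < 1e-15

    def test_monomorphic_genotype_degenerate(self, small_panel):
        gm, _, _, y, C = small_panel
        g = np.ones(gm.n_subjects, dtype=np.int8) * 2
        beta, p = gwas_main_effect(g, y, C)
        assert np.isnan(beta) and np.isnan(p)
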