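"""Logistic fitting, single-SNP tests, and null calibration of the scan."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

import statsmodels.api as sm

from edgescan import (
    ScanSpec,
    SimConfig,
    combine_chi2,
    edge_step1_p,
    fit_logistic,
    genome_scan,
    scan_snp,
    simulate_study,
)
from edgescan.scan import EstimationError
from edgescan.experiments import derive_seed as replicate_seed


def _two_by_two(a, b, c, d):
    """y/x vectors for a 2x2 table: a=exp.case, b=exp.ctrl, c=unexp.case, d=unexp.ctrl."""
    y = np.concatenate([np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)])
    x = np.concatenate([np.ones(a + b), np.zeros(c + d)])
    return y, np.column_stack([np.ones_like(x), x])


class TestFitLogistic:
    def test_saturated_2x2_equals_cross_product_or(self):
        y, X = _two_by_two(10, 20, 20, 10)
        fr = fit_logistic(y, X)
        assert fr.converged
        assert fr.beta[1] == pytest.approx(np.log(0.25), abs=1e-8)

    def test_balanced_independent_covariate_is_zero(self):
        y, X = _two_by_two(5, 5, 5, 5)
        fr = fit_logistic(y, X)
        assert abs(fr.beta[1]) < 1e-8

    def test_perfect_separation_not_converged(self):
        y = np.array([0.0] * 10 + [1.0] * 10)
        x = np.array([0.0] * 10 + [1.0] * 10)
        fr = fit_logistic(y, np.column_stack([np.ones(20), x]))
        assert not fr.converged

    def test_rank_deficient_names_columns(self):
        y = np.array([0, 1, 0, 1, 1, 0], dtype=float)
        x = np.arange(6, dtype=float)
        X = np.column_stack([np.ones(6), x, 2 * x])
        with pytest.raises(EstimationError, match="collinear"):
            fit_logistic(y, X, column_names=["intercept", "x", "x_doubled"])

    def test_matches_statsmodels(self):
        """Independent cross-check of estimates, covariance and Wald p."""
        rng = np.random.default_rng(8)
        n = 500
        X = np.column_stack([np.ones(n), rng.standard_normal((n, 3))])
        eta = X @ np.array([-0.5, 0.8, -0.3, 0.0])
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        ours = fit_logistic(y, X)
        ref = sm.Logit(y, X).fit(disp=0)
        np.testing.assert_allclose(ours.beta, ref.params, atol=1e-6)
        np.testing.assert_allclose(ours.cov, ref.cov_params(), rtol=1e-4, atol=1e-8)
        assert ours.loglik == pytest.approx(ref.llf, abs=1e-8)

    def test_covariance_symmetric_psd_when_converged(self):
        rng = np.random.default_rng(9)
        X = np.column_stack([np.ones(300), rng.standard_normal((300, 2))])
        y = (rng.random(300) < 0.4).astype(float)
        fr = fit_logistic(y, X)
        assert fr.converged
        np.testing.assert_allclose(fr.cov, fr.cov.T, atol=1e-12)
        assert np.linalg.eigvalsh(fr.cov).min() >= -1e-12

    def test_collapsible_2x2x2_matches_log_cross_products(self):
        """Saturated fit on two binary factors reproduces every cell log-OR."""
        counts = {  # (x1, x2) -> (cases, controls)
            (0, 0): (10, 40), (1, 0): (30, 30), (0, 1): (20, 20), (1, 1): (35, 15),
        }
        ys, x1s, x2s = [], [], []
        for (u, v), (ca, co) in counts.items():
            ys += [1] * ca + [0] * co
            x1s += [u] * (ca + co)
            x2s += [v] * (ca + co)
        y = np.array(ys, float)
        x1 = np.array(x1s, float)
        x2 = np.array(x2s, float)
        X = np.column_stack([np.ones_like(y), x1, x2, x1 * x2])
        fr = fit_logistic(y, X)

        def logodds(u, v):
            ca, co = counts[(u, v)]
            return np.log(ca / co)

        assert fr.beta[0] == pytest.approx(logodds(0, 0), abs=1e-6)
        assert fr.beta[1] == pytest.approx(logodds(1, 0) - logodds(0, 0), abs=1e-6)
        assert fr.beta[2] == pytest.approx(logodds(0, 1) - logodds(0, 0), abs=1e-6)
        assert fr.beta[3] == pytest.approx(
            logodds(1, 1) - logodds(1, 0) - logodds(0, 1) + logodds(0, 0), abs=1e-6
        )


class TestCombineChi2:
    def test_single_stat_is_identity(self):
        assert combine_chi2([3.84], [1]) == pytest.approx(stats.chi2.sf(3.84, 1))

    def test_all_zero_gives_one(self):
        assert combine_chi2([0, 0, 0], [1, 1, 1]) == pytest.approx(1.0)

    def test_matches_quadrature(self):
        p = combine_chi2([3.84, 2.71], [1, 1])
        tail, _ = integrate.quad(lambda x: stats.chi2.pdf(x, 2), 6.55, np.inf)
        assert p == pytest.approx(tail, rel=1e-8)

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            combine_chi2([-1.0], [1])
        with pytest.raises(ValueError):
            combine_chi2([np.nan], [1])


class TestScanRecords:
    def test_degenerate_dosage_flagged(self, small_study):
        _, cohort, _ = small_study
        dosage = np.zeros(len(cohort))
        dosage[0] = 1.0
        rec = scan_snp(cohort, dosage)
        assert not rec["converged"]
        assert np.isnan(rec["p_GxE_1df"])

    def test_chunking_is_invisible(self, small_study):
        _, cohort, block = small_study
        full = genome_scan(cohort, block)
        parts = [
            genome_scan(cohort, block.take_snps(np.arange(i, min(i + 7, block.n_snps))))
            for i in range(0, block.n_snps, 7)
        ]
        stitched = pd.concat(parts, ignore_index=True)
        stitched = stitched.sort_values(["chrom", "pos"]).reset_index(drop=True)
        pd.testing.assert_frame_equal(full, stitched)

    def test_empty_block_gives_empty_table(self, small_study):
        _, cohort, block = small_study
        out = genome_scan(cohort, block.take_snps(np.array([], dtype=int)))
        assert len(out) == 0

    def test_misaligned_subjects_error(self, small_study):
        _, cohort, block = small_study
        shuffled = cohort.iloc[::-1].reset_index(drop=True)
        with pytest.raises(ValueError, match="misaligned"):
            genome_scan(shuffled, block)

    def test_step1_from_marginal_and_ge_components_only(self, null_scan):
        """p_step1 recomputes from chi2_DG + chi2_EG and never touches GxE."""
        _, _, records = null_scan
        ok = records["converged"]
        recomputed = records[ok].apply(edge_step1_p, axis=1)
        np.testing.assert_allclose(records.loc[ok, "p_step1"], recomputed, atol=1e-12)

    def test_strong_marginal_effect_drives_screening_not_interaction(self):
        cfg = SimConfig(seed=55, n_cases=2000, n_controls=2000, n_snps=1,
                        beta_G=np.log(1.5), maf_range=(0.3, 0.3))
        cohort, block = simulate_study(cfg)
        rec = scan_snp(cohort, block.dosages[:, 0])
        assert rec["p_step1"] < 1e-6
        assert rec["p_GxE_1df"] > 0.01

    def test_ge_dependence_drives_gamma_not_interaction(self):
        cfg = SimConfig(seed=57, n_cases=2000, n_controls=2000, n_snps=1,
                        gamma_GE=0.25, maf_range=(0.3, 0.3))
        cohort, block = simulate_study(cfg)
        rec = scan_snp(cohort, block.dosages[:, 0])
        assert rec["p_EG"] < 1e-4
        assert rec["p_GxE_1df"] > 0.01

    def test_bmi_sensitivity_terms_fit(self, small_study):
        _, cohort, block = small_study
        rec = scan_snp(cohort, block.dosages[:, 0], ScanSpec(include_bmi_interactions=True))
        assert rec["converged"]
        assert 0 <= rec["p_GxE_1df"] <= 1


class TestNullCalibration:
    def test_gxe_rejection_rate_nominal(self, null_scan):
        _, _, records = null_scan
        p = records["p_GxE_1df"].dropna().to_numpy()
        rate = (p < 0.05).mean()
        se = np.sqrt(0.05 * 0.95 / len(p))
        assert abs(rate - 0.05) < 2.5 * se

    @pytest.mark.parametrize("col", ["p_GxE_1df", "p_joint_3df", "p_step1"])
    def test_null_pvalues_uniform(self, null_scan, col):
        _, _, records = null_scan
        p = records[col].dropna().to_numpy()
        assert len(p) > 1900
        assert stats.kstest(p, "uniform").pvalue > 0.01

    def test_screening_independent_of_interaction_test(self, null_scan):
        _, _, records = null_scan
        sub = records.dropna(subset=["p_step1", "p_GxE_1df"])
        r = np.corrcoef(sub["p_step1"], sub["p_GxE_1df"])[0, 1]
        assert abs(r) < 0.05

    def test_wald_close_to_likelihood_ratio(self, null_scan):
        """1-d.f. Wald and LR chi-squares agree within 5% at n >= 2000."""
        from edgescan.scan import build_covariate_design

        cohort, block, records = null_scan
        spec = ScanSpec()
        y = cohort["D"].to_numpy(float)
        C, _ = build_covariate_design(cohort, spec)
        e = cohort["E_binary"].to_numpy(float)
        rng = np.random.default_rng(3)
        for j in rng.choice(block.n_snps, 20, replace=False):
            g = block.dosages[:, j]
            full = fit_logistic(y, np.column_stack([C, g, e, g * e]), check_rank=False)
            red = fit_logistic(y, np.column_stack([C, g, e]), check_rank=False)
            lr = 2 * (full.loglik - red.loglik)
            wald = records.loc[records.index[j], "chi2_GxE"]
            if lr > 0.5:  # relative comparison meaningless near zero
                assert abs(wald - lr) / lr < 0.05

    def test_interaction_parameter_recovery(self):
        """Mean estimate of beta_GxE over replicates matches ln(1.5); Wald
        95% CIs cover at the nominal rate."""
        true = np.log(1.5)
        estimates, ses = [], []
        for r in range(200):
            cfg = SimConfig(
                seed=replicate_seed(1234, r), n_cases=5000, n_controls=5000,
                n_snps=1, maf_range=(0.25, 0.25), beta_GxE=true,
                beta_E=np.log(0.85), source_multiplier=6,
            )
            cohort, block = simulate_study(cfg)
            rec = scan_snp(cohort, block.dosages[:, 0])
            estimates.append(rec["beta_GxE"])
            ses.append(rec["se_GxE"])
        estimates = np.array(estimates)
        ses = np.array(ses)
        mc_se = estimates.std(ddof=1) / np.sqrt(len(estimates))
        assert abs(estimates.mean() - true) < 2 * mc_se
        cover = np.mean(np.abs(estimates - true) < 1.96 * ses)
        assert abs(cover - 0.95) < 2 * np.sqrt(0.95 * 0.05 / len(estimates))
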