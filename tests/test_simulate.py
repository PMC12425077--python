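"""Statistical behaviour of the synthetic cohort generator."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from edgescan import (
    ACTIVE_MET_CUTOFF,
    SimConfig,
    derive_exposure_variables,
    hwe_exact_test,
    simulate_disease_and_sample,
    simulate_exposure,
    simulate_genotype_block,
    simulate_study,
)
from edgescan.scan import build_covariate_design, fit_logistic, ScanSpec
from edgescan.simulate import SimulationError, _disease_probability, _draw_covariates


def _block(n, **kw):
    cfg = SimConfig(seed=kw.pop("seed", 5), n_snps=kw.pop("n_snps", 2), **kw)
    return cfg, simulate_genotype_block(cfg, n_subjects=n)


class TestGenotypes:
    def test_hwe_genotype_frequencies(self):
        """Hard-call frequencies match the HWE expectation p^2, 2pq, q^2."""
        cfg, block = _block(10000, maf_range=(0.2, 0.2), n_snps=5)
        for j in range(5):
            g = block.dosages[:, j]
            freqs = np.array([(g == k).mean() for k in (0, 1, 2)])
            expected = np.array([0.64, 0.32, 0.04])
            se = np.sqrt(expected * (1 - expected) / 10000)
            assert np.all(np.abs(freqs - expected) < 4 * se + 1e-9)

    def test_zero_ld_gives_independent_snps(self):
        _, block = _block(10000, ld_rho=0.0)
        r = np.corrcoef(block.dosages, rowvar=False)[0, 1]
        assert abs(r) < 0.05

    def test_positive_ld_gives_correlated_snps_within_block(self):
        _, block = _block(5000, ld_rho=0.8, block_size=2, n_snps=4)
        corr = np.corrcoef(block.dosages, rowvar=False)
        assert corr[0, 1] > 0.3  # same block
        assert abs(corr[1, 2]) < 0.08  # across block boundary

    def test_imputation_noise_calibrated_to_target_rsq(self):
        """corr^2(dosage, true genotype) lands near the configured R^2."""
        kw = dict(maf_range=(0.3, 0.3), n_snps=3, frac_imputed=1.0, seed=9)
        _, noisy = _block(10000, target_rsq=0.8, **kw)
        _, clean = _block(10000, target_rsq=1.0, **kw)  # same genotype stream
        for j in range(3):
            r2 = np.corrcoef(noisy.dosages[:, j], clean.dosages[:, j])[0, 1] ** 2
            assert 0.75 < r2 < 0.85

    def test_maf_within_binomial_error(self):
        cfg, block = _block(8000, maf_range=(0.05, 0.5), n_snps=50, seed=3)
        p = block.snp_meta["alt_freq"].to_numpy()
        phat = block.dosages.mean(axis=0) / 2.0
        sd = np.sqrt(p * (1 - p) / (2 * 8000))
        assert np.all(np.abs(phat - p) < 4 * sd)

    def test_hwe_holds_in_generated_population(self):
        """Exact-test rejections at 1e-4 are absent across 1000 null SNPs."""
        _, block = _block(2000, n_snps=1000, seed=17)
        rejections = 0
        for j in range(1000):
            g = block.dosages[:, j]
            p = hwe_exact_test(int((g == 0).sum()), int((g == 1).sum()), int((g == 2).sum()))
            rejections += p < 1e-4
        assert rejections / 1000 <= 5e-4

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SimConfig(maf_range=(0.0, 0.5))
        with pytest.raises(ValueError):
            SimConfig(ld_rho=1.0)
        with pytest.raises(ValueError):
            SimConfig(n_snps=0)
        with pytest.raises(ValueError):
            SimConfig(beta_G=np.inf)
        with pytest.raises(ValueError):
            SimConfig(gamma_GE=0.2, index_snp=None)


class TestExposure:
    def test_active_fraction_matches_target(self):
        cfg, block = _block(10000, seed=21)
        met = simulate_exposure(cfg, block)
        frac = (met >= ACTIVE_MET_CUTOFF).mean()
        assert 0.74 < frac < 0.78

    def test_no_dependence_without_gamma(self):
        cfg, block = _block(10000, seed=23)
        met = simulate_exposure(cfg, block)
        r = np.corrcoef(block.dosages[:, 0], met)[0, 1]
        assert abs(r) < 0.05

    def test_gamma_shifts_exposure_monotonically(self):
        cfg = SimConfig(seed=29, n_snps=1, gamma_GE=0.3, maf_range=(0.3, 0.3))
        block = simulate_genotype_block(cfg, n_subjects=10000)
        met = simulate_exposure(cfg, block)
        g = block.dosages[:, 0]
        means = [met[g == k].mean() for k in (0, 1, 2)]
        assert means[0] < means[1] < means[2]
        # active fraction is still calibrated after marginalising the shift
        assert 0.73 < (met >= ACTIVE_MET_CUTOFF).mean() < 0.79

    def test_exposure_is_skewed_nonnegative(self):
        cfg, block = _block(10000, seed=31)
        met = simulate_exposure(cfg, block)
        assert met.min() >= 0
        assert np.mean(met) > np.median(met)  # right skew


class TestDiseaseAndSampling:
    def test_null_model_balances_exposure(self):
        cfg = SimConfig(seed=37, n_cases=5000, n_controls=5000, n_snps=1)
        cohort, _ = simulate_study(cfg)
        diff = (
            cohort.loc[cohort.D == 1, "E_binary"].mean()
            - cohort.loc[cohort.D == 0, "E_binary"].mean()
        )
        assert abs(diff) < 0.02

    def test_exposure_or_recovery(self):
        """A single large study recovers the generating exposure OR."""
        cfg = SimConfig(seed=41, n_cases=5000, n_controls=5000, n_snps=1, beta_E=np.log(0.85))
        cohort, _ = simulate_study(cfg)
        C, _ = build_covariate_design(cohort, ScanSpec(include_study_indicators=False))
        X = np.column_stack([C, cohort["E_binary"].to_numpy(float)])
        fr = fit_logistic(cohort["D"].to_numpy(float), X, check_rank=False)
        assert abs(np.exp(fr.beta[-1]) - 0.85) < 0.05

    def test_prevalence_monotone_in_intercept(self):
        cov = _draw_covariates(5000, np.random.default_rng(1))
        g = np.zeros(5000)
        e = np.ones(5000)
        prevs = [
            _disease_probability(SimConfig(seed=1, beta0=b0), g, e, cov).mean()
            for b0 in (-3.0, -2.0, -1.0)
        ]
        assert prevs[0] < prevs[1] < prevs[2]

    def test_quota_exhaustion_raises(self):
        cfg = SimConfig(seed=43, n_cases=500, n_controls=10, n_snps=1,
                        beta0=-7.0, source_multiplier=2)
        block = simulate_genotype_block(cfg)
        met = simulate_exposure(cfg, block)
        with pytest.raises(SimulationError, match="source population exhausted"):
            simulate_disease_and_sample(cfg, block, met)

    def test_quotas_exact_per_study(self, small_study):
        _, cohort, _ = small_study
        counts = cohort.groupby("study")["D"].agg(["sum", "count"])
        assert (counts["sum"] == 250).all()
        assert (counts["count"] == 500).all()

    def test_cohort_block_row_alignment(self, small_study):
        _, cohort, block = small_study
        assert np.array_equal(block.subject_ids, cohort["subject_id"].to_numpy())

    def test_deferred_null_snp_generation_matches_full_path(self):
        """The two-phase simulator agrees distributionally with the
        three-stage path: same quotas, calibrated exposure, HWE genotypes."""
        cfg = SimConfig(seed=47, n_cases=400, n_controls=400, n_snps=30,
                        beta_E=np.log(0.8), beta_G=0.2, gamma_GE=0.1)
        cohort_a, block_a = simulate_study(cfg)
        blk = simulate_genotype_block(cfg)
        met = simulate_exposure(cfg, blk)
        cohort_b, block_b = simulate_disease_and_sample(cfg, blk, met, seed=cfg.seed)
        for cohort, block in ((cohort_a, block_a), (cohort_b, block_b)):
            assert cohort["D"].sum() == 400 and len(cohort) == 800
            assert 0.68 < cohort["E_binary"].mean() < 0.84
            af = block.dosages.mean(axis=0) / 2.0
            assert np.all((af > 0.01) & (af < 0.6))


class TestDerivedExposure:
    def test_binary_threshold_is_inclusive(self):
        df = pd.DataFrame(
            {
                "subject_id": ["a", "b"],
                "study": "s",
                "sex": ["female", "female"],
                "met_hours_week": [8.75, 8.74],
            }
        )
        out = derive_exposure_variables(df)
        assert list(out["E_binary"]) == [1, 0]

    def test_quartiles_split_eight_subjects_evenly(self):
        met = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0]
        df = pd.DataFrame(
            {
                "subject_id": list("abcdefgh"),
                "study": "s",
                "sex": "male",
                "met_hours_week": met,
            }
        )
        out = derive_exposure_variables(df)
        assert list(out["E_quartile"]) == [1, 1, 2, 2, 3, 3, 4, 4]

    @pytest.mark.parametrize("transform", [np.exp, np.sqrt, lambda x: 3 * x + 7])
    def test_quartiles_invariant_to_monotone_transform(self, transform):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(60)],
                "study": np.repeat(["u", "v"], 30),
                "sex": np.tile(["male", "female"], 30),
                "met_hours_week": rng.gamma(2.0, 10.0, 60),
            }
        )
        base = derive_exposure_variables(df)
        moved = df.assign(met_hours_week=transform(df["met_hours_week"]))
        assert list(derive_exposure_variables(moved)["E_quartile"]) == list(base["E_quartile"])

    def test_energy_imputed_by_study_sex_mean(self):
        df = pd.DataFrame(
            {
                "subject_id": ["a", "b", "c"],
                "study": "S",
                "sex": "male",
                "met_hours_week": [5.0, 10.0, 20.0],
                "energy_kcal": [1800.0, 2000.0, np.nan],
            }
        )
        out = derive_exposure_variables(df)
        assert out["energy_kcal"].iloc[2] == pytest.approx(1900.0)

    def test_all_missing_energy_cell_left_missing(self):
        df = pd.DataFrame(
            {
                "subject_id": ["a", "b"],
                "study": "S",
                "sex": "male",
                "met_hours_week": [5.0, 10.0],
                "energy_kcal": [np.nan, np.nan],
            }
        )
        out = derive_exposure_variables(df)
        assert out["energy_kcal"].isna().all()
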