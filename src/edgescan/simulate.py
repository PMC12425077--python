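"""Synthetic multi-study case-control cohorts for gene-environment scans.

The generator emulates the statistical substrate a genome-wide
gene-by-physical-activity interaction study rests on: biallelic common-variant
dosages in [0, 2] under Hardy-Weinberg equilibrium with block LD, a
right-skewed weekly physical-activity exposure dichotomised at 8.75 MET-h/wk
(about 76% active), a logistic disease model with genetic main, interaction
and optional gene-exposure-dependence effects, and case-control sampling
within each of several studies.

Exactly one SNP (``index_snp``) carries non-null effects; every other SNP is
a pure LD/noise column. Disease and exposure therefore depend on the genotype
matrix only through that single column, a fact :func:`simulate_study` exploits
to defer generation of the null columns until after case-control sampling.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from ._utils import check_finite, sigmoid, stage_rng

#: MET-h/wk cutoff separating "active" from "inactive"; ~150 min/wk of
#: moderate activity, the physical-activity guideline for cancer prevention.
ACTIVE_MET_CUTOFF = 8.75

#: Standard deviation of log MET-h/wk in the log-normal exposure model.
LOG_MET_SD = 1.0

COHORT_COLUMNS = [
    "subject_id",
    "study",
    "D",
    "met_hours_week",
    "E_binary",
    "E_quartile",
    "age",
    "sex",
    "energy_kcal",
    "bmi",
    "pc1",
    "pc2",
    "pc3",
]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic cohort generator.

    Effect sizes are on the log-odds scale. ``gamma_GE`` is the per-allele
    shift of the latent (log) exposure at the index SNP, the knob that makes
    genotype and exposure dependent in the source population.
    """

    seed: int = 0
    n_studies: int = 1
    n_cases: int = 1000
    n_controls: int = 1000
    n_snps: int = 100
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_rho: float = 0.0
    block_size: int = 10
    frac_imputed: float = 0.0
    target_rsq: float = 0.9
    beta0: float = -2.0
    beta_G: float = 0.0
    beta_E: float = 0.0
    beta_GxE: float = 0.0
    gamma_GE: float = 0.0
    beta_C: dict[str, float] = field(default_factory=dict)
    # Optional per-genotype exposure log-ORs (copies 0, 1, 2); overrides the
    # linear beta_E + beta_GxE*g parameterisation when set.
    beta_E_by_genotype: tuple[float, float, float] | None = None
    exposure_active_frac: float = 0.76
    index_snp: str | None = "snp_0"
    source_multiplier: int = 20

    def __post_init__(self):
        for name in ("n_studies", "n_cases", "n_controls", "n_snps", "block_size"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v > 0):
                raise ValueError(f"{name} must be a positive integer, got {v!r}")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError(f"maf_range must lie in (0, 1), got {self.maf_range}")
        if not 0.0 <= self.ld_rho < 1.0:
            raise ValueError(f"ld_rho must be in [0, 1), got {self.ld_rho}")
        if not 0.0 <= self.frac_imputed <= 1.0:
            raise ValueError(f"frac_imputed must be in [0, 1], got {self.frac_imputed}")
        if not 0.0 < self.target_rsq <= 1.0:
            raise ValueError(f"target_rsq must be in (0, 1], got {self.target_rsq}")
        if not 0.0 < self.exposure_active_frac < 1.0:
            raise ValueError("exposure_active_frac must be in (0, 1)")
        for name in ("beta0", "beta_G", "beta_E", "beta_GxE", "gamma_GE"):
            check_finite(name, getattr(self, name))
        for key, v in self.beta_C.items():
            check_finite(f"beta_C[{key}]", v)
        if self.gamma_GE != 0.0 and self.index_snp is None:
            raise ValueError("gamma_GE != 0 requires an index_snp")

    @property
    def snp_ids(self) -> list[str]:
        return [f"snp_{i}" for i in range(self.n_snps)]

    @property
    def source_size(self) -> int:
        return self.source_multiplier * self.n_studies * (self.n_cases + self.n_controls)


@dataclass
class GenotypeBlock:
    """Dosage matrix (subjects x SNPs) plus per-SNP metadata.

    ``dosages`` holds expected alternate-allele counts in [0, 2]. Genotyped
    SNPs carry exact hard calls in {0, 1, 2}; imputed SNPs carry noisy
    expectations whose squared correlation with the underlying genotype is
    the imputation R^2.
    """

    dosages: np.ndarray
    snp_meta: pd.DataFrame  # snp_id, chrom, pos, ref, alt, alt_freq, rsq, genotyped
    subject_ids: np.ndarray

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.subject_ids = np.asarray(self.subject_ids)
        if self.dosages.shape != (len(self.subject_ids), len(self.snp_meta)):
            raise ValueError("dosage matrix shape does not match metadata")
        if self.dosages.size and (self.dosages.min() < 0 or self.dosages.max() > 2):
            raise ValueError("dosages must lie in [0, 2]")
        if len(set(self.subject_ids)) != len(self.subject_ids):
            raise ValueError("subject ids must be unique")
        for chrom, grp in self.snp_meta.groupby("chrom"):
            if not grp["pos"].is_monotonic_increasing or grp["pos"].duplicated().any():
                raise ValueError(f"positions not strictly increasing on {chrom}")

    @property
    def n_subjects(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    @property
    def snp_ids(self) -> list[str]:
        return list(self.snp_meta["snp_id"])

    def column(self, snp_id: str) -> np.ndarray:
        idx = self.snp_meta.index[self.snp_meta["snp_id"] == snp_id]
        if len(idx) != 1:
            raise KeyError(f"SNP {snp_id!r} not present exactly once")
        return self.dosages[:, self.snp_meta.index.get_loc(idx[0])]

    def pooled_maf(self) -> np.ndarray:
        """Minor-allele frequency per SNP estimated from mean dosage."""
        af = self.dosages.mean(axis=0) / 2.0
        return np.minimum(af, 1.0 - af)

    def take_subjects(self, rows: np.ndarray) -> "GenotypeBlock":
        return GenotypeBlock(
            self.dosages[rows], self.snp_meta.reset_index(drop=True), self.subject_ids[rows]
        )

    def take_snps(self, cols: np.ndarray) -> "GenotypeBlock":
        return GenotypeBlock(
            self.dosages[:, cols],
            self.snp_meta.iloc[cols].reset_index(drop=True),
            self.subject_ids,
        )


class SimulationError(RuntimeError):
    pass


def _snp_metadata(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    lo, hi = config.maf_range
    mafs = rng.uniform(lo, hi, size=config.n_snps)
    pos = np.cumsum(rng.integers(500, 5000, size=config.n_snps))
    imputed = rng.random(config.n_snps) < config.frac_imputed
    return pd.DataFrame(
        {
            "snp_id": config.snp_ids,
            "chrom": "1",
            "pos": pos.astype(int),
            "ref": "A",
            "alt": "G",
            "alt_freq": mafs,
            "rsq": np.where(imputed, config.target_rsq, 1.0),
            "genotyped": ~imputed,
        }
    )


def _hard_calls_from_latent(latent: np.ndarray, alt_freq: np.ndarray) -> np.ndarray:
    """Threshold a pair of latent Gaussian haplotypes into allele counts.

    Thresholding each haplotype at the normal quantile of 1 - alt_freq makes
    every marginal genotype exactly HWE(alt_freq) regardless of the latent
    correlation that induces LD.
    """
    thresh = stats.norm.ppf(1.0 - alt_freq)
    return (latent[0] > thresh).astype(float) + (latent[1] > thresh).astype(float)


def _latent_haplotypes(
    n: int, n_snps: int, rho: float, block_size: int, rng: np.random.Generator
) -> np.ndarray:
    """Two independent latent haplotype fields with AR(1) LD within blocks."""
    z = rng.standard_normal((2, n, n_snps))
    if rho > 0:
        a = np.sqrt(1.0 - rho**2)
        for j in range(1, n_snps):
            if j % block_size != 0:  # block boundaries reset the chain
                z[:, :, j] = rho * z[:, :, j - 1] + a * z[:, :, j]
    return z


def _impute_noise(
    genotypes: np.ndarray, meta: pd.DataFrame, target_rsq: float, rng: np.random.Generator
) -> np.ndarray:
    """Degrade hard calls into noisy dosages matching the imputation R^2.

    Additive Gaussian noise with variance var(G) * (1 - r^2) / r^2 gives
    corr^2(dosage, genotype) = r^2 before clipping to [0, 2].
    """
    dosages = genotypes.astype(float).copy()
    imputed = ~meta["genotyped"].to_numpy()
    if imputed.any() and target_rsq < 1.0:
        p = meta.loc[imputed, "alt_freq"].to_numpy()
        var_g = 2.0 * p * (1.0 - p)
        sd = np.sqrt(var_g * (1.0 - target_rsq) / target_rsq)
        noise = rng.standard_normal((genotypes.shape[0], int(imputed.sum()))) * sd
        dosages[:, imputed] = np.clip(dosages[:, imputed] + noise, 0.0, 2.0)
    return dosages


def simulate_genotype_block(
    config: SimConfig, seed: int | None = None, n_subjects: int | None = None
) -> GenotypeBlock:
    """Draw a population genotype block under HWE with block LD.

    ``n_subjects`` defaults to the full case-control source population size.
    """
    seed = config.seed if seed is None else seed
    n = config.source_size if n_subjects is None else int(n_subjects)
    rng = stage_rng(seed, "genotypes")
    meta = _snp_metadata(config, rng)
    latent = _latent_haplotypes(n, config.n_snps, config.ld_rho, config.block_size, rng)
    genotypes = _hard_calls_from_latent(latent, meta["alt_freq"].to_numpy())
    dosages = _impute_noise(genotypes, meta, config.target_rsq, stage_rng(seed, "noise"))
    subject_ids = np.array([f"s{i:07d}" for i in range(n)])
    return GenotypeBlock(dosages, meta, subject_ids)


def _exposure_location(config: SimConfig, index_freq: float | None) -> float:
    """Root-find the log-normal location so P(MET >= 8.75) hits the target.

    The active fraction marginalises the per-allele latent shift over HWE
    genotype frequencies at the index SNP.
    """
    target = config.exposure_active_frac
    log_cut = np.log(ACTIVE_MET_CUTOFF)
    if config.gamma_GE == 0.0 or index_freq is None:
        return log_cut - LOG_MET_SD * stats.norm.ppf(1.0 - target)
    p = index_freq
    w = np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2])
    g = np.array([0.0, 1.0, 2.0])

    def active_frac(mu):
        return float(w @ stats.norm.sf(log_cut, loc=mu + config.gamma_GE * g, scale=LOG_MET_SD)) - target

    return optimize.brentq(active_frac, -50.0, 50.0)


def simulate_exposure(
    config: SimConfig, block: GenotypeBlock, seed: int | None = None
) -> np.ndarray:
    """Draw weekly MET-hours: log-normal, optionally genotype-dependent."""
    seed = config.seed if seed is None else seed
    rng = stage_rng(seed, "exposure")
    if config.gamma_GE != 0.0:
        if config.index_snp not in block.snp_ids:
            raise ValueError("gamma_GE != 0 but index_snp missing from block")
        g = block.column(config.index_snp)
        freq = float(block.snp_meta.set_index("snp_id").loc[config.index_snp, "alt_freq"])
    else:
        g = 0.0
        freq = None
    mu = _exposure_location(config, freq)
    log_met = mu + config.gamma_GE * g + LOG_MET_SD * rng.standard_normal(block.n_subjects)
    return np.exp(log_met)


def _draw_covariates(n: int, rng: np.random.Generator) -> pd.DataFrame:
    age = np.clip(rng.normal(63.0, 8.0, n), 40.0, 90.0)
    sex = rng.integers(0, 2, n)  # 1 = male
    energy = np.clip(rng.normal(1900.0, 700.0, n), 1.0, None)
    bmi = np.clip(rng.normal(27.0, 4.5, n), 15.0, None)
    pcs = rng.standard_normal((n, 3))
    return pd.DataFrame(
        {
            "age": age,
            "sex": sex,
            "energy_kcal": energy,
            "bmi": bmi,
            "pc1": pcs[:, 0],
            "pc2": pcs[:, 1],
            "pc3": pcs[:, 2],
        }
    )


def _disease_probability(
    config: SimConfig, g: np.ndarray, e_binary: np.ndarray, covars: pd.DataFrame
) -> np.ndarray:
    eta = np.full(len(covars), config.beta0)
    if config.beta_E_by_genotype is not None:
        betas = np.asarray(config.beta_E_by_genotype, dtype=float)
        strata = np.clip(np.rint(g), 0, 2).astype(int)
        eta = eta + config.beta_G * g + betas[strata] * e_binary
    else:
        eta = eta + config.beta_G * g + config.beta_E * e_binary + config.beta_GxE * g * e_binary
    for name, coef in config.beta_C.items():
        eta = eta + coef * covars[name].to_numpy()
    return sigmoid(eta)


def simulate_disease_and_sample(
    config: SimConfig,
    block: GenotypeBlock,
    exposure: np.ndarray,
    seed: int | None = None,
) -> tuple[pd.DataFrame, GenotypeBlock]:
    """Draw disease status and retain case/control quotas per study.

    Subjects are pre-assigned to studies in contiguous chunks of the source
    population; within each chunk exactly ``n_cases`` cases and ``n_controls``
    controls are kept (a SimulationError names the short stratum otherwise).
    """
    seed = config.seed if seed is None else seed
    if len(exposure) != block.n_subjects:
        raise ValueError("exposure not aligned with genotype block")
    rng_cov = stage_rng(seed, "covariates")
    rng_dis = stage_rng(seed, "disease")
    rng_samp = stage_rng(seed, "sampling")

    n = block.n_subjects
    covars = _draw_covariates(n, rng_cov)
    e_binary = (exposure >= ACTIVE_MET_CUTOFF).astype(int)
    g = block.column(config.index_snp) if config.index_snp in block.snp_ids else np.zeros(n)
    prob = _disease_probability(config, g, e_binary, covars)
    disease = (rng_dis.random(n) < prob).astype(int)

    study_of = np.arange(n) % config.n_studies
    keep_rows: list[np.ndarray] = []
    study_labels: list[np.ndarray] = []
    for s in range(config.n_studies):
        in_study = np.flatnonzero(study_of == s)
        cases = in_study[disease[in_study] == 1]
        controls = in_study[disease[in_study] == 0]
        if len(cases) < config.n_cases or len(controls) < config.n_controls:
            raise SimulationError(
                f"study {s}: source population exhausted "
                f"({len(cases)} cases / {len(controls)} controls available, "
                f"{config.n_cases}/{config.n_controls} requested); "
                "increase source_multiplier or adjust beta0"
            )
        picked = np.concatenate(
            [
                rng_samp.choice(cases, config.n_cases, replace=False),
                rng_samp.choice(controls, config.n_controls, replace=False),
            ]
        )
        picked.sort()
        keep_rows.append(picked)
        study_labels.append(np.full(len(picked), f"study_{s}", dtype=object))

    rows = np.concatenate(keep_rows)
    labels = np.concatenate(study_labels)
    cohort = pd.DataFrame(
        {
            "subject_id": block.subject_ids[rows],
            "study": labels,
            "D": disease[rows],
            "met_hours_week": exposure[rows],
        }
    )
    cohort = pd.concat([cohort, covars.iloc[rows].reset_index(drop=True)], axis=1)
    cohort["sex"] = np.where(cohort["sex"] == 1, "male", "female")
    cohort = derive_exposure_variables(cohort)
    return cohort[COHORT_COLUMNS], block.take_subjects(rows)


def derive_exposure_variables(cohort: pd.DataFrame) -> pd.DataFrame:
    """Derive the binary and quartile exposure codings; impute energy.

    E_binary is 1 iff MET-h/wk >= 8.75. Quartile codes 1-4 are assigned
    within each (study, sex) cell from MET ranks, so any order-preserving
    transform of MET leaves the coding unchanged. Missing total energy is
    replaced by the (study, sex) mean of observed values; cells with no
    observed energy are left missing.
    """
    out = cohort.copy()
    if "met_hours_week" not in out or out["met_hours_week"].isna().all():
        raise ValueError("met_hours_week required to derive exposure variables")
    out["E_binary"] = (out["met_hours_week"] >= ACTIVE_MET_CUTOFF).astype(int)

    def quartile_codes(met: pd.Series) -> pd.Series:
        ranks = met.rank(method="first")
        return np.ceil(ranks * 4.0 / len(met)).astype(int)

    out["E_quartile"] = (
        out.groupby(["study", "sex"], group_keys=False)["met_hours_week"]
        .apply(quartile_codes)
        .astype(int)
    )
    if "energy_kcal" in out:
        means = out.groupby(["study", "sex"])["energy_kcal"].transform("mean")
        out["energy_kcal"] = out["energy_kcal"].fillna(means)
    for col in COHORT_COLUMNS:
        if col not in out:
            out[col] = np.nan
    return out


def simulate_study(config: SimConfig, seed: int | None = None) -> tuple[pd.DataFrame, GenotypeBlock]:
    """End-to-end cohort simulation with deferred null-SNP generation.

    Disease and exposure depend on genotype only through the index SNP, so
    the source population is simulated with that single column; the remaining
    SNPs are drawn for the retained case-control subjects afterwards. The
    result has the same distribution as running the three-stage pipeline on
    the full source-population block, at a fraction of the memory and time.
    """
    seed = config.seed if seed is None else seed
    has_index = config.index_snp is not None and config.index_snp in config.snp_ids
    if has_index:
        index_cfg = dataclasses.replace(
            config, n_snps=1, index_snp="snp_0", ld_rho=0.0, frac_imputed=0.0
        )
        index_block = simulate_genotype_block(index_cfg, seed=seed)
        exposure = simulate_exposure(index_cfg, index_block, seed=seed)
        cohort, sampled_index = simulate_disease_and_sample(index_cfg, index_block, exposure, seed=seed)
    else:
        null_cfg = dataclasses.replace(config, n_snps=1, index_snp=None, gamma_GE=0.0)
        dummy = simulate_genotype_block(null_cfg, seed=seed)
        exposure = simulate_exposure(null_cfg, dummy, seed=seed)
        cohort, sampled_index = simulate_disease_and_sample(null_cfg, dummy, exposure, seed=seed)

    rest_cfg = dataclasses.replace(config, gamma_GE=0.0, index_snp=None)
    rest = simulate_genotype_block(rest_cfg, seed=seed + 1, n_subjects=len(cohort))
    meta = rest.snp_meta.copy()
    dosages = rest.dosages
    if has_index:
        # splice the causal column into its slot, keeping the drawn metadata
        idx = config.snp_ids.index(config.index_snp)
        dosages = dosages.copy()
        dosages[:, idx] = sampled_index.dosages[:, 0]
        meta.loc[idx, ["alt_freq", "rsq", "genotyped"]] = (
            sampled_index.snp_meta.loc[0, ["alt_freq", "rsq", "genotyped"]].to_numpy()
        )
    block = GenotypeBlock(dosages, meta, cohort["subject_id"].to_numpy())
    return cohort, block
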