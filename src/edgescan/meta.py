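"""Multi-study meta-analysis, genomic inflation, and stratified follow-up.

Study-specific exposure log-odds-ratios are pooled with a random-effects
model: DerSimonian-Laird between-study variance tau^2 and the Hartung-Knapp
variance estimator with t-based confidence intervals (k - 1 degrees of
freedom). Heterogeneity is summarised by Cochran's Q, its chi-square(k-1)
p-value and I^2 = max(0, 100 * (Q - df) / Q).

Genomic inflation lambda is the median association chi-square divided by the
null chi-square(1) median (~0.4549); lambda_1000 rescales it to an
equivalent study of 1000 cases and 1000 controls:

    lambda_1000 = 1 + (lambda - 1) * (1/n_cases + 1/n_controls) / (2/1000).

Stratified follow-up mirrors the usual presentation for an interaction hit:
exposure odds ratios within each (rounded) genotype stratum and per-allele
odds ratios within each exposure stratum, with displayed case/control counts
computed as expected counts from dosage-implied genotype probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .scan import ScanSpec, build_covariate_design, fit_logistic

#: median of the chi-square distribution with 1 d.f.
CHI2_1_MEDIAN = float(stats.chi2.ppf(0.5, 1))


@dataclass
class MetaResult:
    per_study: pd.DataFrame  # study, logOR, SE, n (n optional)
    logor: float
    se: float
    ci_low: float
    ci_high: float
    tau2: float
    Q: float
    Q_df: int
    p_het: float
    I2: float

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.logor))

    @property
    def or_ci(self) -> tuple[float, float]:
        return float(np.exp(self.ci_low)), float(np.exp(self.ci_high))


def hk_meta(per_study, conf_level: float = 0.95) -> MetaResult:
    """Random-effects pooling with Hartung-Knapp variance and t-based CI.

    ``per_study`` is a sequence of (logOR, SE) pairs or a DataFrame with
    ``logOR``/``SE`` columns. Requires at least two studies; a single study
    should be reported unpooled.
    """
    if isinstance(per_study, pd.DataFrame):
        theta = per_study["logOR"].to_numpy(dtype=float)
        se = per_study["SE"].to_numpy(dtype=float)
        table = per_study.copy()
    else:
        arr = np.asarray(per_study, dtype=float)
        theta, se = arr[:, 0], arr[:, 1]
        table = pd.DataFrame({"study": np.arange(len(theta)), "logOR": theta, "SE": se})
    k = len(theta)
    if k < 2:
        raise ValueError("meta-analysis needs >= 2 studies; report a single study unpooled")
    if not np.all(np.isfinite(theta)) or not np.all(np.isfinite(se)) or np.any(se <= 0):
        raise ValueError("per-study estimates and SEs must be finite with SE > 0")

    w_fixed = 1.0 / se**2
    theta_fixed = float(w_fixed @ theta / w_fixed.sum())
    Q = float(w_fixed @ (theta - theta_fixed) ** 2)
    df = k - 1
    c = w_fixed.sum() - (w_fixed**2).sum() / w_fixed.sum()
    tau2 = max(0.0, (Q - df) / c)

    w = 1.0 / (se**2 + tau2)
    pooled = float(w @ theta / w.sum())
    hk_var = float(w @ (theta - pooled) ** 2 / (df * w.sum()))
    hk_se = np.sqrt(hk_var)
    tq = stats.t.ppf(0.5 + conf_level / 2.0, df)
    I2 = max(0.0, 100.0 * (Q - df) / Q) if Q > 0 else 0.0
    return MetaResult(
        per_study=table,
        logor=pooled,
        se=hk_se,
        ci_low=pooled - tq * hk_se,
        ci_high=pooled + tq * hk_se,
        tau2=tau2,
        Q=Q,
        Q_df=df,
        p_het=float(stats.chi2.sf(Q, df)),
        I2=I2,
    )


class HartungKnappMeta(BaseEstimator):
    """Estimator interface over :func:`hk_meta`."""

    def __init__(self, conf_level: float = 0.95):
        self.conf_level = conf_level

    def fit(self, per_study, y=None) -> "HartungKnappMeta":
        r = hk_meta(per_study, conf_level=self.conf_level)
        self.result_ = r
        self.logor_ = r.logor
        self.se_ = r.se
        self.tau2_ = r.tau2
        self.I2_ = r.I2
        return self


@dataclass
class InflationStats:
    lam: float
    lambda_1000: float
    n_cases: int
    n_controls: int


def genomic_inflation(chi2: np.ndarray, n_cases: int, n_controls: int) -> InflationStats:
    """Genomic inflation factor and its 1000-case/1000-control rescaling."""
    chi2 = np.asarray(chi2, dtype=float)
    if chi2.size == 0:
        raise ValueError("need at least one chi-square value")
    if np.any(chi2 < 0):
        raise ValueError("chi-square values must be nonnegative")
    lam = float(np.median(chi2) / CHI2_1_MEDIAN)
    scale = (1.0 / n_cases + 1.0 / n_controls) / (1.0 / 1000 + 1.0 / 1000)
    return InflationStats(lam, 1.0 + (lam - 1.0) * scale, int(n_cases), int(n_controls))


def qq_points(p: np.ndarray) -> pd.DataFrame:
    """Expected vs. observed -log10 p for a Q-Q plot (no plotting here)."""
    p = np.asarray(p, dtype=float)
    if np.any(p > 1) or np.any(p < 0):
        raise ValueError("p-values must be in [0, 1]")
    if np.any(p == 0):
        import warnings

        warnings.warn("p = 0 clipped to smallest positive float")
        p = np.clip(p, np.finfo(float).tiny, None)
    m = len(p)
    observed = np.sort(p)
    expected = np.arange(1, m + 1) / (m + 1.0)
    return pd.DataFrame(
        {"expected_neglog10": -np.log10(expected), "observed_neglog10": -np.log10(observed)}
    )


def _crude_or(a: float, b: float, c: float, d: float) -> tuple[float, float, float, bool]:
    """Cross-product OR with Woolf CI; Haldane-Anscombe 0.5 on zero cells."""
    corrected = min(a, b, c, d) == 0
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    logor = np.log(a * d / (b * c))
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return float(np.exp(logor)), float(np.exp(logor - 1.96 * se)), float(np.exp(logor + 1.96 * se)), corrected


def _genotype_probs(dosage: np.ndarray) -> np.ndarray:
    """Per-subject genotype probabilities implied by a dosage in [0, 2].

    A dosage d <= 1 is read as P(het) = d, P(ref-hom) = 1 - d; d > 1 as
    P(alt-hom) = d - 1, P(het) = 2 - d. Exact for hard calls.
    """
    d = np.asarray(dosage, dtype=float)
    probs = np.zeros((len(d), 3))
    lo = d <= 1.0
    probs[lo, 0] = 1.0 - d[lo]
    probs[lo, 1] = d[lo]
    probs[~lo, 1] = 2.0 - d[~lo]
    probs[~lo, 2] = d[~lo] - 1.0
    return probs


@dataclass
class StratifiedOrTable:
    by_genotype: pd.DataFrame  # exposure ORs within genotype strata
    by_exposure: pd.DataFrame  # per-allele ORs within exposure strata


def _exposure_levels(cohort: pd.DataFrame, exposure: str):
    if exposure == "binary":
        return cohort["E_binary"].to_numpy(dtype=float), [0, 1], ["inactive", "active"]
    if exposure == "quartile":
        return cohort["E_quartile"].to_numpy(dtype=float), [1, 2, 3, 4], ["Q1", "Q2", "Q3", "Q4"]
    raise ValueError(f"unknown exposure {exposure!r}")


def stratified_or_table(
    cohort: pd.DataFrame,
    dosage: np.ndarray,
    exposure: str = "binary",
    spec: ScanSpec | None = None,
) -> StratifiedOrTable:
    """Genotype-stratified exposure ORs and exposure-stratified per-allele ORs.

    Genotype strata are formed by rounding the dosage to the nearest integer
    for model fits; the displayed case/control counts are expected counts
    under the dosage-implied genotype probabilities. Within each genotype
    stratum the exposure OR comes from an adjusted logistic fit (reference:
    inactive, or Q1 for the quartile coding); crude cross-product ORs with
    Woolf CIs are emitted alongside for checking.
    """
    spec = spec or ScanSpec(exposure=exposure)
    dosage = np.asarray(dosage, dtype=float)
    if len(dosage) != len(cohort):
        raise ValueError("dosage not aligned to cohort")
    y = cohort["D"].to_numpy(dtype=float)
    e, levels, labels = _exposure_levels(cohort, exposure)
    strata = np.clip(np.rint(dosage), 0, 2).astype(int)
    probs = _genotype_probs(dosage)

    geno_rows = []
    for gcode, gname in zip((0, 1, 2), ("0 copies", "1 copy", "2 copies")):
        in_g = strata == gcode
        pg = probs[:, gcode]
        for lev, lab in zip(levels, labels):
            in_lev = e == lev
            n_case = float(pg[in_lev & (y == 1)].sum())
            n_ctrl = float(pg[in_lev & (y == 0)].sum())
            row = {
                "genotype": gname, "exposure": lab,
                "n_cases": n_case, "n_controls": n_ctrl,
                "OR": np.nan, "ci_low": np.nan, "ci_high": np.nan, "p": np.nan,
                "crude_OR": np.nan, "crude_ci_low": np.nan, "crude_ci_high": np.nan,
                "zero_cell_corrected": False,
            }
            if lev == levels[0]:
                row["OR"] = 1.0  # reference category
            else:
                sub = cohort[in_g]
                if len(sub) and sub["D"].nunique() == 2:
                    e_sub = e[in_g]
                    mask = (e_sub == lev) | (e_sub == levels[0])
                    sub2 = sub[mask]
                    if len(sub2) and sub2["D"].nunique() == 2 and len(np.unique(e_sub[mask])) == 2:
                        C, _ = build_covariate_design(sub2, spec)
                        X = np.column_stack([C, (e_sub[mask] == lev).astype(float)])
                        try:
                            fr = fit_logistic(sub2["D"].to_numpy(float), X, check_rank=False)
                            if fr.converged:
                                b, v = fr.beta[-1], fr.cov[-1, -1]
                                with np.errstate(over="ignore"):
                                    row["OR"] = float(np.exp(b))
                                    row["ci_low"] = float(np.exp(b - 1.96 * np.sqrt(v)))
                                    row["ci_high"] = float(np.exp(b + 1.96 * np.sqrt(v)))
                                row["p"] = float(stats.chi2.sf(b**2 / v, 1))
                        except Exception:
                            pass
                    a = float(np.sum(in_g & (e == lev) & (y == 1)))
                    b_ = float(np.sum(in_g & (e == lev) & (y == 0)))
                    c_ = float(np.sum(in_g & (e == levels[0]) & (y == 1)))
                    d_ = float(np.sum(in_g & (e == levels[0]) & (y == 0)))
                    if (a + b_) > 0 and (c_ + d_) > 0:
                        or_, lo_, hi_, corr = _crude_or(a, b_, c_, d_)
                        row.update(
                            crude_OR=or_, crude_ci_low=lo_, crude_ci_high=hi_,
                            zero_cell_corrected=corr,
                        )
            geno_rows.append(row)

    expo_rows = []
    for lev, lab in zip(levels, labels):
        in_lev = e == lev
        row = {"exposure": lab, "per_allele_OR": np.nan, "ci_low": np.nan,
               "ci_high": np.nan, "p": np.nan}
        sub = cohort[in_lev]
        if len(sub) and sub["D"].nunique() == 2 and dosage[in_lev].std() > 0:
            C, _ = build_covariate_design(sub, spec)
            X = np.column_stack([C, dosage[in_lev]])
            try:
                fr = fit_logistic(sub["D"].to_numpy(float), X, check_rank=False)
                if fr.converged:
                    b, v = fr.beta[-1], fr.cov[-1, -1]
                    row.update(
                        per_allele_OR=float(np.exp(b)),
                        ci_low=float(np.exp(b - 1.96 * np.sqrt(v))),
                        ci_high=float(np.exp(b + 1.96 * np.sqrt(v))),
                        p=float(stats.chi2.sf(b**2 / v, 1)),
                    )
            except Exception:
                pass
        expo_rows.append(row)

    return StratifiedOrTable(pd.DataFrame(geno_rows), pd.DataFrame(expo_rows))


def per_study_exposure_effects(
    cohort: pd.DataFrame, spec: ScanSpec | None = None
) -> pd.DataFrame:
    """Adjusted exposure logOR and SE per study (input to :func:`hk_meta`)."""
    spec = spec or ScanSpec()
    spec = ScanSpec(
        exposure=spec.exposure, covariates=spec.covariates,
        include_study_indicators=False,
        include_bmi_interactions=spec.include_bmi_interactions,
    )
    rows = []
    for study, sub in cohort.groupby("study", sort=True):
        sub = sub.reset_index(drop=True)
        e = (sub["E_binary"] if spec.exposure == "binary" else sub["E_quartile"]).to_numpy(float)
        C, _ = build_covariate_design(sub, spec)
        X = np.column_stack([C, e])
        fr = fit_logistic(sub["D"].to_numpy(float), X, check_rank=False)
        rows.append(
            {
                "study": study,
                "logOR": float(fr.beta[-1]),
                "SE": float(np.sqrt(fr.cov[-1, -1])),
                "n": len(sub),
                "converged": fr.converged,
            }
        )
    return pd.DataFrame(rows)
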