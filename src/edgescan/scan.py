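"""Per-SNP association models and test statistics for GxE discovery scans.

For each SNP G, binary disease D, exposure E (active/inactive or quartile
1-4 treated as continuous) and adjustment covariates C, the scan fits:

* the interaction model  logit P(D=1) = b0 + bG*G + bE*E + bGxE*G*E + bC*C,
  giving the 1-d.f. Wald test of bGxE = 0 (departure from multiplicative
  joint effects);
* the marginal model  logit P(D=1) = b0 + bG*G + bC*C, giving the marginal
  disease-gene chi-square;
* the gene-environment model  G = c0 + gamma_G*E + c*C  by least squares in
  the combined case-control sample, giving the 1-d.f. gamma_G chi-square.

From these it assembles the joint 3-d.f. test of bG = bGxE = gamma_G = 0
(2-d.f. Wald on (bG, bGxE) plus the gamma_G chi-square, combined as
independent chi-squares) and the 2-d.f. screening statistic used as step 1
of the two-step weighted testing procedure (marginal D-G plus G-E
chi-squares) -- a ranking statistic independent of the step-2 GxE test
under the null.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from ._utils import sigmoid
from .simulate import GenotypeBlock

DEFAULT_COVARIATES = ("age", "sex", "energy_kcal", "pc1", "pc2", "pc3")

MAX_ABS_COEF = 30.0  # larger log-odds indicate separation, not signal


class EstimationError(RuntimeError):
    pass


@dataclass
class FitResult:
    beta: np.ndarray
    cov: np.ndarray
    loglik: float
    converged: bool
    n_iter: int


def _loglik(y: np.ndarray, eta: np.ndarray) -> float:
    # log L = y'eta - sum log(1 + e^eta), computed without overflow
    return float(y @ eta - np.logaddexp(0.0, eta).sum())


def _name_collinear_columns(X: np.ndarray, names: list[str] | None) -> list[str]:
    from scipy.linalg import qr

    _, r, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    bad = piv[np.sum(diag > tol):]
    if names is None:
        names = [f"x{j}" for j in range(X.shape[1])]
    return [names[j] for j in bad]


def fit_logistic(
    y: np.ndarray,
    X: np.ndarray,
    start: np.ndarray | None = None,
    max_iter: int = 50,
    score_tol: float = 1e-8,
    ll_tol: float = 1e-10,
    column_names: list[str] | None = None,
    check_rank: bool = True,
) -> FitResult:
    """Maximum-likelihood logistic regression by IRLS.

    Converged when the maximum absolute score drops below ``score_tol`` or
    the relative log-likelihood change below ``ll_tol``; runaway coefficients
    (|beta| > 30, the signature of separation) or hitting the iteration cap
    return ``converged=False`` with the last iterate.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("response must be binary 0/1")
    if check_rank and np.linalg.matrix_rank(X) < X.shape[1]:
        bad = _name_collinear_columns(X, column_names)
        raise EstimationError(f"design matrix is rank deficient; collinear columns: {bad}")

    beta = np.zeros(X.shape[1]) if start is None else np.asarray(start, dtype=float).copy()
    eta = X @ beta
    ll = _loglik(y, eta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        mu = sigmoid(eta)
        score = X.T @ (y - mu)
        if np.abs(score).max() < score_tol:
            converged = True
            break
        w = np.clip(mu * (1.0 - mu), 1e-12, None)
        xtwx = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(xtwx, score)
        except np.linalg.LinAlgError as exc:
            raise EstimationError(f"singular weighted information matrix: {exc}") from exc
        # step-halving keeps IRLS monotone on badly scaled designs
        for _ in range(20):
            cand = beta + step
            eta_c = X @ cand
            ll_c = _loglik(y, eta_c)
            if ll_c >= ll - 1e-12:
                break
            step = step / 2.0
        beta, eta = cand, eta_c
        if np.abs(beta).max() > MAX_ABS_COEF:
            converged = False
            break
        if abs(ll_c - ll) < ll_tol * (abs(ll) + 1e-12):
            converged = True
            ll = ll_c
            break
        ll = ll_c

    mu = sigmoid(eta)
    w = np.clip(mu * (1.0 - mu), 1e-12, None)
    xtwx = (X * w[:, None]).T @ X
    try:
        cov = np.linalg.inv(xtwx)
    except np.linalg.LinAlgError:
        cov = np.full_like(xtwx, np.nan)
        converged = False
    return FitResult(beta=beta, cov=cov, loglik=_loglik(y, eta), converged=converged, n_iter=it)


def combine_chi2(stats_vec, dfs) -> float:
    """Upper-tail p-value of a sum of independent chi-square statistics."""
    s = np.asarray(stats_vec, dtype=float)
    d = np.asarray(dfs, dtype=int)
    if s.size == 0 or s.size != d.size:
        raise ValueError("stats and dfs must be non-empty and equal length")
    if np.any(~np.isfinite(s)) or np.any(s < 0):
        raise ValueError(f"chi-square statistics must be finite and nonnegative, got {stats_vec}")
    return float(stats.chi2.sf(s.sum(), d.sum()))


@dataclass(frozen=True)
class ScanSpec:
    """Model options for the per-SNP scan."""

    exposure: str = "binary"  # "binary" or "quartile" (continuous 1-4)
    covariates: tuple[str, ...] = DEFAULT_COVARIATES
    include_study_indicators: bool = True
    include_bmi_interactions: bool = False

    def __post_init__(self):
        if self.exposure not in ("binary", "quartile"):
            raise ValueError(f"exposure must be 'binary' or 'quartile', got {self.exposure!r}")


def _exposure_vector(cohort: pd.DataFrame, spec: ScanSpec) -> np.ndarray:
    col = "E_binary" if spec.exposure == "binary" else "E_quartile"
    return cohort[col].to_numpy(dtype=float)


def build_covariate_design(cohort: pd.DataFrame, spec: ScanSpec) -> tuple[np.ndarray, list[str]]:
    """Intercept + covariates (+ study indicators), continuous ones centred."""
    n = len(cohort)
    cols: list[np.ndarray] = [np.ones(n)]
    names = ["intercept"]
    for c in spec.covariates:
        if c not in cohort.columns:
            continue
        v = cohort[c]
        if c == "sex":
            x = (v == "male").to_numpy(dtype=float) if v.dtype == object else v.to_numpy(float)
        else:
            x = v.to_numpy(dtype=float)
        if np.isnan(x).any():
            continue  # covariate unavailable for some subjects: drop from adjustment
        if c not in ("sex",):
            s = x.std()
            x = (x - x.mean()) / (s if s > 0 else 1.0)
        cols.append(x)
        names.append(c)
    if spec.include_study_indicators:
        studies = sorted(cohort["study"].unique())
        for s in studies[1:]:
            cols.append((cohort["study"] == s).to_numpy(dtype=float))
            names.append(f"study[{s}]")
    if spec.include_bmi_interactions and "bmi" in cohort.columns:
        b = cohort["bmi"].to_numpy(dtype=float)
        if not np.isnan(b).any():
            b = (b - b.mean()) / b.std()
            cols.append(b)
            names.append("bmi")
    return np.column_stack(cols), names


def _gamma_ge_stats(C: np.ndarray, e: np.ndarray, G: np.ndarray):
    """Vectorised OLS of every dosage column on exposure plus covariates."""
    Z = np.column_stack([C, e])
    ztz_inv = np.linalg.inv(Z.T @ Z)
    coefs = ztz_inv @ (Z.T @ G)  # (k+1) x m
    resid = G - Z @ coefs
    dof = Z.shape[0] - Z.shape[1]
    sigma2 = (resid**2).sum(axis=0) / dof
    var_gamma = sigma2 * ztz_inv[-1, -1]
    gamma = coefs[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(var_gamma > 0, gamma**2 / var_gamma, np.nan)
    return gamma, np.sqrt(var_gamma), chi2


_RECORD_COLUMNS = [
    "snp_id", "chrom", "pos",
    "beta_G", "se_G", "beta_E", "se_E", "beta_GxE", "se_GxE",
    "gamma_G", "se_gamma",
    "chi2_DG", "chi2_EG", "chi2_GxE",
    "p_DG", "p_EG", "p_GxE_1df", "p_joint_3df", "p_step1",
    "converged",
]


def _nan_record(snp_id, chrom, pos):
    rec = dict.fromkeys(_RECORD_COLUMNS, np.nan)
    rec.update(snp_id=snp_id, chrom=chrom, pos=pos, converged=False)
    return rec


def _scan_one(
    y: np.ndarray,
    C: np.ndarray,
    e: np.ndarray,
    g: np.ndarray,
    gamma_tuple,
    snp_id: str,
    chrom: str,
    pos: int,
    start_full: np.ndarray,
    start_marg: np.ndarray,
    bmi: np.ndarray | None,
) -> dict:
    mac = min(g.sum(), 2 * len(g) - g.sum())  # minor-dosage count
    if g.std() == 0.0 or mac < 2:
        return _nan_record(snp_id, chrom, pos)
    k = C.shape[1]
    X_full = np.column_stack([C, g, e, g * e])
    if bmi is not None:
        X_full = np.column_stack([X_full, g * bmi, e * bmi])
    X_marg = np.column_stack([C, g])
    try:
        full = fit_logistic(y, X_full, start=start_full, check_rank=False)
        marg = fit_logistic(y, X_marg, start=start_marg, check_rank=False)
    except EstimationError:
        return _nan_record(snp_id, chrom, pos)
    gamma, se_gamma, chi2_eg = gamma_tuple
    if not (full.converged and marg.converged):
        rec = _nan_record(snp_id, chrom, pos)
        rec.update(gamma_G=gamma, se_gamma=se_gamma, chi2_EG=chi2_eg)
        return rec

    bG_m, vG_m = marg.beta[k], marg.cov[k, k]
    chi2_dg = bG_m**2 / vG_m
    bE, vE = full.beta[k + 1], full.cov[k + 1, k + 1]
    bGxE, vGxE = full.beta[k + 2], full.cov[k + 2, k + 2]
    chi2_gxe = bGxE**2 / vGxE
    # 2-d.f. Wald on (bG, bGxE) in the interaction model
    idx = [k, k + 2]
    b2 = full.beta[idx]
    V2 = full.cov[np.ix_(idx, idx)]
    chi2_2df = float(b2 @ np.linalg.solve(V2, b2))

    p_dg = float(stats.chi2.sf(chi2_dg, 1))
    p_eg = float(stats.chi2.sf(chi2_eg, 1)) if np.isfinite(chi2_eg) else np.nan
    p_gxe = float(stats.chi2.sf(chi2_gxe, 1))
    p_joint = (
        combine_chi2([chi2_2df, chi2_eg], [2, 1]) if np.isfinite(chi2_eg) else np.nan
    )
    p_step1 = (
        combine_chi2([chi2_dg, chi2_eg], [1, 1]) if np.isfinite(chi2_eg) else np.nan
    )
    return {
        "snp_id": snp_id, "chrom": chrom, "pos": pos,
        "beta_G": full.beta[k], "se_G": np.sqrt(full.cov[k, k]),
        "beta_E": bE, "se_E": np.sqrt(vE),
        "beta_GxE": bGxE, "se_GxE": np.sqrt(vGxE),
        "gamma_G": gamma, "se_gamma": se_gamma,
        "chi2_DG": chi2_dg, "chi2_EG": chi2_eg, "chi2_GxE": chi2_gxe,
        "p_DG": p_dg, "p_EG": p_eg, "p_GxE_1df": p_gxe,
        "p_joint_3df": p_joint, "p_step1": p_step1,
        "converged": True,
    }


def scan_snp(cohort: pd.DataFrame, dosage: np.ndarray, spec: ScanSpec = ScanSpec()) -> dict:
    """Fit all single-SNP models for one dosage vector; returns a record dict."""
    dosage = np.asarray(dosage, dtype=float)
    if len(dosage) != len(cohort):
        raise ValueError("dosage not aligned to cohort")
    y = cohort["D"].to_numpy(dtype=float)
    C, _ = build_covariate_design(cohort, spec)
    e = _exposure_vector(cohort, spec)
    gamma_tuple = tuple(np.asarray(v).item() for v in _gamma_ge_stats(C, e, dosage[:, None]))
    base = fit_logistic(y, C, check_rank=False)
    bmi = None
    if spec.include_bmi_interactions and "bmi" in cohort.columns:
        b = cohort["bmi"].to_numpy(dtype=float)
        if not np.isnan(b).any():
            bmi = (b - b.mean()) / b.std()
    start_full = np.concatenate([base.beta, np.zeros(3 + (2 if bmi is not None else 0))])
    start_marg = np.concatenate([base.beta, [0.0]])
    return _scan_one(
        y, C, e, dosage, gamma_tuple, "snp", "NA", 0, start_full, start_marg, bmi
    )


def genome_scan(
    cohort: pd.DataFrame,
    block: GenotypeBlock,
    spec: ScanSpec = ScanSpec(),
    chunk_size: int | None = None,
) -> pd.DataFrame:
    """Run the per-SNP scan over a whole genotype block.

    Results are ordered by (chromosome, position) and are identical whether
    computed in one pass or in chunks (each SNP's fit is independent).
    """
    if not np.array_equal(block.subject_ids, cohort["subject_id"].to_numpy()):
        raise ValueError("genotype block subject ids are misaligned with the cohort")
    meta = block.snp_meta
    order = np.lexsort((meta["pos"].to_numpy(), meta["chrom"].to_numpy()))
    if block.n_snps == 0:
        return pd.DataFrame(columns=_RECORD_COLUMNS)

    y = cohort["D"].to_numpy(dtype=float)
    C, _ = build_covariate_design(cohort, spec)
    e = _exposure_vector(cohort, spec)
    base = fit_logistic(y, C, check_rank=False)
    bmi = None
    if spec.include_bmi_interactions and "bmi" in cohort.columns:
        b = cohort["bmi"].to_numpy(dtype=float)
        if not np.isnan(b).any():
            bmi = (b - b.mean()) / b.std()
    start_full = np.concatenate([base.beta, np.zeros(3 + (2 if bmi is not None else 0))])
    start_marg = np.concatenate([base.beta, [0.0]])

    gammas, se_gammas, chi2_egs = _gamma_ge_stats(C, e, block.dosages)

    records = []
    for j in order:
        rec = _scan_one(
            y, C, e, block.dosages[:, j],
            (gammas[j], se_gammas[j], chi2_egs[j]),
            meta["snp_id"].iat[j], str(meta["chrom"].iat[j]), int(meta["pos"].iat[j]),
            start_full, start_marg, bmi,
        )
        records.append(rec)
    return pd.DataFrame(records, columns=_RECORD_COLUMNS)


def edge_step1_p(record: dict | pd.Series) -> float:
    """Step-1 screening p-value: marginal D-G plus G-E chi-squares, 2 d.f."""
    c1, c2 = record["chi2_DG"], record["chi2_EG"]
    if not (np.isfinite(c1) and np.isfinite(c2)):
        return np.nan
    return combine_chi2([c1, c2], [1, 1])


class GenomeScanner(BaseEstimator):
    """Estimator wrapper around :func:`genome_scan`.

    After ``fit(cohort, block)``, ``records_`` holds one row per SNP with
    coefficients, standard errors, chi-squares and p-values for the 1-d.f.
    GxE, marginal, G-E, joint 3-d.f. and step-1 screening tests.
    """

    def __init__(self, exposure: str = "binary",
                 covariates: tuple[str, ...] = DEFAULT_COVARIATES,
                 include_study_indicators: bool = True,
                 include_bmi_interactions: bool = False):
        self.exposure = exposure
        self.covariates = covariates
        self.include_study_indicators = include_study_indicators
        self.include_bmi_interactions = include_bmi_interactions

    def _spec(self) -> ScanSpec:
        return ScanSpec(
            exposure=self.exposure,
            covariates=tuple(self.covariates),
            include_study_indicators=self.include_study_indicators,
            include_bmi_interactions=self.include_bmi_interactions,
        )

    def fit(self, cohort: pd.DataFrame, block: GenotypeBlock) -> "GenomeScanner":
        self.records_ = genome_scan(cohort, block, self._spec())
        return self
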