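"""Two-step weighted hypothesis testing (EDGE-style) for GxE scans.

Step 1 ranks SNPs by an independent screening p-value; step 2 tests GxE with
bin-specific significance thresholds. Rather than fixed-size rank bins, SNPs
are partitioned by step-1 p-value thresholds *in expectation*: with an
assumed count ``m_expected`` of independent uniform tests and an initial bin
size ``B``, bin j nominally holds B * 2^(j-1) SNPs, so its p-value interval
is (B(2^(j-1) - 1)/m, B(2^j - 1)/m]. The overall significance budget
``alpha`` is split geometrically (alpha_j = alpha * 2^-j), and within each
bin the threshold divides the budget by the *effective* number of tests
m_eff, estimated from the eigenvalues of the bin's SNP-SNP correlation
matrix (smallest k capturing >= 99.5% of total variance, the simpleM
convention). This keeps LD-packed top bins from paying a full Bonferroni
price while preserving family-wise error control at alpha.

For every SNP a two-step p-value p* = p2 * m_eff_j * 2^j / m_expected is
reported; p* <= alpha/m_expected exactly when the SNP is rejected, making
p* directly comparable to the usual genome-wide threshold (5e-8 when
alpha = 0.05 and m_expected = 1e6).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .simulate import GenotypeBlock


@dataclass
class EdgeBinning:
    """The weighted-testing partition of step-1 p-values."""

    alpha: float
    B: int
    m_expected: float
    upper: np.ndarray  # per-bin upper p boundary, last capped at 1
    budgets: np.ndarray  # alpha_j = alpha * 2^-j
    assignments: np.ndarray  # bin index (0-based) per SNP, in input order
    counts: np.ndarray
    m_eff: np.ndarray | None = None
    thresholds: np.ndarray | None = None

    @property
    def n_bins(self) -> int:
        return len(self.upper)

    @property
    def lower(self) -> np.ndarray:
        return np.concatenate([[0.0], self.upper[:-1]])

    @property
    def nominal_sizes(self) -> np.ndarray:
        return self.B * 2 ** np.arange(self.n_bins)

    def summary(self) -> pd.DataFrame:
        d = {
            "bin": np.arange(1, self.n_bins + 1),
            "p_lower": self.lower,
            "p_upper": self.upper,
            "nominal_size": self.nominal_sizes,
            "n_snps": self.counts,
            "budget": self.budgets,
        }
        if self.m_eff is not None:
            d["m_eff"] = self.m_eff
            d["threshold"] = self.thresholds
        return pd.DataFrame(d)


def build_bins(
    step1_p: np.ndarray, alpha: float = 0.05, B: int = 5, m_expected: float = 1e6
) -> EdgeBinning:
    """Partition SNPs into expectation-based bins from step-1 p-values.

    Bin j (1-based) covers (B(2^(j-1)-1)/m, B(2^j -1)/m], the interval a
    uniform p-value falls in with probability sized to the nominal bin count.
    Missing step-1 p-values go to the final bin. The number of bins is the
    smallest J with B(2^J - 1) >= m_expected; the residual geometric budget
    alpha * 2^-J is left unallocated, so sum(budgets) < alpha.
    """
    if alpha <= 0 or B <= 0 or m_expected <= 0:
        raise ValueError("alpha, B and m_expected must be positive")
    p = np.asarray(step1_p, dtype=float)
    if np.nanmin(p, initial=0.0) < 0 or np.nanmax(p, initial=0.0) > 1:
        raise ValueError("step-1 p-values must lie in [0, 1]")
    n_bins = 1
    while B * (2**n_bins - 1) < m_expected:
        n_bins += 1
    j = np.arange(1, n_bins + 1)
    upper = np.minimum(B * (2.0**j - 1.0) / m_expected, 1.0)
    budgets = alpha * 2.0 ** (-j.astype(float))
    # interval membership (lower, upper]: index of first boundary >= p
    assignments = np.searchsorted(upper, p, side="left")
    assignments = np.where(np.isnan(p), n_bins - 1, assignments)
    assignments = np.minimum(assignments, n_bins - 1).astype(int)
    counts = np.bincount(assignments, minlength=n_bins)
    return EdgeBinning(
        alpha=alpha, B=B, m_expected=float(m_expected),
        upper=upper, budgets=budgets, assignments=assignments, counts=counts,
    )


def m_eff_from_corr(corr: np.ndarray, eigen_fraction: float = 0.995) -> int:
    """Smallest k whose top-k eigenvalues reach ``eigen_fraction`` of variance."""
    eigvals = np.linalg.eigvalsh(np.asarray(corr, dtype=float))[::-1]
    eigvals = np.clip(eigvals, 0.0, None)
    frac = np.cumsum(eigvals) / eigvals.sum()
    return int(np.searchsorted(frac, eigen_fraction - 1e-12) + 1)


def effective_tests(dosage_submatrix: np.ndarray, eigen_fraction: float = 0.995) -> int:
    """Effective number of independent tests among a bin's SNPs.

    The smallest k such that the top-k eigenvalues of the SNP-SNP correlation
    matrix account for at least ``eigen_fraction`` of the total variance.
    Zero-variance columns are dropped with a warning.
    """
    X = np.asarray(dosage_submatrix, dtype=float)
    if X.ndim != 2 or X.shape[1] == 0:
        raise ValueError("submatrix must have at least one SNP column")
    sd = X.std(axis=0)
    if np.any(sd == 0):
        warnings.warn("dropping zero-variance SNP columns before eigen-decomposition")
        X = X[:, sd > 0]
        if X.shape[1] == 0:
            return 1
    if X.shape[1] == 1:
        return 1
    return m_eff_from_corr(np.corrcoef(X, rowvar=False), eigen_fraction)


def compute_bin_m_eff(
    binning: EdgeBinning, block: GenotypeBlock, eigen_fraction: float = 0.995
) -> EdgeBinning:
    """Fill per-bin effective test counts and thresholds from genotype data."""
    m_eff = np.zeros(binning.n_bins, dtype=int)
    for j in range(binning.n_bins):
        cols = np.flatnonzero(binning.assignments == j)
        if len(cols) == 0:
            continue
        m_eff[j] = effective_tests(block.dosages[:, cols], eigen_fraction)
    with np.errstate(divide="ignore"):
        thresholds = np.where(m_eff > 0, binning.budgets / np.maximum(m_eff, 1), 0.0)
    binning.m_eff = m_eff
    binning.thresholds = thresholds
    return binning


def apply_weighted_test(records: pd.DataFrame, binning: EdgeBinning) -> pd.DataFrame:
    """Per-SNP decisions and two-step p-values from a filled binning.

    A SNP in bin j is rejected iff its step-2 GxE p-value is at most
    tau_j = alpha_j / m_eff_j, and its reported two-step p-value is
    p* = p2 * m_eff_j * 2^j / m_expected so that p* <= alpha/m_expected
    exactly characterises rejection. SNPs with missing step-1 or step-2
    p-values are never rejected.
    """
    if binning.m_eff is None or binning.thresholds is None:
        raise ValueError("binning has no effective-test counts; run compute_bin_m_eff first")
    if len(records) != len(binning.assignments):
        raise ValueError("scan table and binning cover different SNP sets")
    j0 = binning.assignments  # 0-based
    p2 = records["p_GxE_1df"].to_numpy(dtype=float)
    tau = binning.thresholds[j0]
    m_eff = np.maximum(binning.m_eff, 1)[j0]
    with np.errstate(over="ignore"):
        p_star = p2 * m_eff * 2.0 ** (j0 + 1) / binning.m_expected
    valid = np.isfinite(p2) & np.isfinite(records["p_step1"].to_numpy(dtype=float))
    reject = valid & (p2 <= tau)
    out = pd.DataFrame(
        {
            "snp_id": records["snp_id"].to_numpy(),
            "bin": j0 + 1,
            "p_step1": records["p_step1"].to_numpy(dtype=float),
            "p_GxE_1df": p2,
            "m_eff": m_eff,
            "threshold": tau,
            "p_two_step": np.where(valid, p_star, np.nan),
            "reject": reject,
        }
    )
    order = np.lexsort(
        (records["pos"].to_numpy() if "pos" in records else np.arange(len(out)),
         records["chrom"].to_numpy() if "chrom" in records else np.zeros(len(out)),
         np.where(np.isfinite(out["p_step1"]), out["p_step1"], np.inf))
    )
    return out.iloc[order].reset_index(drop=True)


class EdgeWeightedTester(BaseEstimator):
    """Estimator interface for the full two-step weighted testing stage.

    ``fit(records, block)`` builds the expectation-based bins from the scan
    table's step-1 p-values, estimates per-bin effective test counts from the
    genotype block, and stores ``binning_`` and the per-SNP ``decisions_``.
    """

    def __init__(self, alpha: float = 0.05, bin_size: int = 5,
                 m_expected: float = 1e6, eigen_fraction: float = 0.995):
        self.alpha = alpha
        self.bin_size = bin_size
        self.m_expected = m_expected
        self.eigen_fraction = eigen_fraction

    def fit(self, records: pd.DataFrame, block: GenotypeBlock) -> "EdgeWeightedTester":
        if list(records["snp_id"]) != block.snp_ids:
            raise ValueError("scan records and genotype block list different SNPs")
        binning = build_bins(
            records["p_step1"].to_numpy(dtype=float),
            alpha=self.alpha, B=self.bin_size, m_expected=self.m_expected,
        )
        self.binning_ = compute_bin_m_eff(binning, block, self.eigen_fraction)
        self.decisions_ = apply_weighted_test(records, self.binning_)
        return self
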