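"""SNP-level quality control: HWE exact test, imputation-R^2 and MAF filters.

Filter semantics follow the usual genotyping-QC conventions for an imputed
case-control consortium: Hardy-Weinberg equilibrium is tested only on
directly genotyped (hard-call) SNPs, imputation quality applies only to
imputed SNPs, and the pooled minor-allele-frequency filter applies to all.
Boundary behaviour is deliberate: MAF exactly at the threshold fails
(MAF <= 1% is excluded) while R^2 exactly at the threshold passes
(only R^2 < 0.8 is excluded).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from sklearn.base import BaseEstimator

from .simulate import GenotypeBlock


@dataclass(frozen=True)
class QcThresholds:
    hwe_p_min: float = 1e-4
    min_rsq: float = 0.8
    min_maf: float = 0.01

    def __post_init__(self):
        for name in ("hwe_p_min", "min_rsq", "min_maf"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {v}")


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Two-sided exact Hardy-Weinberg p-value (Levene-Haldane).

    Conditions on the observed allele counts and sums the probabilities of
    all heterozygote counts no more likely than the observed one, under the
    exact conditional distribution

        P(n_Aa | n, n_a) = C * 2^n_Aa / (n_AA! n_Aa! n_aa!)

    Monomorphic SNPs return p = 1 by convention.
    """
    counts = (int(n_AA), int(n_Aa), int(n_aa))
    if any(c < 0 for c in counts):
        raise ValueError(f"genotype counts must be nonnegative, got {counts}")
    n = sum(counts)
    if n == 0:
        raise ValueError("at least one genotype observation required")
    n_a = counts[1] + 2 * counts[2]  # minor-ish allele count; symmetry below
    n_A = counts[1] + 2 * counts[0]
    if n_a == 0 or n_A == 0:
        return 1.0
    rare = min(n_a, n_A)
    # all heterozygote counts with the same parity as `rare`
    hets = np.arange(rare % 2, rare + 1, 2)
    homr = (rare - hets) // 2
    homc = n - hets - homr
    logp = (
        hets * np.log(2.0)
        - gammaln(homr + 1)
        - gammaln(hets + 1)
        - gammaln(homc + 1)
    )
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    observed = probs[hets == counts[1]]
    if observed.size == 0:  # parity mismatch cannot happen for valid counts
        raise ValueError(f"inconsistent genotype counts {counts}")
    # small relative slack so ties with the observed probability are included
    return float(min(1.0, probs[probs <= observed[0] * (1 + 1e-12)].sum()))


def _hwe_p_from_calls(calls: np.ndarray) -> float:
    n_aa = int(np.sum(calls == 2))
    n_Aa = int(np.sum(calls == 1))
    n_AA = int(np.sum(calls == 0))
    return hwe_exact_test(n_AA, n_Aa, n_aa)


class SnpQcFilter(BaseEstimator):
    """Filter a genotype block on HWE, imputation R^2 and pooled MAF.

    Parameters mirror :class:`QcThresholds`. After :meth:`fit`, ``report_``
    holds one row per input SNP with the pass flag, failure reasons and the
    statistics they were based on; :meth:`transform` returns the filtered
    block. Call-rate and duplicate-concordance checks do not apply to
    complete synthetic data and are accepted as no-ops with a warning.
    """

    def __init__(self, hwe_p_min: float = 1e-4, min_rsq: float = 0.8, min_maf: float = 0.01,
                 call_rate_min: float | None = None):
        self.hwe_p_min = hwe_p_min
        self.min_rsq = min_rsq
        self.min_maf = min_maf
        self.call_rate_min = call_rate_min

    def fit(self, block: GenotypeBlock, y=None) -> "SnpQcFilter":
        QcThresholds(self.hwe_p_min, self.min_rsq, self.min_maf)  # validate
        if self.call_rate_min is not None:
            warnings.warn("call-rate filter is a no-op on complete dosage data")
        meta = block.snp_meta
        maf = block.pooled_maf() if block.n_subjects else np.minimum(
            meta["alt_freq"], 1 - meta["alt_freq"]
        ).to_numpy()
        rows = []
        for j in range(block.n_snps):
            reasons = []
            hwe_p = np.nan
            if meta["genotyped"].iat[j] and block.n_subjects:
                hwe_p = _hwe_p_from_calls(block.dosages[:, j])
                if hwe_p < self.hwe_p_min:
                    reasons.append("hwe")
            else:
                if meta["rsq"].iat[j] < self.min_rsq:
                    reasons.append("rsq")
            if maf[j] <= self.min_maf:
                reasons.append("maf")
            rows.append(
                {
                    "snp_id": meta["snp_id"].iat[j],
                    "pass": not reasons,
                    "reasons": ",".join(reasons),
                    "hwe_p": hwe_p,
                    "maf": maf[j],
                    "rsq": meta["rsq"].iat[j],
                }
            )
        self.report_ = pd.DataFrame(rows)
        self.keep_mask_ = self.report_["pass"].to_numpy()
        return self

    def transform(self, block: GenotypeBlock) -> GenotypeBlock:
        if not hasattr(self, "keep_mask_"):
            raise RuntimeError("SnpQcFilter must be fitted before transform")
        return block.take_snps(np.flatnonzero(self.keep_mask_))

    def fit_transform(self, block: GenotypeBlock, y=None) -> GenotypeBlock:
        return self.fit(block).transform(block)


def apply_snp_filters(
    block: GenotypeBlock, thresholds: QcThresholds = QcThresholds()
) -> tuple[GenotypeBlock, pd.DataFrame]:
    """Functional wrapper over :class:`SnpQcFilter`."""
    f = SnpQcFilter(thresholds.hwe_p_min, thresholds.min_rsq, thresholds.min_maf)
    filtered = f.fit_transform(block)
    return filtered, f.report_
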