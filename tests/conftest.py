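import numpy as np
import pytest

from edgescan import ScanSpec, SimConfig, genome_scan, simulate_study

NULL_SCAN_SNPS = 2000


@pytest.fixture(scope="session")
def small_study():
    """A small multi-feature cohort: LD blocks, imputed SNPs, two studies."""
    cfg = SimConfig(
        seed=11,
        n_studies=2,
        n_cases=250,
        n_controls=250,
        n_snps=40,
        ld_rho=0.4,
        block_size=8,
        frac_imputed=0.3,
        target_rsq=0.9,
        beta_E=np.log(0.85),
    )
    cohort, block = simulate_study(cfg)
    return cfg, cohort, block


@pytest.fixture(scope="session")
def null_scan():
    """Scan of many independent null SNPs (all effects zero, no G-E link)."""
    cfg = SimConfig(
        seed=42, n_cases=500, n_controls=500, n_snps=NULL_SCAN_SNPS, index_snp=None
    )
    cohort, block = simulate_study(cfg)
    records = genome_scan(cohort, block, ScanSpec())
    return cohort, block, records
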