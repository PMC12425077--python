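"""End-to-end pipeline driver: simulate -> QC -> scan -> EDGE -> meta/follow-up.

Every stage writes its artifacts as TSV into the output directory, and a
``manifest.json`` records the configuration hash, seed and package version
so any output can be regenerated. Reruns with an identical configuration
produce byte-identical artifacts: all randomness flows from the configured
seed and no stage reads the clock or environment for entropy.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .edge import EdgeWeightedTester
from .io import (
    read_cohort_tsv,
    read_genotypes_tsv,
    read_genotypes_vcf,
    write_cohort_tsv,
    write_genotypes_tsv,
)
from .meta import genomic_inflation, hk_meta, per_study_exposure_effects, qq_points, stratified_or_table
from .qc import SnpQcFilter
from .scan import GenomeScanner, ScanSpec
from .simulate import SimConfig, simulate_study

log = logging.getLogger("edgescan")

ALL_STAGES = ("simulate", "qc", "scan", "edge", "meta", "followup")


@dataclass
class PipelineConfig:
    out_dir: str = "edgescan_out"
    genotypes: str | None = None  # input path (.vcf or .tsv); None -> simulate
    phenotypes: str | None = None
    seed: int = 0
    exposure: str = "binary"
    sim: dict = field(default_factory=dict)  # SimConfig overrides
    qc: dict = field(default_factory=dict)  # SnpQcFilter params
    scan: dict = field(default_factory=dict)  # GenomeScanner params
    edge: dict = field(default_factory=dict)  # EdgeWeightedTester params
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        canon = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()


def _sim_config(config: PipelineConfig) -> SimConfig:
    return SimConfig(seed=config.seed, **config.sim)


def _load_inputs(config: PipelineConfig, out: Path):
    if config.genotypes is None:
        raise FileNotFoundError("no genotype input configured and simulate stage not run")
    gpath = Path(config.genotypes)
    if not gpath.exists():
        candidate = out / gpath.name
        if candidate.exists():
            gpath = candidate
        else:
            raise FileNotFoundError(f"genotype input {config.genotypes} not found")
    block = read_genotypes_vcf(gpath) if gpath.suffix == ".vcf" else read_genotypes_tsv(gpath)
    cohort = None
    if config.phenotypes is not None:
        ppath = Path(config.phenotypes)
        if not ppath.exists() and (out / ppath.name).exists():
            ppath = out / ppath.name
        cohort, msgs = read_cohort_tsv(ppath)
        for m in msgs:
            log.warning("cohort validation: %s", m)
    return cohort, block


def run_pipeline(config: PipelineConfig, stages: tuple[str, ...] = ALL_STAGES) -> dict:
    """Execute the requested stages in order; returns {artifact: path}.

    A stage failure aborts the run with the stage name; the manifest written
    so far is preserved so partial outputs remain attributable.
    """
    logging.basicConfig(
        level=getattr(logging, config.log_level.upper(), logging.INFO),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )
    out = Path(config.out_dir)
    needs_inputs = "simulate" not in stages and set(stages) & {"qc", "scan", "edge", "meta", "followup"}
    if needs_inputs:
        if config.genotypes is None:
            raise FileNotFoundError("no genotype input configured and simulate stage not requested")
        gp = Path(config.genotypes)
        if not gp.exists() and not (out / gp.name).exists():
            raise FileNotFoundError(f"genotype input {config.genotypes} not found")
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}
    manifest = {
        "config": config.to_dict(),
        "config_sha256": config.digest(),
        "seed": config.seed,
        "version": __version__,
        "artifacts": artifacts,
    }

    def checkpoint():
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)

    cohort = block = None
    scan_records = decisions = None
    spec = ScanSpec(exposure=config.exposure, **config.scan)

    try:
        if "simulate" in stages:
            log.info("stage simulate: seed=%d", config.seed)
            cohort, block = simulate_study(_sim_config(config))
            write_cohort_tsv(cohort, out / "cohort.tsv")
            write_genotypes_tsv(block, out / "genotypes.tsv")
            config.genotypes = str(out / "genotypes.tsv")
            config.phenotypes = str(out / "cohort.tsv")
            artifacts["cohort"] = str(out / "cohort.tsv")
            artifacts["genotypes"] = str(out / "genotypes.tsv")
            checkpoint()

        needs_data = set(stages) & {"qc", "scan", "edge", "meta", "followup"}
        if needs_data and (cohort is None or block is None):
            cohort, block = _load_inputs(config, out)

        if "qc" in stages:
            log.info("stage qc: %d SNPs in", block.n_snps)
            qc = SnpQcFilter(**config.qc).fit(block)
            block = qc.transform(block)
            qc.report_.to_csv(out / "qc_report.tsv", sep="\t", index=False)
            artifacts["qc_report"] = str(out / "qc_report.tsv")
            log.info("stage qc: %d SNPs pass", block.n_snps)
            checkpoint()

        if "scan" in stages:
            log.info("stage scan: %d SNPs x %d subjects", block.n_snps, len(cohort))
            scanner = GenomeScanner(exposure=spec.exposure, **config.scan).fit(cohort, block)
            scan_records = scanner.records_
            scan_records.to_csv(out / "scan.tsv", sep="\t", index=False)
            artifacts["scan"] = str(out / "scan.tsv")
            checkpoint()

        if "edge" in stages:
            if scan_records is None:
                scan_records = pd.read_csv(out / "scan.tsv", sep="\t")
            edge_params = dict(config.edge)
            edge_params.setdefault("m_expected", block.n_snps)
            tester = EdgeWeightedTester(**edge_params).fit(scan_records, block)
            decisions = tester.decisions_
            decisions.to_csv(out / "edge_decisions.tsv", sep="\t", index=False)
            tester.binning_.summary().to_csv(out / "edge_bins.tsv", sep="\t", index=False)
            artifacts["edge_decisions"] = str(out / "edge_decisions.tsv")
            artifacts["edge_bins"] = str(out / "edge_bins.tsv")
            log.info("stage edge: %d rejections", int(decisions["reject"].sum()))
            checkpoint()

        if "meta" in stages:
            per_study = per_study_exposure_effects(cohort, spec)
            per_study.to_csv(out / "per_study_effects.tsv", sep="\t", index=False)
            artifacts["per_study_effects"] = str(out / "per_study_effects.tsv")
            if len(per_study) >= 2:
                m = hk_meta(per_study)
                pd.DataFrame(
                    [{
                        "pooled_logOR": m.logor, "pooled_OR": m.odds_ratio,
                        "SE": m.se, "ci_low": m.or_ci[0], "ci_high": m.or_ci[1],
                        "tau2": m.tau2, "Q": m.Q, "Q_df": m.Q_df,
                        "p_het": m.p_het, "I2": m.I2,
                    }]
                ).to_csv(out / "meta.tsv", sep="\t", index=False)
                artifacts["meta"] = str(out / "meta.tsv")
            if scan_records is None and (out / "scan.tsv").exists():
                scan_records = pd.read_csv(out / "scan.tsv", sep="\t")
            if scan_records is not None:
                chi2 = scan_records["chi2_GxE"].dropna().to_numpy()
                n_ca = int(cohort["D"].sum())
                n_co = int((1 - cohort["D"]).sum())
                infl = genomic_inflation(chi2, n_ca, n_co)
                pd.DataFrame(
                    [{
                        "lambda": infl.lam, "lambda_1000": infl.lambda_1000,
                        "n_cases": n_ca, "n_controls": n_co,
                    }]
                ).to_csv(out / "inflation.tsv", sep="\t", index=False)
                qq = qq_points(scan_records["p_GxE_1df"].dropna().to_numpy())
                qq.to_csv(out / "qq.tsv", sep="\t", index=False)
                artifacts["inflation"] = str(out / "inflation.tsv")
                artifacts["qq"] = str(out / "qq.tsv")
            checkpoint()

        if "followup" in stages:
            if decisions is None and (out / "edge_decisions.tsv").exists():
                decisions = pd.read_csv(out / "edge_decisions.tsv", sep="\t")
            if scan_records is None and (out / "scan.tsv").exists():
                scan_records = pd.read_csv(out / "scan.tsv", sep="\t")
            target = None
            if decisions is not None and len(decisions):
                hits = decisions.sort_values("p_two_step")
                target = str(hits["snp_id"].iloc[0])
            elif scan_records is not None and len(scan_records):
                target = str(scan_records.sort_values("p_GxE_1df")["snp_id"].iloc[0])
            if target is not None and target in block.snp_ids:
                table = stratified_or_table(
                    cohort, block.column(target), exposure=config.exposure, spec=spec
                )
                table.by_genotype.insert(0, "snp_id", target)
                table.by_exposure.insert(0, "snp_id", target)
                table.by_genotype.to_csv(out / "stratified_by_genotype.tsv", sep="\t", index=False)
                table.by_exposure.to_csv(out / "stratified_by_exposure.tsv", sep="\t", index=False)
                artifacts["stratified_by_genotype"] = str(out / "stratified_by_genotype.tsv")
                artifacts["stratified_by_exposure"] = str(out / "stratified_by_exposure.tsv")
            checkpoint()
    except Exception:
        checkpoint()
        raise

    checkpoint()
    return artifacts
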