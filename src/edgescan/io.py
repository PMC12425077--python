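"""Reading and writing the toolkit's file formats.

Genotypes travel either as VCF (one record per SNP, FORMAT ``DS`` carrying
the dosage; directly genotyped SNPs additionally carry ``GT``) or as a plain
TSV dosage matrix with a header row of SNP ids plus a sidecar metadata TSV.
Phenotypes/covariates are a TSV with one row per subject. All tables are
UTF-8, tab-separated, Unix newlines; positions are 1-based (VCF convention)
and dosages count the alternate allele.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .simulate import COHORT_COLUMNS, GenotypeBlock


class FormatError(ValueError):
    pass


# ---------------------------------------------------------------------------
# genotypes: VCF

_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=AF,Number=A,Type=Float,Description="Alternate allele frequency">
##INFO=<ID=RSQ,Number=1,Type=Float,Description="Imputation quality R-squared">
##INFO=<ID=TYPED,Number=0,Type=Flag,Description="Directly genotyped">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DS,Number=1,Type=Float,Description="Alternate allele dosage">
"""

_GT_CODES = {0: "0/0", 1: "0/1", 2: "1/1"}


def write_genotypes_vcf(block: GenotypeBlock, path: str | Path) -> None:
    path = Path(path)
    meta = block.snp_meta
    with open(path, "w", newline="\n") as fh:
        fh.write(_VCF_HEADER)
        for chrom in meta["chrom"].unique():
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(map(str, block.subject_ids))
            + "\n"
        )
        for j in range(block.n_snps):
            row = meta.iloc[j]
            typed = bool(row["genotyped"])
            info = f"AF={row['alt_freq']:.6g};RSQ={row['rsq']:.6g}"
            if typed:
                info += ";TYPED"
            dos = block.dosages[:, j]
            if typed:
                fmt = "GT:DS"
                cells = [f"{_GT_CODES[int(round(d))]}:{d:.4f}" for d in dos]
            else:
                fmt = "DS"
                cells = [f"{d:.4f}" for d in dos]
            fh.write(
                f"{row['chrom']}\t{int(row['pos'])}\t{row['snp_id']}\t{row['ref']}\t"
                f"{row['alt']}\t.\tPASS\t{info}\t{fmt}\t" + "\t".join(cells) + "\n"
            )


def read_genotypes_vcf(path: str | Path) -> GenotypeBlock:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    subject_ids = np.array(vcf.samples)
    dosages, rows = [], []
    for var in vcf:
        coord = f"{var.CHROM}:{var.POS}"
        fmt = var.FORMAT or []
        if "DS" in fmt:
            ds = np.asarray(var.format("DS"), dtype=float).ravel()
        elif "GT" in fmt:
            # hard-call fallback: dosage from the called genotype
            ds = np.array([float(a + b) for a, b, *_ in var.genotypes])
        else:
            raise FormatError(f"record {coord}: neither DS nor GT present")
        if np.any(ds < 0) or np.any(ds > 2) or np.any(~np.isfinite(ds)):
            raise FormatError(f"record {coord}: dosage outside [0, 2]")
        typed = var.INFO.get("TYPED") is not None
        rsq = var.INFO.get("RSQ")
        af = var.INFO.get("AF")
        dosages.append(ds)
        rows.append(
            {
                "snp_id": var.ID or coord,
                "chrom": var.CHROM,
                "pos": var.POS,
                "ref": var.REF,
                "alt": var.ALT[0] if var.ALT else ".",
                "alt_freq": float(af) if af is not None else float(ds.mean() / 2.0),
                "rsq": float(rsq) if rsq is not None else 1.0,
                "genotyped": typed,
            }
        )
    if not rows:
        raise FormatError(f"{path}: no variant records")
    return GenotypeBlock(np.column_stack(dosages), pd.DataFrame(rows), subject_ids)


# ---------------------------------------------------------------------------
# genotypes: TSV dosage matrix

def write_genotypes_tsv(block: GenotypeBlock, path: str | Path) -> None:
    path = Path(path)
    df = pd.DataFrame(block.dosages, columns=block.snp_ids)
    df.insert(0, "subject_id", block.subject_ids)
    # 17 significant digits so binary doubles round-trip exactly
    df.to_csv(path, sep="\t", index=False, lineterminator="\n", float_format="%.17g")
    block.snp_meta.to_csv(
        path.with_suffix(path.suffix + ".meta"), sep="\t", index=False, lineterminator="\n"
    )


def read_genotypes_tsv(path: str | Path) -> GenotypeBlock:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    if df.columns[0] != "subject_id":
        raise FormatError(f"{path}: first column must be subject_id")
    subject_ids = df["subject_id"].to_numpy()
    dosages = df.drop(columns="subject_id").to_numpy(dtype=float)
    bad = np.argwhere((dosages < 0) | (dosages > 2) | ~np.isfinite(dosages))
    if len(bad):
        i, j = bad[0]
        raise FormatError(
            f"{path}: dosage {dosages[i, j]!r} outside [0, 2] at row {i + 2}, "
            f"SNP {df.columns[j + 1]}"
        )
    meta_path = path.with_suffix(path.suffix + ".meta")
    if meta_path.exists():
        meta = pd.read_csv(meta_path, sep="\t")
        meta["chrom"] = meta["chrom"].astype(str)
    else:
        snp_ids = list(df.columns[1:])
        integral = np.all(np.equal(np.mod(dosages, 1), 0), axis=0)
        meta = pd.DataFrame(
            {
                "snp_id": snp_ids,
                "chrom": "1",
                "pos": np.arange(1, len(snp_ids) + 1),
                "ref": "A",
                "alt": "G",
                "alt_freq": dosages.mean(axis=0) / 2.0,
                "rsq": 1.0,
                "genotyped": integral,
            }
        )
    return GenotypeBlock(dosages, meta, subject_ids)


# ---------------------------------------------------------------------------
# cohort table

_VALID_SEX = {"female", "male"}


def write_cohort_tsv(cohort: pd.DataFrame, path: str | Path) -> None:
    cohort.to_csv(path, sep="\t", index=False, lineterminator="\n", na_rep="")


def read_cohort_tsv(path: str | Path) -> tuple[pd.DataFrame, list[str]]:
    """Read and validate a phenotype/covariate table.

    Returns the typed table and a list of per-row validation messages; rows
    failing validation (unknown sex code, negative MET, non-binary disease
    status) are dropped and reported. Duplicated subject ids are a hard error.
    """
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str, "study": str, "sex": str})
    required = {"subject_id", "study", "D", "met_hours_week", "age", "sex"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing required columns {sorted(missing)}")
    if df["subject_id"].duplicated().any():
        dup = df["subject_id"][df["subject_id"].duplicated()].iloc[0]
        raise FormatError(f"{path}: duplicated subject id {dup!r}")
    warnings_list: list[str] = []
    keep = np.ones(len(df), dtype=bool)
    bad_sex = ~df["sex"].isin(_VALID_SEX)
    for i in np.flatnonzero(bad_sex):
        warnings_list.append(f"row {i + 2}: unknown sex code {df['sex'].iat[i]!r}")
    bad_met = df["met_hours_week"].astype(float) < 0
    for i in np.flatnonzero(bad_met.to_numpy()):
        warnings_list.append(f"row {i + 2}: negative MET-h/wk {df['met_hours_week'].iat[i]}")
    bad_d = ~df["D"].isin([0, 1])
    for i in np.flatnonzero(bad_d.to_numpy()):
        warnings_list.append(f"row {i + 2}: disease status {df['D'].iat[i]!r} not in {{0,1}}")
    keep &= ~(bad_sex.to_numpy() | bad_met.to_numpy() | bad_d.to_numpy())
    out = df[keep].reset_index(drop=True)
    for col in COHORT_COLUMNS:
        if col not in out.columns:
            out[col] = np.nan
    return out, warnings_list


# ---------------------------------------------------------------------------
# config

def load_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return data or {}


def dump_yaml(obj: dict, path: str | Path) -> None:
    with open(path, "w", newline="\n") as fh:
        yaml.safe_dump(obj, fh, sort_keys=True)
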