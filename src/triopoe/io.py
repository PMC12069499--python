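"""Readers, writers and report assembly.

Formats: long-format phenotype CSV, minimal VCF v4.2 with a GT field only,
and 6-column PLINK-style FAM pedigrees (sex coded 1=male, 2=female; offspring
rows carry both parental ids).  Reading validates against the cohort
invariants and reports offending line numbers.
"""
from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import MISSING_GENOTYPE, PHENOTYPE_COLUMNS, TrioCohort

__all__ = [
    "write_cohort",
    "write_phenotypes",
    "write_vcf",
    "write_fam",
    "read_phenotypes",
    "read_trios",
    "read_cohort",
    "assemble_report",
    "plot_z_matrix",
]

_GT = {0: "0/0", 1: "0/1", 2: "1/1", MISSING_GENOTYPE: "./."}


def write_phenotypes(cohort: TrioCohort, path: str | Path) -> None:
    cohort.phenotypes[PHENOTYPE_COLUMNS].to_csv(path, index=False)


def write_fam(cohort: TrioCohort, path: str | Path) -> None:
    """PLINK-style FAM: fid iid father mother sex phenotype(-9)."""
    lines = []
    for row in cohort.pedigree.itertuples(index=False):
        lines.append(f"{row.family_id} {row.mother_id} 0 0 2 -9")
        lines.append(f"{row.family_id} {row.father_id} 0 0 1 -9")
        sex = 2 if row.offspring_sex == "F" else 1
        lines.append(f"{row.family_id} {row.offspring_id} {row.father_id} {row.mother_id} {sex} -9")
    Path(path).write_text("\n".join(lines) + "\n")


def write_vcf(cohort: TrioCohort, path: str | Path) -> None:
    """Minimal biallelic VCF v4.2 with GT only (codes count ALT = minor alleles)."""
    if cohort.genotypes is None:
        raise ValueError("cohort has no genotypes to write")
    geno = cohort.genotypes
    snps = cohort.snps
    if snps is None:
        snps = pd.DataFrame(
            {"snp_id": geno.columns, "chrom": "1",
             "pos": 1000 * (np.arange(len(geno.columns)) + 1), "ref": "A", "alt": "B"}
        )
    samples = list(geno.index)
    header = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        *(f"##contig=<ID={c}>" for c in dict.fromkeys(snps["chrom"].astype(str))),
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples),
    ]
    lines = header
    for row in snps.itertuples(index=False):
        codes = geno[row.snp_id].to_numpy()
        gts = "\t".join(_GT[int(c)] for c in codes)
        lines.append(f"{row.chrom}\t{row.pos}\t{row.snp_id}\t{row.ref}\t{row.alt}\t.\tPASS\t.\tGT\t{gts}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_cohort(cohort: TrioCohort, outdir: str | Path) -> dict[str, Path]:
    """Write phenotypes.csv, trios.fam and (when present) genotypes.vcf + truth CSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {"phenotypes": outdir / "phenotypes.csv", "fam": outdir / "trios.fam"}
    write_phenotypes(cohort, paths["phenotypes"])
    write_fam(cohort, paths["fam"])
    if cohort.genotypes is not None:
        paths["vcf"] = outdir / "genotypes.vcf"
        write_vcf(cohort, paths["vcf"])
    if cohort.truth is not None:
        paths["truth_origins"] = outdir / "truth_origins.csv"
        cohort.truth.origins.to_csv(paths["truth_origins"], index=False)
        paths["truth_perturbations"] = outdir / "truth_perturbations.csv"
        cohort.truth.perturbations.to_csv(paths["truth_perturbations"], index=False)
    return paths


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    """Read and validate a long-format phenotype CSV.

    Raises ``ValueError`` naming the first offending CSV line (1-based,
    counting the header) for duplicate (individual, visit, trait) records,
    unknown roles, or non-numeric values.
    """
    ph = pd.read_csv(path, dtype={"visit": str})
    missing = [c for c in PHENOTYPE_COLUMNS if c not in ph.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    bad_role = ~ph["role"].isin(("mother", "father", "offspring"))
    if bad_role.any():
        line = int(ph.index[bad_role][0]) + 2
        raise ValueError(f"{path}: unknown role {ph.loc[bad_role, 'role'].iloc[0]!r} at line {line}")
    dup = ph.duplicated(subset=["individual_id", "visit", "trait"])
    if dup.any():
        line = int(ph.index[dup][0]) + 2
        row = ph.loc[dup].iloc[0]
        raise ValueError(
            f"{path}: duplicate record for ({row['individual_id']}, {row['visit']}, "
            f"{row['trait']}) at line {line}"
        )
    ph["value"] = pd.to_numeric(ph["value"], errors="raise")
    ph["age"] = pd.to_numeric(ph["age"], errors="raise")
    return ph


def _read_fam(path: str | Path) -> pd.DataFrame:
    rows = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 6:
            raise ValueError(f"{path}: line {ln}: expected 6 FAM columns, got {len(parts)}")
        rows.append(parts)
    fam = pd.DataFrame(rows, columns=["family_id", "individual_id", "father_id", "mother_id", "sex", "phenotype"])
    return fam


def read_trios(vcf_path: str | Path, fam_path: str | Path):
    """Read trio genotypes + pedigree from a VCF (GT) and a FAM file.

    Returns ``(genotypes, snps, pedigree)``.  Only biallelic records are kept;
    multi-allelic records are skipped with a warning.  Every pedigree
    individual must be a VCF sample (error names the missing id).
    """
    from cyvcf2 import VCF

    fam = _read_fam(fam_path)
    offspring = fam[(fam["father_id"] != "0") & (fam["mother_id"] != "0")]
    if offspring.empty:
        raise ValueError(f"{fam_path}: no offspring rows (both parent ids set) found")
    pedigree = pd.DataFrame(
        {
            "family_id": offspring["family_id"].to_numpy(),
            "mother_id": offspring["mother_id"].to_numpy(),
            "father_id": offspring["father_id"].to_numpy(),
            "offspring_id": offspring["individual_id"].to_numpy(),
            "offspring_sex": np.where(offspring["sex"].to_numpy() == "2", "F", "M"),
        }
    )

    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    sample_set = set(samples)
    for col in ("mother_id", "father_id", "offspring_id"):
        for ind in pedigree[col]:
            if ind not in sample_set:
                raise ValueError(f"pedigree individual {ind!r} is not a sample in {vcf_path}")

    cols: dict[str, np.ndarray] = {}
    meta = []
    for rec in vcf:
        if len(rec.ALT) != 1:
            warnings.warn(
                f"skipping multi-allelic record {rec.ID or rec.POS} (biallelic-only contract)",
                stacklevel=2,
            )
            continue
        codes = np.empty(len(samples), dtype=np.int16)
        for i, g in enumerate(rec.genotypes):
            a, b = g[0], g[1]
            codes[i] = MISSING_GENOTYPE if (a < 0 or b < 0) else a + b
        snp_id = rec.ID or f"{rec.CHROM}:{rec.POS}"
        cols[snp_id] = codes
        meta.append({"snp_id": snp_id, "chrom": rec.CHROM, "pos": rec.POS,
                     "ref": rec.REF, "alt": rec.ALT[0]})
    genotypes = pd.DataFrame(cols, index=pd.Index(samples, name="individual_id"))
    snps = pd.DataFrame(meta, columns=["snp_id", "chrom", "pos", "ref", "alt"])
    return genotypes, snps, pedigree


def read_cohort(indir: str | Path) -> TrioCohort:
    """Rebuild a cohort from a directory written by :func:`write_cohort` (no truth)."""
    indir = Path(indir)
    phenotypes = read_phenotypes(indir / "phenotypes.csv")
    vcf = indir / "genotypes.vcf"
    if vcf.exists():
        genotypes, snps, pedigree = read_trios(vcf, indir / "trios.fam")
    else:
        genotypes, snps = None, None
        fam = _read_fam(indir / "trios.fam")
        offspring = fam[(fam["father_id"] != "0") & (fam["mother_id"] != "0")]
        pedigree = pd.DataFrame(
            {
                "family_id": offspring["family_id"].to_numpy(),
                "mother_id": offspring["mother_id"].to_numpy(),
                "father_id": offspring["father_id"].to_numpy(),
                "offspring_id": offspring["individual_id"].to_numpy(),
                "offspring_sex": np.where(offspring["sex"].to_numpy() == "2", "F", "M"),
            }
        )
    cohort = TrioCohort(pedigree=pedigree, phenotypes=phenotypes, genotypes=genotypes, snps=snps)
    cohort.validate()
    return cohort


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

CROSS_SECTIONAL_COLUMNS = [
    "trait", "visit", "stratum", "status",
    "beta_maternal", "se_maternal", "p_maternal", "n_maternal",
    "beta_paternal", "se_paternal", "p_paternal", "n_paternal",
    "z", "p_poe", "cov_used", "significant_nominal", "significant_bonferroni",
]

GENETIC_COLUMNS = [
    "snp_id", "trait", "visit", "status",
    "maternal_estimate", "maternal_se", "maternal_p",
    "paternal_estimate", "paternal_se", "paternal_p",
    "poe_estimate", "poe_se", "poe_p",
]


def assemble_report(
    outdir: str | Path,
    cross_sectional: pd.DataFrame | None = None,
    longitudinal: pd.DataFrame | None = None,
    genetic: pd.DataFrame | None = None,
    config_repr: str = "",
    seed: int | None = None,
) -> dict[str, Path]:
    """Write result CSVs with a fixed column order plus a machine-readable run log.

    Empty inputs produce header-only files; a rerun with the same inputs is
    byte-identical (the run log carries no timestamp for that reason).
    """
    import statsmodels

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def _write(df: pd.DataFrame | None, columns: list[str], name: str) -> None:
        if df is None:
            return
        out = pd.DataFrame(df)
        for col in columns:
            if col not in out.columns:
                out[col] = pd.NA
        extra = [c for c in out.columns if c not in columns]
        out[columns + extra].to_csv(outdir / name, index=False)
        paths[name] = outdir / name

    _write(cross_sectional, CROSS_SECTIONAL_COLUMNS, "cross_sectional_poe.csv")
    if longitudinal is not None:
        cols = list(longitudinal.columns)
        longitudinal.to_csv(outdir / "longitudinal_poe.csv", index=False, columns=cols)
        paths["longitudinal_poe.csv"] = outdir / "longitudinal_poe.csv"
    _write(genetic, GENETIC_COLUMNS, "genetic_poe.csv")

    log = {
        "config_sha256": hashlib.sha256(config_repr.encode()).hexdigest(),
        "seed": seed,
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "statsmodels": statsmodels.__version__,
        },
    }
    log_path = outdir / "run_log.json"
    log_path.write_text(json.dumps(log, indent=2, sort_keys=True) + "\n")
    paths["run_log.json"] = log_path
    return paths


def plot_z_matrix(scan: pd.DataFrame, path: str | Path, stratum: str = "all") -> None:
    """Optional heatmap of Wald Z by trait x visit for one stratum."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sub = scan[(scan["stratum"] == stratum) & (scan["status"] == "ok")]
    mat = sub.pivot(index="trait", columns="visit", values="z")
    fig, ax = plt.subplots(figsize=(1.2 * len(mat.columns) + 3, 0.5 * len(mat) + 2))
    im = ax.imshow(mat.to_numpy(dtype=float), cmap="RdBu_r", vmin=-4, vmax=4, aspect="auto")
    ax.set_xticks(range(len(mat.columns)), mat.columns)
    ax.set_yticks(range(len(mat.index)), mat.index)
    fig.colorbar(im, ax=ax, label="Wald Z (maternal - paternal)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
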