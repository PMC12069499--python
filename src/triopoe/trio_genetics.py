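"""Trio genotype QC, allele-origin assignment and allele-origin association tests.

Genotype codes count minor (B) alleles: 0 = AA, 1 = AB, 2 = BB, -1 = missing.
For a heterozygous offspring the transmitting parent of the minor allele is
determined from the parental genotypes whenever at least one parent is
homozygous; trios where offspring and both parents are heterozygous are
intrinsically ambiguous without population phasing and are excluded from the
origin-based models.

Association models (fitted with generalised estimating equations, independence
working correlation, robust sandwich SEs clustered on family; with one
offspring per family this equals heteroskedasticity-robust OLS):

* maternal: offspring carrying a maternally inherited minor allele (ApBm) vs AA
* paternal: AmBp vs AA
* poe: the reciprocal-heterozygote contrast, ApBm vs AmBp
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import gammaln, logsumexp

from .cohort import MISSING_GENOTYPE, TrioCohort
from .config import QCThresholds
from .cross_sectional import SkipRecord
from .transforms import log_transform, zscore

__all__ = [
    "OriginStatus",
    "OriginCall",
    "GeeResult",
    "hwe_exact_test",
    "detect_mendelian_errors",
    "assign_parental_origin",
    "assign_origins",
    "qc_filter",
    "genetic_poe_association",
    "genetic_poe_scan",
]


class OriginStatus(str, Enum):
    RESOLVED = "RESOLVED"
    AMBIGUOUS = "AMBIGUOUS"
    MENDELIAN_ERROR = "MENDELIAN_ERROR"
    MISSING = "MISSING"


@dataclass
class OriginCall:
    """Per trio / per SNP parental origin of the offspring's alleles."""

    family_id: str | None
    snp_id: str | None
    offspring_genotype: int
    maternal_allele: str | None  # "A" | "B" | None when unknown
    paternal_allele: str | None
    status: OriginStatus


@dataclass
class GeeResult:
    """One allele-origin association fit."""

    snp_id: str
    trait: str
    visit: str
    model: str  # maternal | paternal | poe
    estimate: float
    se: float
    p_value: float
    n_per_group: dict[str, int]
    covariates: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------


def hwe_exact_test(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Two-sided conditional exact test of Hardy-Weinberg proportions.

    Conditional on the observed allele counts, sums the probabilities of all
    heterozygote counts whose probability does not exceed that of the observed
    configuration.  Computed in log space, so it stays exact in practice for
    founder panels of any realistic size.
    """
    for v in (n_aa, n_ab, n_bb):
        if v < 0 or int(v) != v:
            raise ValueError(f"genotype counts must be non-negative integers, got {(n_aa, n_ab, n_bb)}")
    n_aa, n_ab, n_bb = int(n_aa), int(n_ab), int(n_bb)
    n = n_aa + n_ab + n_bb
    if n < 1:
        raise ValueError("at least one genotype is required")
    n_b = 2 * n_bb + n_ab
    rare = min(n_b, 2 * n - n_b)
    if rare == 0:
        return 1.0  # monomorphic: a single attainable configuration
    hets = np.arange(rare % 2, rare + 1, 2)
    hom_rare = (rare - hets) // 2
    hom_common = n - hets - hom_rare
    logp = (
        gammaln(n + 1)
        - gammaln(hets + 1)
        - gammaln(hom_rare + 1)
        - gammaln(hom_common + 1)
        + hets * math.log(2.0)
        + gammaln(rare + 1)
        + gammaln(2 * n - rare + 1)
        - gammaln(2 * n + 1)
    )
    logp -= logsumexp(logp)  # normalize away accumulated rounding
    obs = int(np.flatnonzero(hets == n_ab)[0])
    include = logp <= logp[obs] + 1e-10  # slack so exact ties are kept together
    return float(min(1.0, np.exp(logsumexp(logp[include]))))


def hwe_chi2_test(n_aa: int, n_ab: int, n_bb: int) -> float:
    """One-df chi-square HWE test, a fallback for very large founder panels."""
    n = n_aa + n_ab + n_bb
    if n < 1:
        raise ValueError("at least one genotype is required")
    p = (2 * n_aa + n_ab) / (2 * n)
    q = 1 - p
    if p in (0.0, 1.0):
        return 1.0
    exp = np.array([n * p * p, 2 * n * p * q, n * q * q])
    obs = np.array([n_aa, n_ab, n_bb], dtype=float)
    stat = float(((obs - exp) ** 2 / exp).sum())
    from scipy.stats import chi2

    return float(chi2.sf(stat, df=1))


# ---------------------------------------------------------------------------
# Mendelian logic
# ---------------------------------------------------------------------------

_TRANSMISSIBLE = {0: (0,), 1: (0, 1), 2: (1,)}


def detect_mendelian_errors(mother_g: int, father_g: int, offspring_g: int) -> bool:
    """True iff the trio genotype combination is impossible under biparental transmission.

    Any missing genotype returns False: the trio cannot be adjudicated.
    """
    if MISSING_GENOTYPE in (mother_g, father_g, offspring_g):
        return False
    for g in (mother_g, father_g, offspring_g):
        if g not in (0, 1, 2):
            raise ValueError(f"invalid genotype code {g!r}")
    possible = {a + b for a in _TRANSMISSIBLE[mother_g] for b in _TRANSMISSIBLE[father_g]}
    return offspring_g not in possible


def assign_parental_origin(
    mother_g: int, father_g: int, offspring_g: int,
    family_id: str | None = None, snp_id: str | None = None,
) -> OriginCall:
    """Deterministic parental-origin call for one trio at one biallelic SNP.

    Homozygous offspring force both origins; a heterozygous offspring is
    resolved whenever at least one parent is homozygous; the double-
    heterozygote trio is AMBIGUOUS; impossible combinations are
    MENDELIAN_ERROR; any missing genotype is MISSING.
    """
    def call(mat, pat, status):
        return OriginCall(family_id, snp_id, offspring_g, mat, pat, status)

    if MISSING_GENOTYPE in (mother_g, father_g, offspring_g):
        return call(None, None, OriginStatus.MISSING)
    if detect_mendelian_errors(mother_g, father_g, offspring_g):
        return call(None, None, OriginStatus.MENDELIAN_ERROR)
    if offspring_g == 0:
        return call("A", "A", OriginStatus.RESOLVED)
    if offspring_g == 2:
        return call("B", "B", OriginStatus.RESOLVED)
    # heterozygous offspring
    if mother_g == 0:
        return call("A", "B", OriginStatus.RESOLVED)
    if mother_g == 2:
        return call("B", "A", OriginStatus.RESOLVED)
    if father_g == 0:
        return call("B", "A", OriginStatus.RESOLVED)
    if father_g == 2:
        return call("A", "B", OriginStatus.RESOLVED)
    return call(None, None, OriginStatus.AMBIGUOUS)


def assign_origins(cohort: TrioCohort, snp_ids: Sequence[str] | None = None) -> pd.DataFrame:
    """Vectorized origin calls for every (family, SNP); one row each.

    Columns: family_id, snp_id, offspring_genotype, maternal_allele,
    paternal_allele, status.
    """
    if cohort.genotypes is None:
        raise ValueError("cohort has no genotypes")
    geno = cohort.genotypes
    if snp_ids is None:
        snp_ids = list(geno.columns)

    # 4x4x4 lookup over codes (-1 mapped to 3)
    codes = (MISSING_GENOTYPE, 0, 1, 2)
    lut_mat = np.empty(64, dtype=object)
    lut_pat = np.empty(64, dtype=object)
    lut_status = np.empty(64, dtype=object)
    for i, m in enumerate(codes):
        for j, f in enumerate(codes):
            for k, o in enumerate(codes):
                c = assign_parental_origin(m, f, o)
                idx = i * 16 + j * 4 + k
                lut_mat[idx] = c.maternal_allele
                lut_pat[idx] = c.paternal_allele
                lut_status[idx] = c.status.value

    ped = cohort.pedigree
    m_codes = geno.reindex(ped["mother_id"])[snp_ids].to_numpy()
    f_codes = geno.reindex(ped["father_id"])[snp_ids].to_numpy()
    o_codes = geno.reindex(ped["offspring_id"])[snp_ids].to_numpy()

    def key(arr):
        return np.where(arr == MISSING_GENOTYPE, 0, arr + 1)

    idx = key(m_codes) * 16 + key(f_codes) * 4 + key(o_codes)
    n_fam, n_snp = idx.shape
    out = pd.DataFrame(
        {
            "family_id": np.repeat(ped["family_id"].to_numpy(), n_snp),
            "snp_id": np.tile(np.asarray(snp_ids, dtype=object), n_fam),
            "offspring_genotype": o_codes.ravel(),
            "maternal_allele": lut_mat[idx.ravel()],
            "paternal_allele": lut_pat[idx.ravel()],
            "status": lut_status[idx.ravel()],
        }
    )
    return out


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------


def qc_filter(
    genotypes: pd.DataFrame,
    pedigree: pd.DataFrame,
    thresholds: QCThresholds | None = None,
    exact_hwe_max_n: int = 5000,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Exclude SNPs by missingness, founder MAF and founder HWE.

    Missingness is computed over all samples; MAF and the HWE test use
    founders (parents) only.  Returns the filtered genotype matrix and a
    per-SNP report with every statistic and the first failing rule.
    """
    if genotypes is None or genotypes.empty:
        raise ValueError("empty genotype table")
    thresholds = thresholds or QCThresholds()
    thresholds.validate()
    founders = [i for i in pd.unique(pd.concat([pedigree["mother_id"], pedigree["father_id"]]))
                if i in genotypes.index]
    founder_geno = genotypes.loc[founders]

    rows = []
    for snp in genotypes.columns:
        col = genotypes[snp].to_numpy()
        missingness = float(np.mean(col == MISSING_GENOTYPE))
        fg = founder_geno[snp].to_numpy()
        fg = fg[fg != MISSING_GENOTYPE]
        if fg.size == 0:
            maf, hwe_p = float("nan"), float("nan")
        else:
            alt_freq = fg.sum() / (2 * fg.size)
            maf = float(min(alt_freq, 1 - alt_freq))
            counts = [int((fg == 0).sum()), int((fg == 1).sum()), int((fg == 2).sum())]
            if fg.size <= exact_hwe_max_n:
                hwe_p = hwe_exact_test(*counts)
            else:  # pragma: no cover - large-panel fallback
                hwe_p = hwe_chi2_test(*counts)
        first_fail = None
        if missingness > thresholds.max_missingness:
            first_fail = "missingness"
        elif not np.isnan(maf) and maf < thresholds.min_maf:
            first_fail = "maf"
        elif not np.isnan(hwe_p) and hwe_p < thresholds.min_hwe_p:
            first_fail = "hwe"
        rows.append(
            {
                "snp_id": snp,
                "missingness": missingness,
                "maf": maf,
                "hwe_p": hwe_p,
                "n_founders": int(fg.size),
                "pass": first_fail is None,
                "first_fail": first_fail,
            }
        )
    report = pd.DataFrame(rows)
    keep = report.loc[report["pass"], "snp_id"].tolist()
    return genotypes[keep], report


# ---------------------------------------------------------------------------
# association models
# ---------------------------------------------------------------------------

_MODELS = ("maternal", "paternal", "poe")


def _analysis_groups(calls: pd.DataFrame, model: str) -> pd.DataFrame:
    """Select families and code the contrast indicator for one model."""
    resolved = calls[calls["status"] == OriginStatus.RESOLVED.value]
    aa = resolved[resolved["offspring_genotype"] == 0]
    het = resolved[resolved["offspring_genotype"] == 1]
    mat_b = het[het["maternal_allele"] == "B"]  # ApBm: minor allele from the mother
    pat_b = het[het["paternal_allele"] == "B"]  # AmBp: minor allele from the father
    if model == "maternal":
        parts = [aa.assign(indicator=0.0), mat_b.assign(indicator=1.0)]
        labels = ("AA", "ApBm")
    elif model == "paternal":
        parts = [aa.assign(indicator=0.0), pat_b.assign(indicator=1.0)]
        labels = ("AA", "AmBp")
    elif model == "poe":
        parts = [pat_b.assign(indicator=0.0), mat_b.assign(indicator=1.0)]
        labels = ("AmBp", "ApBm")
    else:
        raise ValueError(f"model must be one of {_MODELS}, got {model!r}")
    out = pd.concat(parts, ignore_index=True)
    out.attrs["labels"] = labels
    return out


def genetic_poe_association(
    cohort: TrioCohort,
    origin_calls: pd.DataFrame,
    snp_id: str,
    trait: str,
    visit: str,
    model: str,
    covariates: Sequence[str] = ("age", "sex", "bmi"),
    transform: str = "log_z",
    bmi_trait: str = "bmi",
    min_group: int = 10,
) -> GeeResult | SkipRecord:
    """One allele-origin association: maternal (ApBm vs AA), paternal (AmBp vs AA)
    or poe (ApBm vs AmBp).

    The trait is log-transformed then z-scored on the analysis sample
    (``transform="log_z"``, the default; also ``"z"`` or ``"none"``).  The fit
    is a Gaussian GEE with independence working correlation clustered by
    family and robust SEs.  Groups below ``min_group`` produce a
    :class:`SkipRecord` carrying the counts.
    """
    calls = origin_calls[origin_calls["snp_id"] == snp_id]
    if calls.empty:
        raise ValueError(f"no origin calls for SNP {snp_id!r}")
    groups = _analysis_groups(calls, model)
    labels = groups.attrs["labels"]

    off = cohort.offspring_table(trait, visit)
    frame = groups.set_index("family_id").join(off, how="inner")
    frame = frame.rename(columns={"value": "y"})
    cov_cols: list[str] = []
    if "age" in covariates:
        cov_cols.append("age")
    if "sex" in covariates:
        frame["sex01"] = (frame["sex"] == "F").astype(float)
        cov_cols.append("sex01")
    if "bmi" in covariates and trait != bmi_trait and bmi_trait in cohort.trait_names:
        frame["bmi"] = cohort.offspring_table(bmi_trait, visit)["value"].reindex(frame.index)
        cov_cols.append("bmi")
    extra = [c for c in covariates if c not in ("age", "sex", "bmi")]
    for cov in extra:  # any other covariate is looked up as a trait at this visit
        if cov not in cohort.trait_names:
            raise ValueError(f"covariate {cov!r} is not a trait in this cohort")
        frame[cov] = cohort.offspring_table(cov, visit)["value"].reindex(frame.index)
        cov_cols.append(cov)

    frame = frame.dropna(subset=["y", "indicator"] + cov_cols)
    counts = {
        labels[0]: int((frame["indicator"] == 0.0).sum()),
        labels[1]: int((frame["indicator"] == 1.0).sum()),
    }
    if min(counts.values()) < min_group:
        return SkipRecord(trait, visit, "all", f"{model}:{snp_id}",
                          f"group below floor {counts}", n=len(frame))

    y = frame["y"].to_numpy(dtype=float)
    if transform == "log_z":
        y = zscore(log_transform(y))
    elif transform == "z":
        y = zscore(y)
    elif transform != "none":
        raise ValueError(f"unknown transform {transform!r}")
    if np.std(y) == 0:
        return SkipRecord(trait, visit, "all", f"{model}:{snp_id}", "constant trait", n=len(frame))

    X = np.column_stack(
        [np.ones(len(frame)), frame["indicator"].to_numpy()]
        + [frame[c].to_numpy(dtype=float) for c in cov_cols]
    )
    fam = pd.Categorical(frame.index).codes
    gee = sm.GEE(y, X, groups=fam, family=sm.families.Gaussian(),
                 cov_struct=sm.cov_struct.Independence())
    res = gee.fit()
    return GeeResult(
        snp_id=snp_id,
        trait=trait,
        visit=visit,
        model=model,
        estimate=float(res.params[1]),
        se=float(res.bse[1]),
        p_value=float(res.pvalues[1]),
        n_per_group=counts,
        covariates=list(cov_cols),
    )


def genetic_poe_scan(
    cohort: TrioCohort,
    targets: Sequence[tuple[str, str, str]],
    origin_calls: pd.DataFrame | None = None,
    qc: QCThresholds | None = None,
    models: Sequence[str] = _MODELS,
    **kwargs,
) -> pd.DataFrame:
    """Run all three origin models for each (snp, trait, visit) target.

    Applies QC first (founder MAF / missingness / HWE) unless pre-computed
    ``origin_calls`` are supplied.  Returns one tidy row per target with the
    maternal / paternal / poe estimate, SE and p, mirroring the usual
    published layout.
    """
    if origin_calls is None:
        if cohort.genotypes is None:
            raise ValueError("cohort has no genotypes")
        filtered, _report = qc_filter(cohort.genotypes, cohort.pedigree, qc)
        sub = TrioCohort(cohort.pedigree, cohort.phenotypes, filtered, cohort.snps, cohort.truth)
        origin_calls = assign_origins(sub)
    rows = []
    for snp_id, trait, visit in targets:
        row: dict = {"snp_id": snp_id, "trait": trait, "visit": visit}
        if snp_id not in set(origin_calls["snp_id"]):
            row["status"] = "skipped: SNP removed by QC or absent"
            rows.append(row)
            continue
        status = "ok"
        for model in models:
            res = genetic_poe_association(cohort, origin_calls, snp_id, trait, visit, model, **kwargs)
            if isinstance(res, SkipRecord):
                status = f"skipped ({model}): {res.reason}"
                continue
            row[f"{model}_estimate"] = res.estimate
            row[f"{model}_se"] = res.se
            row[f"{model}_p"] = res.p_value
        row["status"] = status
        rows.append(row)
    columns = ["snp_id", "trait", "visit", "status"]
    for model in models:
        columns += [f"{model}_estimate", f"{model}_se", f"{model}_p"]
    return pd.DataFrame(rows, columns=columns)
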