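"""Synthetic trio-cohort generator with known parental and imprinted effects.

The generator draws founder couples, Mendelian-transmits SNP alleles to one
offspring per family, and builds longitudinal offspring phenotypes whose
maternal/paternal slopes, family random intercepts, residual scales and
allele-origin (imprinted) genetic effects are all set by the configuration —
giving every downstream estimator a known truth to recover.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort import MISSING_GENOTYPE, CohortTruth, TrioCohort
from .config import SimulationConfig, SnpSpec

__all__ = ["simulate_cohort", "transmit_alleles", "inject_missingness_and_errors"]


def transmit_alleles(mother_genotype: int, father_genotype: int, rng: np.random.Generator):
    """Mendelian transmission of one SNP from a parental pair to an offspring.

    Each transmitted allele is drawn uniformly from the corresponding parent's
    two alleles (so a heterozygote transmits the minor allele with probability
    1/2).  Returns ``(offspring_code, maternal_minor, paternal_minor)`` where
    the last two count transmitted minor alleles (0 or 1).  A missing parental
    genotype flags the corresponding transmitted allele — and the offspring
    code — as unknown (``None`` / :data:`MISSING_GENOTYPE`).
    """
    def _draw(code):
        if code == MISSING_GENOTYPE or code is None:
            return None
        if code not in (0, 1, 2):
            raise ValueError(f"invalid parental genotype code {code!r}")
        if code == 1:
            return int(rng.integers(0, 2))
        return code // 2

    mat = _draw(mother_genotype)
    pat = _draw(father_genotype)
    if mat is None or pat is None:
        return MISSING_GENOTYPE, mat, pat
    return mat + pat, mat, pat


def _transmit_vector(parent_codes: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Vectorized gamete draw: per parent, number of minor alleles transmitted (0/1)."""
    coin = rng.integers(0, 2, size=parent_codes.shape)
    out = np.where(parent_codes == 2, 1, np.where(parent_codes == 1, coin, 0))
    return out.astype(np.int16)


def _founder_codes(n: int, maf: float, rng: np.random.Generator) -> np.ndarray:
    """Founder genotypes in Hardy-Weinberg equilibrium: sum of two Bernoulli(maf) alleles."""
    return (rng.random(n) < maf).astype(np.int16) + (rng.random(n) < maf).astype(np.int16)


def simulate_cohort(config: SimulationConfig) -> TrioCohort:
    """Generate a :class:`TrioCohort` from a validated config; deterministic given seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_families

    width = max(4, len(str(n)))
    fam_ids = np.array([f"fam{i:0{width}d}" for i in range(1, n + 1)])
    mother_ids = np.array([f"m{i:0{width}d}" for i in range(1, n + 1)])
    father_ids = np.array([f"f{i:0{width}d}" for i in range(1, n + 1)])
    offspring_ids = np.array([f"o{i:0{width}d}" for i in range(1, n + 1)])

    sex = np.where(rng.random(n) < config.prop_female, "F", "M")
    pedigree = pd.DataFrame(
        {
            "family_id": fam_ids,
            "mother_id": mother_ids,
            "father_id": father_ids,
            "offspring_id": offspring_ids,
            "offspring_sex": sex,
        }
    )

    mother_age = rng.uniform(*config.mother_age_range, size=n).round(1)
    father_age = rng.uniform(*config.father_age_range, size=n).round(1)

    # --- genotypes and transmission truth --------------------------------
    geno_cols: dict[str, np.ndarray] = {}
    origin_rows = []
    genetic_load: dict[str, np.ndarray] = {}  # trait -> latent genetic effect
    for snp in config.snps:
        m_codes = _founder_codes(n, snp.minor_allele_freq, rng)
        f_codes = _founder_codes(n, snp.minor_allele_freq, rng)
        mat = _transmit_vector(m_codes, rng)
        pat = _transmit_vector(f_codes, rng)
        o_codes = (mat + pat).astype(np.int16)
        geno_cols[snp.id] = np.concatenate([m_codes, f_codes, o_codes])
        origin_rows.append(
            pd.DataFrame(
                {
                    "family_id": fam_ids,
                    "snp_id": snp.id,
                    "maternal_allele": mat,
                    "paternal_allele": pat,
                }
            )
        )
        if snp.target_trait is not None:
            load = snp.effect_maternal_allele * mat + snp.effect_paternal_allele * pat
            genetic_load[snp.target_trait] = genetic_load.get(snp.target_trait, 0.0) + load

    all_ids = np.concatenate([mother_ids, father_ids, offspring_ids])
    genotypes = None
    snp_table = None
    if config.snps:
        genotypes = pd.DataFrame(geno_cols, index=pd.Index(all_ids, name="individual_id"))
        snp_table = pd.DataFrame(
            {
                "snp_id": [s.id for s in config.snps],
                "chrom": [s.chrom for s in config.snps],
                "pos": [s.pos if s.pos is not None else 1000 * (i + 1) for i, s in enumerate(config.snps)],
                "ref": [s.ref for s in config.snps],
                "alt": [s.alt for s in config.snps],
            }
        )
    origins = (
        pd.concat(origin_rows, ignore_index=True)
        if origin_rows
        else pd.DataFrame(columns=["family_id", "snp_id", "maternal_allele", "paternal_allele"])
    )

    # --- parental phenotype missingness pattern ---------------------------
    drop_family = rng.random(n) < config.missing_parent_rate
    drop_mother = drop_family & (rng.random(n) < 0.5)
    drop_father = drop_family & ~drop_mother

    # --- offspring visit ages (shared across traits within a visit) -------
    visit_age = {
        v.label: v.age + rng.uniform(-config.age_jitter, config.age_jitter, size=n).round(2)
        for v in config.visits
    }

    # --- phenotypes --------------------------------------------------------
    cols: dict[str, list] = {k: [] for k in ("individual_id", "family_id", "role", "sex", "visit", "age", "trait", "value")}

    def _emit(ids, fams, role, sexes, visit, ages, trait, values):
        cols["individual_id"].append(ids)
        cols["family_id"].append(fams)
        cols["role"].append(np.repeat(role, len(ids)))
        cols["sex"].append(sexes)
        cols["visit"].append(np.repeat(visit, len(ids)))
        cols["age"].append(ages)
        cols["trait"].append(np.repeat(trait, len(ids)))
        cols["value"].append(values)

    female = np.repeat("F", n)
    male = np.repeat("M", n)
    rho = config.spousal_correlation
    for trait in config.traits:
        z_m = rng.standard_normal(n)
        z_f = rho * z_m + np.sqrt(max(0.0, 1.0 - rho**2)) * rng.standard_normal(n)
        u_fam = trait.family_random_sd * rng.standard_normal(n)
        gen = genetic_load.get(trait.name, np.zeros(n))

        def _value(mean, sd, z):
            raw = mean + sd * z
            return np.exp(raw) if trait.skew == "lognormal" else raw

        mv = _value(trait.mother_mean, trait.mother_sd, z_m)
        fv = _value(trait.father_mean, trait.father_sd, z_f)
        mv = np.where(drop_mother, np.nan, mv)
        fv = np.where(drop_father, np.nan, fv)
        _emit(mother_ids, fam_ids, "mother", female, "baseline", mother_age, trait.name, mv)
        _emit(father_ids, fam_ids, "father", male, "baseline", father_age, trait.name, fv)

        for visit in config.visits:
            bm = np.array([trait.maternal_slope(visit.label, s) for s in ("M", "F")])
            bp = np.array([trait.paternal_slope(visit.label, s) for s in ("M", "F")])
            is_f = (sex == "F").astype(int)
            latent = (
                bm[is_f] * z_m
                + bp[is_f] * z_f
                + gen
                + u_fam
                + trait.residual_sd * rng.standard_normal(n)
            )
            ov = _value(trait.offspring_mean, trait.offspring_sd, latent)
            _emit(offspring_ids, fam_ids, "offspring", sex, visit.label, visit_age[visit.label], trait.name, ov)

    phenotypes = pd.DataFrame({k: np.concatenate(v) for k, v in cols.items()})
    phenotypes["age"] = phenotypes["age"].astype(float)
    phenotypes["value"] = phenotypes["value"].astype(float)

    cohort = TrioCohort(
        pedigree=pedigree,
        phenotypes=phenotypes,
        genotypes=genotypes,
        snps=snp_table,
        truth=CohortTruth(config=config, origins=origins),
    )

    if any(s.genotype_missing_rate > 0 or s.genotyping_error_rate > 0 for s in config.snps):
        cohort = inject_missingness_and_errors(cohort, rng=rng)
    return cohort


def inject_missingness_and_errors(
    cohort: TrioCohort,
    missing_rate: float | None = None,
    error_rate: float | None = None,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> TrioCohort:
    """Perturb observed genotypes: random no-calls and random miscalls.

    Rates default to each SNP's configured ``genotype_missing_rate`` /
    ``genotyping_error_rate`` (uniform overrides may be passed explicitly).
    Errors flip a call to one of the other two codes uniformly.  Every
    perturbation is appended to the cohort truth record.  Rates of zero leave
    the cohort unchanged.
    """
    if cohort.genotypes is None:
        raise ValueError("cohort has no genotypes to perturb")
    if rng is None:
        rng = np.random.default_rng(seed)
    geno = cohort.genotypes.copy()
    truth = cohort.truth
    spec_by_id: dict[str, SnpSpec] = {}
    if truth is not None and truth.config is not None:
        spec_by_id = {s.id: s for s in truth.config.snps}

    records = []
    n = len(geno.index)
    for snp_id in geno.columns:
        spec = spec_by_id.get(snp_id)
        m_rate = missing_rate if missing_rate is not None else (spec.genotype_missing_rate if spec else 0.0)
        e_rate = error_rate if error_rate is not None else (spec.genotyping_error_rate if spec else 0.0)
        if not 0.0 <= m_rate <= 1.0 or not 0.0 <= e_rate <= 1.0:
            raise ValueError("rates must be in [0, 1]")
        if m_rate == 0 and e_rate == 0:
            continue
        col = geno[snp_id].to_numpy().copy()
        observed = col != MISSING_GENOTYPE

        flip = (rng.random(n) < e_rate) & observed
        if flip.any():
            # replace with one of the two other valid codes, uniformly
            shift = rng.integers(1, 3, size=n)
            new = (col + shift) % 3
            for idx in np.flatnonzero(flip):
                records.append((geno.index[idx], snp_id, "flip", int(col[idx]), int(new[idx])))
            col = np.where(flip, new, col).astype(col.dtype)

        miss = (rng.random(n) < m_rate) & (col != MISSING_GENOTYPE)
        if miss.any():
            for idx in np.flatnonzero(miss):
                records.append((geno.index[idx], snp_id, "missing", int(col[idx]), MISSING_GENOTYPE))
            col = np.where(miss, MISSING_GENOTYPE, col).astype(col.dtype)
        geno[snp_id] = col

    new_pert = pd.DataFrame(
        records, columns=["individual_id", "snp_id", "kind", "true_code", "observed_code"]
    )
    if truth is not None:
        pert = (
            pd.concat([truth.perturbations, new_pert], ignore_index=True)
            if len(truth.perturbations)
            else new_pert
        )
        truth = CohortTruth(config=truth.config, origins=truth.origins, perturbations=pert)
    return TrioCohort(
        pedigree=cohort.pedigree,
        phenotypes=cohort.phenotypes,
        genotypes=geno,
        snps=cohort.snps,
        truth=truth,
    )
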