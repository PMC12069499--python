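"""Ready-made simulation configurations emulating the Pune trio cohorts.

`pmns_like_config` mirrors the design of the Pune Maternal Nutrition Study:
~700 parent-offspring trios, offspring follow-up at birth / 6 / 12 / 24
years, young short-statured rural parents, and maternal/paternal effect sizes
per visit set to the published all-offspring estimates (magnitudes ~0.05-0.45
per parental SD).  Glucose shows the published maternal bias at 6-24 y;
insulin's maternal effect is negative at 6 y and positive from 12 y.  Three
imprinted-SNP analogues (insulin-secretion, triglyceride and HDL loci) carry
maternal-biased allele effects of the order of the published reciprocal-
heterozygote estimates.  `pcs_like_config` is the smaller urban replication
design (~400 trios, visits 4 / 8 / 21 y).
"""
from __future__ import annotations

from .config import SimulationConfig, SnpSpec, TraitSpec, Visit

__all__ = ["pmns_like_config", "pcs_like_config"]


def _pmns_traits() -> list[TraitSpec]:
    return [
        TraitSpec(
            name="weight",
            beta_maternal={"birth": 0.176, "6y": 0.207, "12y": 0.312, "24y": 0.365},
            beta_paternal={"birth": 0.058, "6y": 0.206, "12y": 0.345, "24y": 0.259},
            mother_mean=42.0, mother_sd=5.0, father_mean=55.0, father_sd=7.0,
            family_random_sd=0.3,
        ),
        TraitSpec(
            name="height",
            beta_maternal={"birth": 0.223, "6y": 0.421, "12y": 0.430, "24y": 0.482},
            beta_paternal={"birth": 0.165, "6y": 0.366, "12y": 0.460, "24y": 0.415},
            mother_mean=152.0, mother_sd=5.0, father_mean=164.0, father_sd=6.0,
            family_random_sd=0.3,
        ),
        TraitSpec(
            name="bmi",
            beta_maternal={"birth": 0.106, "6y": 0.101, "12y": 0.217, "24y": 0.309},
            beta_paternal={"birth": 0.063, "6y": 0.112, "12y": 0.221, "24y": 0.283},
            mother_mean=18.1, mother_sd=1.9, father_mean=20.4, father_sd=2.2,
            family_random_sd=0.3,
        ),
        TraitSpec(
            name="fasting_glucose",
            beta_maternal={"6y": 0.287, "12y": 0.212, "24y": 0.082},
            beta_paternal={"6y": 0.174, "12y": 0.078, "24y": 0.030},
            # lognormal: mean/sd are log-scale (~4.5 mmol/l, ~8% CV)
            mother_mean=1.50, mother_sd=0.08, father_mean=1.53, father_sd=0.08,
            offspring_mean=1.50, offspring_sd=0.3,
            family_random_sd=0.25, skew="lognormal",
        ),
        TraitSpec(
            name="fasting_insulin",
            beta_maternal={"6y": -0.090, "12y": 0.158, "24y": 0.165},
            beta_paternal={"6y": 0.069, "12y": 0.010, "24y": 0.132},
            mother_mean=3.3, mother_sd=0.5, father_mean=3.4, father_sd=0.5,
            offspring_mean=3.0, offspring_sd=0.4,
            family_random_sd=0.25, skew="lognormal",
        ),
        TraitSpec(
            name="homa2b",
            beta_maternal={"6y": -0.023, "12y": 0.183, "24y": 0.156},
            beta_paternal={"6y": 0.128, "12y": 0.068, "24y": 0.038},
            mother_mean=4.6, mother_sd=0.35, father_mean=4.6, father_sd=0.35,
            offspring_mean=4.6, offspring_sd=0.35,
            family_random_sd=0.25, skew="lognormal",
        ),
        TraitSpec(
            name="triglycerides",
            beta_maternal={"6y": 0.208, "12y": 0.213, "24y": 0.208},
            beta_paternal={"6y": 0.120, "12y": 0.204, "24y": 0.249},
            mother_mean=0.1, mother_sd=0.35, father_mean=0.2, father_sd=0.35,
            offspring_mean=0.0, offspring_sd=0.35,
            family_random_sd=0.25, skew="lognormal",
        ),
        TraitSpec(
            name="cholesterol",
            beta_maternal={"6y": 0.279, "12y": 0.364, "24y": 0.319},
            beta_paternal={"6y": 0.151, "12y": 0.230, "24y": 0.250},
            mother_mean=4.2, mother_sd=0.8, father_mean=4.4, father_sd=0.9,
            offspring_mean=4.0, offspring_sd=0.8,
            family_random_sd=0.3,
        ),
        TraitSpec(
            name="hdl_cholesterol",
            beta_maternal={"6y": 0.244, "12y": 0.390, "24y": 0.382},
            beta_paternal={"6y": 0.242, "12y": 0.251, "24y": 0.237},
            mother_mean=1.2, mother_sd=0.25, father_mean=1.1, father_sd=0.25,
            offspring_mean=1.2, offspring_sd=0.25,
            family_random_sd=0.3,
        ),
    ]


def _poe_snps() -> list[SnpSpec]:
    # imprinted-locus analogues: allele-origin-asymmetric effects of the
    # magnitude of the published reciprocal-heterozygote estimates
    return [
        SnpSpec(id="snp_ins_secretion", minor_allele_freq=0.35,
                effect_maternal_allele=0.35, effect_paternal_allele=-0.05,
                target_trait="homa2b", chrom="11", pos=2818521, ref="C", alt="T"),
        SnpSpec(id="snp_triglyceride", minor_allele_freq=0.45,
                effect_maternal_allele=-0.20, effect_paternal_allele=0.05,
                target_trait="triglycerides", chrom="7", pos=130748625, ref="C", alt="T"),
        SnpSpec(id="snp_hdl", minor_allele_freq=0.25,
                effect_maternal_allele=-0.13, effect_paternal_allele=0.0,
                target_trait="hdl_cholesterol", chrom="11", pos=1675619, ref="C", alt="T"),
    ]


def pmns_like_config(n_families: int = 700, seed: int = 0) -> SimulationConfig:
    """Rural birth-cohort design: ~700 trios, visits at birth/6/12/24 years."""
    cfg = SimulationConfig(
        n_families=n_families,
        visits=[Visit("birth", 0.0), Visit("6y", 6.0), Visit("12y", 12.0), Visit("24y", 24.0)],
        traits=_pmns_traits(),
        snps=_poe_snps(),
        prop_female=0.48,
        missing_parent_rate=0.08,
        seed=seed,
    )
    cfg.validate()
    return cfg


def pcs_like_config(n_families: int = 400, seed: int = 0) -> SimulationConfig:
    """Urban replication design: ~400 trios, visits at 4/8/21 years."""
    traits = [t for t in _pmns_traits() if t.name in
              ("weight", "height", "bmi", "fasting_glucose", "cholesterol", "hdl_cholesterol")]
    remap = {"birth": None, "6y": "4y", "12y": "8y", "24y": "21y"}
    for t in traits:
        for attr in ("beta_maternal", "beta_paternal"):
            sched = getattr(t, attr)
            if isinstance(sched, dict):
                setattr(t, attr, {remap[k]: v for k, v in sched.items() if remap[k]})
    cfg = SimulationConfig(
        n_families=n_families,
        visits=[Visit("4y", 4.0), Visit("8y", 8.0), Visit("21y", 21.0)],
        traits=traits,
        snps=[],
        prop_female=0.48,
        missing_parent_rate=0.08,
        seed=seed,
    )
    cfg.validate()
    return cfg
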