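"""Configuration objects for trio-cohort simulation and analysis.

Every knob of the synthetic generator and of the analysis pipeline lives in a
small validated dataclass here, so that a whole run is reproducible from one
config plus one seed.
"""
from __future__ import annotations

from collections.abc import Mapping
from dataclasses import dataclass, field
from typing import Any, Callable, Sequence

import yaml

__all__ = [
    "ConfigError",
    "Visit",
    "TraitSpec",
    "SnpSpec",
    "SimulationConfig",
    "QCThresholds",
    "PipelineConfig",
    "resolve_effect",
    "simulation_config_from_dict",
    "load_yaml_config",
]

SKEW_KINDS = ("none", "lognormal")
TRANSFORM_KINDS = ("none", "log", "log2", "log_z", "inverse_normal", "zscore")

# an effect can be a constant, a per-visit mapping, or a per-visit/per-sex
# mapping; "*" is the fallback key at either level
EffectLike = float | Mapping[str, Any] | Callable[[str, str], float]


class ConfigError(ValueError):
    """Invalid configuration; the message names the offending field."""


def resolve_effect(effect: EffectLike, visit: str, sex: str) -> float:
    """Resolve an effect specification to a slope for one visit and offspring sex.

    ``effect`` may be a plain number (same slope everywhere), a mapping keyed
    by visit label (value either a number or a ``{"M": .., "F": ..}`` mapping),
    or a callable ``f(visit, sex)``.  The key ``"*"`` acts as a default at
    either level; missing entries resolve to 0.
    """
    if callable(effect):
        return float(effect(visit, sex))
    if isinstance(effect, Mapping):
        v = effect.get(visit, effect.get("*", 0.0))
        if isinstance(v, Mapping):
            v = v.get(sex, v.get("*", 0.0))
        return float(v)
    return float(effect)


@dataclass(frozen=True)
class Visit:
    """A follow-up wave: a categorical label plus the nominal offspring age in years."""

    label: str
    age: float


@dataclass
class TraitSpec:
    """Generative model for one trait in the synthetic cohort.

    The offspring value at visit ``v`` for an offspring of sex ``s`` is built
    from a standardized latent variable

        latent = bm(v, s) * z_mother + bp(v, s) * z_father
                 + allele-origin genetic effects + family intercept + residual

    and emitted as ``offspring_mean + offspring_sd * latent`` (or
    ``exp(offspring_mean + offspring_sd * latent)`` for lognormal traits, in
    which case the mean/sd parameters are on the log scale).  Parent values are
    affine (or log-affine) in an independent standard-normal latent, so
    z-scoring a parent's observed trait recovers the latent exactly and an OLS
    slope on it estimates the configured beta directly.
    """

    name: str
    beta_maternal: EffectLike = 0.0
    beta_paternal: EffectLike = 0.0
    mother_mean: float = 0.0
    mother_sd: float = 1.0
    father_mean: float = 0.0
    father_sd: float = 1.0
    offspring_mean: float = 0.0
    offspring_sd: float = 1.0
    family_random_sd: float = 0.0
    residual_sd: float = 1.0
    skew: str = "none"

    def maternal_slope(self, visit: str, sex: str) -> float:
        return resolve_effect(self.beta_maternal, visit, sex)

    def paternal_slope(self, visit: str, sex: str) -> float:
        return resolve_effect(self.beta_paternal, visit, sex)

    def validate(self) -> None:
        if not self.name:
            raise ConfigError("TraitSpec.name must be non-empty")
        if self.residual_sd <= 0:
            raise ConfigError(f"TraitSpec.residual_sd must be > 0 for {self.name!r}")
        for fld in ("mother_sd", "father_sd", "offspring_sd"):
            if getattr(self, fld) < 0:
                raise ConfigError(f"TraitSpec.{fld} must be >= 0 for {self.name!r}")
        if self.family_random_sd < 0:
            raise ConfigError(f"TraitSpec.family_random_sd must be >= 0 for {self.name!r}")
        if self.skew not in SKEW_KINDS:
            raise ConfigError(f"TraitSpec.skew must be one of {SKEW_KINDS} for {self.name!r}")


@dataclass
class SnpSpec:
    """Generative model for one biallelic SNP with allele-origin-specific effects.

    ``effect_maternal_allele``/``effect_paternal_allele`` are added to the
    latent trait (in residual-SD units) per copy of the minor allele inherited
    from that parent; making them unequal simulates an imprinted locus.
    """

    id: str
    minor_allele_freq: float
    effect_maternal_allele: float = 0.0
    effect_paternal_allele: float = 0.0
    target_trait: str | None = None
    genotype_missing_rate: float = 0.0
    genotyping_error_rate: float = 0.0
    chrom: str = "1"
    pos: int | None = None
    ref: str = "A"
    alt: str = "B"

    def validate(self) -> None:
        if not self.id:
            raise ConfigError("SnpSpec.id must be non-empty")
        if not 0.0 < self.minor_allele_freq < 1.0:
            raise ConfigError(f"SnpSpec.minor_allele_freq must be in (0, 1) for {self.id!r}")
        for fld in ("genotype_missing_rate", "genotyping_error_rate"):
            v = getattr(self, fld)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"SnpSpec.{fld} must be in [0, 1] for {self.id!r}")


@dataclass
class SimulationConfig:
    """All knobs of the synthetic trio-cohort generator."""

    n_families: int
    visits: Sequence[Visit]
    traits: Sequence[TraitSpec]
    snps: Sequence[SnpSpec] = field(default_factory=list)
    prop_female: float = 0.5
    missing_parent_rate: float = 0.0
    spousal_correlation: float = 0.0
    age_jitter: float = 0.5
    mother_age_range: tuple[float, float] = (18.0, 30.0)
    father_age_range: tuple[float, float] = (21.0, 36.0)
    seed: int = 0

    def validate(self) -> None:
        if self.n_families < 1:
            raise ConfigError("SimulationConfig.n_families must be >= 1")
        if not self.visits:
            raise ConfigError("SimulationConfig.visits must be non-empty")
        ages = [v.age for v in self.visits]
        if any(b <= a for a, b in zip(ages, ages[1:])):
            raise ConfigError("SimulationConfig.visits ages must be strictly increasing")
        labels = [v.label for v in self.visits]
        if len(set(labels)) != len(labels):
            raise ConfigError("SimulationConfig.visits labels must be unique")
        for fld in ("prop_female", "missing_parent_rate"):
            v = getattr(self, fld)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"SimulationConfig.{fld} must be in [0, 1]")
        if not -1.0 <= self.spousal_correlation <= 1.0:
            raise ConfigError("SimulationConfig.spousal_correlation must be in [-1, 1]")
        if self.age_jitter < 0:
            raise ConfigError("SimulationConfig.age_jitter must be >= 0")
        if not self.traits:
            raise ConfigError("SimulationConfig.traits must be non-empty")
        names = [t.name for t in self.traits]
        if len(set(names)) != len(names):
            raise ConfigError("SimulationConfig.traits names must be unique")
        for t in self.traits:
            t.validate()
        snp_ids = [s.id for s in self.snps]
        if len(set(snp_ids)) != len(snp_ids):
            raise ConfigError("SimulationConfig.snps ids must be unique")
        for s in self.snps:
            s.validate()
            if s.target_trait is not None and s.target_trait not in names:
                raise ConfigError(
                    f"SnpSpec.target_trait {s.target_trait!r} of {s.id!r} is not a configured trait"
                )


@dataclass
class QCThresholds:
    """SNP exclusion thresholds: missingness > 5%, MAF < 1%, HWE p < 0.05 by default."""

    max_missingness: float = 0.05
    min_maf: float = 0.01
    min_hwe_p: float = 0.05

    def validate(self) -> None:
        for fld in ("max_missingness", "min_maf", "min_hwe_p"):
            v = getattr(self, fld)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"QCThresholds.{fld} must be in [0, 1]")


@dataclass
class PipelineConfig:
    """End-to-end run options shared by the reporting layer and the CLI."""

    transforms: dict[str, str] = field(default_factory=dict)
    bmi_trait: str = "bmi"
    alpha: float = 0.05
    bonferroni_p: float = 0.001
    cov_method: str = "zero"
    qc: QCThresholds = field(default_factory=QCThresholds)
    seed: int = 0

    def validate(self) -> None:
        for trait, kind in self.transforms.items():
            if kind not in TRANSFORM_KINDS:
                raise ConfigError(f"PipelineConfig.transforms[{trait!r}] must be one of {TRANSFORM_KINDS}")
        if self.cov_method not in ("zero", "joint", "bootstrap"):
            raise ConfigError("PipelineConfig.cov_method must be zero, joint or bootstrap")
        self.qc.validate()


def simulation_config_from_dict(d: Mapping[str, Any]) -> SimulationConfig:
    """Build a validated :class:`SimulationConfig` from a plain (YAML-style) mapping."""
    try:
        visits = [Visit(label=str(v["label"]), age=float(v["age"])) for v in d["visits"]]
        traits = [TraitSpec(**t) for t in d["traits"]]
        snps = [SnpSpec(**s) for s in d.get("snps", [])]
    except (KeyError, TypeError) as exc:
        raise ConfigError(f"malformed simulation config: {exc}") from exc
    known = {
        k: d[k]
        for k in (
            "prop_female",
            "missing_parent_rate",
            "spousal_correlation",
            "age_jitter",
            "seed",
        )
        if k in d
    }
    cfg = SimulationConfig(
        n_families=int(d["n_families"]), visits=visits, traits=traits, snps=snps, **known
    )
    cfg.validate()
    return cfg


def load_yaml_config(path: str) -> dict[str, Any]:
    with open(path) as fh:
        out = yaml.safe_load(fh)
    if not isinstance(out, dict):
        raise ConfigError(f"config file {path} did not parse to a mapping")
    return out
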