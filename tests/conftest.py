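import pytest
from hypothesis import HealthCheck, settings

from triopoe.config import SimulationConfig, SnpSpec, TraitSpec, Visit
from triopoe.simulate import simulate_cohort

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_config(
    n_families=400,
    beta_m=0.3,
    beta_p=0.1,
    n_visits=1,
    family_random_sd=0.0,
    snps=(),
    seed=0,
    **kwargs,
):
    """One-trait test config; offspring scale unity so slopes estimate beta directly."""
    visits = [Visit(f"v{i}", 2.0 * i + 2.0) for i in range(n_visits)]
    trait = TraitSpec(
        name="trait",
        beta_maternal=beta_m,
        beta_paternal=beta_p,
        family_random_sd=family_random_sd,
        **kwargs,
    )
    return SimulationConfig(
        n_families=n_families, visits=visits, traits=[trait], snps=list(snps), seed=seed
    )


def lognormal_snp_config(n_families=700, effect_m=0.3, effect_p=0.0, maf=0.3, seed=0,
                         beta_m=0.0, beta_p=0.0):
    """Positive-valued (lognormal) trait with one allele-origin-specific SNP."""
    trait = TraitSpec(
        name="trait",
        beta_maternal=beta_m,
        beta_paternal=beta_p,
        offspring_mean=3.0,
        offspring_sd=1.0,
        mother_mean=3.0,
        mother_sd=0.4,
        father_mean=3.0,
        father_sd=0.4,
        skew="lognormal",
    )
    snp = SnpSpec(
        id="snp1",
        minor_allele_freq=maf,
        effect_maternal_allele=effect_m,
        effect_paternal_allele=effect_p,
        target_trait="trait",
    )
    return SimulationConfig(
        n_families=n_families, visits=[Visit("6y", 6.0)], traits=[trait], snps=[snp], seed=seed
    )


@pytest.fixture(scope="session")
def demo_cohort():
    """A moderately sized cohort with genetics, reused by read-only tests."""
    return simulate_cohort(lognormal_snp_config(n_families=600, seed=42))
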