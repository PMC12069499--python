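"""In-memory containers for a parent-offspring trio cohort.

A cohort couples a pedigree (one offspring per family with both parents), a
long-format phenotype table (one row per individual per visit per trait), and
optionally a genotype matrix with its SNP annotation.  Simulated cohorts also
carry a truth record so downstream estimates can be checked against the
generating parameters.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .config import SimulationConfig

__all__ = ["TrioCohort", "CohortTruth", "MISSING_GENOTYPE", "PHENOTYPE_COLUMNS"]

#: sentinel genotype code for a missing call (valid codes are 0, 1, 2)
MISSING_GENOTYPE = -1

PHENOTYPE_COLUMNS = [
    "individual_id",
    "family_id",
    "role",
    "sex",
    "visit",
    "age",
    "trait",
    "value",
]

ROLES = ("mother", "father", "offspring")


@dataclass
class CohortTruth:
    """Generator-only ground truth: config, transmitted-allele origins, perturbations.

    ``origins`` has one row per (family, SNP) with the number of minor alleles
    transmitted by each parent (0/1, or -1 when the parent genotype was
    missing).  ``perturbations`` records every genotype the error/missingness
    injector touched.
    """

    config: "SimulationConfig"
    origins: pd.DataFrame
    perturbations: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["individual_id", "snp_id", "kind", "true_code", "observed_code"]
        )
    )


@dataclass
class TrioCohort:
    """A trio cohort: pedigree + long phenotypes (+ genotypes, + truth)."""

    pedigree: pd.DataFrame  # family_id, mother_id, father_id, offspring_id, offspring_sex
    phenotypes: pd.DataFrame  # PHENOTYPE_COLUMNS
    genotypes: pd.DataFrame | None = None  # index individual_id, columns SNP ids, int codes
    snps: pd.DataFrame | None = None  # snp_id, chrom, pos, ref, alt
    truth: CohortTruth | None = None

    # -- validation ------------------------------------------------------

    def validate(self) -> None:
        """Check the container invariants; raises ``ValueError`` on violation."""
        ped = self.pedigree
        for col in ("family_id", "mother_id", "father_id", "offspring_id", "offspring_sex"):
            if col not in ped.columns:
                raise ValueError(f"pedigree is missing column {col!r}")
        if ped["family_id"].duplicated().any():
            dup = ped.loc[ped["family_id"].duplicated(), "family_id"].iloc[0]
            raise ValueError(f"family {dup!r} appears more than once in the pedigree")
        ph = self.phenotypes
        missing = [c for c in PHENOTYPE_COLUMNS if c not in ph.columns]
        if missing:
            raise ValueError(f"phenotype table is missing columns {missing}")
        bad_roles = set(ph["role"].unique()) - set(ROLES)
        if bad_roles:
            raise ValueError(f"phenotype table has unknown roles {sorted(bad_roles)}")
        dup = ph.duplicated(subset=["individual_id", "visit", "trait"])
        if dup.any():
            row = ph.loc[dup].iloc[0]
            raise ValueError(
                "duplicate phenotype record for "
                f"({row['individual_id']!r}, {row['visit']!r}, {row['trait']!r})"
            )
        # every offspring phenotype row must belong to a pedigree family with
        # exactly one mother and one father id
        fam_ids = set(ped["family_id"])
        orphan = set(ph["family_id"].unique()) - fam_ids
        if orphan:
            raise ValueError(f"phenotype rows reference unknown families {sorted(orphan)[:5]}")
        if self.genotypes is not None:
            codes = self.genotypes.to_numpy()
            ok = np.isin(codes, (MISSING_GENOTYPE, 0, 1, 2))
            if not ok.all():
                bad = np.unique(codes[~ok])
                raise ValueError(f"genotype matrix contains invalid codes {bad.tolist()}")

    # -- convenience accessors ------------------------------------------

    @property
    def n_families(self) -> int:
        return len(self.pedigree)

    @property
    def visit_labels(self) -> list[str]:
        off = self.phenotypes[self.phenotypes["role"] == "offspring"]
        return list(pd.unique(off["visit"]))

    @property
    def trait_names(self) -> list[str]:
        return list(pd.unique(self.phenotypes["trait"]))

    def offspring_table(self, trait: str, visit: str) -> pd.DataFrame:
        """Per-family offspring records for one trait at one visit.

        Returns a frame indexed by ``family_id`` with ``value``, ``age`` and
        ``sex`` columns.
        """
        ph = self.phenotypes
        sel = ph[(ph["role"] == "offspring") & (ph["visit"] == visit) & (ph["trait"] == trait)]
        out = sel.set_index("family_id")[["value", "age", "sex"]]
        return out

    def parent_values(self, trait: str, role: str) -> pd.Series:
        """Per-family parental trait values (first record if several waves exist)."""
        if role not in ("mother", "father"):
            raise ValueError(f"role must be mother or father, got {role!r}")
        ph = self.phenotypes
        sel = ph[(ph["role"] == role) & (ph["trait"] == trait)]
        return sel.drop_duplicates("family_id").set_index("family_id")["value"]

    def parent_ages(self, role: str) -> pd.Series:
        ph = self.phenotypes
        sel = ph[ph["role"] == role]
        return sel.drop_duplicates("family_id").set_index("family_id")["age"]

    def founder_ids(self) -> list[str]:
        return list(self.pedigree["mother_id"]) + list(self.pedigree["father_id"])
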