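"""Trio genotype logic (Mendelian truth table, origin calls, HWE, QC) and the
allele-origin association models."""
import itertools
import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from triopoe.cohort import MISSING_GENOTYPE, TrioCohort
from triopoe.config import QCThresholds
from triopoe.simulate import simulate_cohort
from triopoe.trio_genetics import (
    assign_origins,
    assign_parental_origin,
    detect_mendelian_errors,
    genetic_poe_association,
    hwe_exact_test,
    qc_filter,
)

from conftest import lognormal_snp_config


# --- independent brute-force oracle over parental transmissions -------------

def possible_origins(mother_g, father_g):
    """All (maternal, paternal) transmitted minor-allele pairs a trio allows."""
    t = {0: (0,), 1: (0, 1), 2: (1,)}
    return {(a, b) for a in t[mother_g] for b in t[father_g]}


class TestMendelianTruthTable:
    def test_exhaustive_27_combinations_match_enumeration(self):
        for m, f, o in itertools.product((0, 1, 2), repeat=3):
            feasible = {a + b for a, b in possible_origins(m, f)}
            assert detect_mendelian_errors(m, f, o) == (o not in feasible), (m, f, o)

    def test_exhaustive_origin_assignment_matches_enumeration(self):
        for m, f, o in itertools.product((0, 1, 2), repeat=3):
            call = assign_parental_origin(m, f, o)
            pairs = {p for p in possible_origins(m, f) if sum(p) == o}
            if not pairs:
                assert call.status == "MENDELIAN_ERROR"
            elif len(pairs) == 1:
                ((mat, pat),) = pairs
                assert call.status == "RESOLVED"
                assert call.maternal_allele == ("B" if mat else "A")
                assert call.paternal_allele == ("B" if pat else "A")
            else:
                assert call.status == "AMBIGUOUS"
                assert (m, f, o) == (1, 1, 1)  # only the double-het trio is ambiguous

    def test_resolved_alleles_sum_to_offspring_code(self):
        for m, f, o in itertools.product((0, 1, 2), repeat=3):
            call = assign_parental_origin(m, f, o)
            if call.status == "RESOLVED":
                n_b = (call.maternal_allele == "B") + (call.paternal_allele == "B")
                assert n_b == o

    def test_missing_genotypes_cannot_be_adjudicated(self):
        assert not detect_mendelian_errors(MISSING_GENOTYPE, 0, 1)
        call = assign_parental_origin(0, MISSING_GENOTYPE, 1)
        assert call.status == "MISSING"

    @pytest.mark.parametrize("trio", [(0, 0, 1), (2, 2, 1), (0, 2, 0), (0, 2, 2)])
    def test_known_impossible_trios(self, trio):
        assert detect_mendelian_errors(*trio)

    @pytest.mark.parametrize("trio", [(0, 2, 1), (1, 1, 0), (1, 1, 2), (2, 0, 1)])
    def test_known_possible_trios(self, trio):
        assert not detect_mendelian_errors(*trio)


class TestOriginCallsOnSimulatedCohort:
    def test_resolved_calls_match_generator_truth(self, demo_cohort):
        calls = assign_origins(demo_cohort)
        truth = demo_cohort.truth.origins.set_index(["family_id", "snp_id"])
        resolved = calls[calls["status"] == "RESOLVED"].set_index(["family_id", "snp_id"])
        joined = resolved.join(truth, rsuffix="_true")
        mat = joined["maternal_allele"].map({"A": 0, "B": 1})
        pat = joined["paternal_allele"].map({"A": 0, "B": 1})
        assert (mat == joined["maternal_allele_true"]).all()
        assert (pat == joined["paternal_allele_true"]).all()

    def test_ambiguous_only_for_double_heterozygotes(self, demo_cohort):
        calls = assign_origins(demo_cohort).set_index("family_id")
        geno = demo_cohort.genotypes
        ped = demo_cohort.pedigree.set_index("family_id")
        amb = calls[calls["status"] == "AMBIGUOUS"]
        for fam, row in amb.iterrows():
            assert geno.loc[ped.loc[fam, "mother_id"], row["snp_id"]] == 1
            assert geno.loc[ped.loc[fam, "father_id"], row["snp_id"]] == 1
            assert row["offspring_genotype"] == 1

    def test_statuses_partition_all_trios(self, demo_cohort):
        calls = assign_origins(demo_cohort)
        counts = calls.groupby("snp_id").size()
        assert (counts == demo_cohort.n_families).all()


# --- HWE exact test ---------------------------------------------------------

def hwe_oracle(n_aa, n_ab, n_bb) -> float:
    """Exact-rational enumeration of the conditional heterozygote distribution."""
    n = n_aa + n_ab + n_bb
    nb = 2 * n_bb + n_ab
    rare = min(nb, 2 * n - nb)
    if rare == 0:
        return 1.0
    weights = {}
    for h in range(rare % 2, rare + 1, 2):
        hr = (rare - h) // 2
        hc = n - h - hr
        weights[h] = Fraction(
            math.factorial(n) * 2**h,
            math.factorial(h) * math.factorial(hr) * math.factorial(hc),
        )
    obs = weights[n_ab]
    return float(sum(w for w in weights.values() if w <= obs) / sum(weights.values()))


class TestHweExact:
    def test_monomorphic_is_certain(self):
        assert hwe_exact_test(25, 0, 0) == 1.0
        assert hwe_exact_test(0, 0, 40) == 1.0

    def test_total_heterozygote_deficit_is_vanishingly_unlikely(self):
        assert hwe_exact_test(50, 0, 50) < 1e-20

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            hwe_exact_test(-1, 2, 3)

    def test_matches_oracle_on_small_tables(self):
        for n in range(1, 26):
            for naa in range(n + 1):
                for nab in range(n - naa + 1):
                    nbb = n - naa - nab
                    assert hwe_exact_test(naa, nab, nbb) == pytest.approx(
                        hwe_oracle(naa, nab, nbb), abs=1e-12
                    )

    def test_matches_oracle_on_random_larger_tables(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            n = int(rng.integers(26, 201))
            naa = int(rng.integers(0, n + 1))
            nab = int(rng.integers(0, n - naa + 1))
            nbb = n - naa - nab
            assert hwe_exact_test(naa, nab, nbb) == pytest.approx(
                hwe_oracle(naa, nab, nbb), abs=1e-12
            )


# --- QC ---------------------------------------------------------------------

def _panel_cohort():
    """Hand-built founder panel of 5 SNPs where exactly 2 should survive QC.

    snp_miss: 10% missing (fails missingness); snp_rare: MAF 0.5% (fails MAF);
    snp_hwe: massive heterozygote deficit (fails HWE); snp_ok1/snp_ok2: clean.
    """
    rng = np.random.default_rng(0)
    n = 200  # founders per role
    ped = pd.DataFrame(
        {
            "family_id": [f"fam{i}" for i in range(n)],
            "mother_id": [f"m{i}" for i in range(n)],
            "father_id": [f"f{i}" for i in range(n)],
            "offspring_id": [f"o{i}" for i in range(n)],
            "offspring_sex": "F",
        }
    )
    ids = list(ped["mother_id"]) + list(ped["father_id"]) + list(ped["offspring_id"])

    def hwe_codes(maf, size):
        return (rng.random(size) < maf).astype(int) + (rng.random(size) < maf).astype(int)

    total = 3 * n
    geno = pd.DataFrame(index=pd.Index(ids, name="individual_id"))
    miss = hwe_codes(0.3, total)
    miss[: int(0.10 * total)] = MISSING_GENOTYPE
    geno["snp_miss"] = miss
    rare = np.zeros(total, dtype=int)
    rare[:4] = 1  # 4 carriers among 400 founders -> MAF 0.5%
    geno["snp_rare"] = rare
    hwe = np.concatenate([np.zeros(total // 2, dtype=int), np.full(total - total // 2, 2)])
    geno["snp_hwe"] = hwe  # only homozygotes at 50/50: gross HWE violation
    geno["snp_ok1"] = hwe_codes(0.3, total)
    geno["snp_ok2"] = hwe_codes(0.4, total)
    return geno, ped


class TestQcFilter:
    def test_constructed_panel_keeps_exactly_two(self):
        geno, ped = _panel_cohort()
        filtered, report = qc_filter(geno, ped, QCThresholds())
        assert set(filtered.columns) == {"snp_ok1", "snp_ok2"}
        rep = report.set_index("snp_id")
        assert rep.loc["snp_miss", "first_fail"] == "missingness"
        assert rep.loc["snp_rare", "first_fail"] == "maf"
        assert rep.loc["snp_hwe", "first_fail"] == "hwe"
        assert rep.loc[["snp_ok1", "snp_ok2"], "pass"].all()

    def test_vacuous_thresholds_keep_everything(self):
        geno, ped = _panel_cohort()
        filtered, _ = qc_filter(geno, ped, QCThresholds(max_missingness=1.0, min_maf=0.0, min_hwe_p=0.0))
        assert list(filtered.columns) == list(geno.columns)

    def test_empty_table_rejected(self):
        _, ped = _panel_cohort()
        with pytest.raises(ValueError, match="empty"):
            qc_filter(pd.DataFrame(), ped, QCThresholds())

    def test_maf_and_hwe_use_founders_only(self):
        geno, ped = _panel_cohort()
        # corrupt every offspring genotype; founder statistics must not move
        geno2 = geno.copy()
        off = [i for i in geno2.index if i.startswith("o")]
        geno2.loc[off, "snp_ok1"] = 2
        _, rep1 = qc_filter(geno, ped, QCThresholds())
        _, rep2 = qc_filter(geno2, ped, QCThresholds())
        r1 = rep1.set_index("snp_id").loc["snp_ok1"]
        r2 = rep2.set_index("snp_id").loc["snp_ok1"]
        assert r1["maf"] == r2["maf"] and r1["hwe_p"] == r2["hwe_p"]


# --- association models -------------------------------------------------------

class TestGeneticAssociation:
    def test_gee_equals_robust_ols_with_singleton_clusters(self, demo_cohort):
        import statsmodels.api as sm

        from triopoe.transforms import log_transform, zscore
        from triopoe.trio_genetics import _analysis_groups

        calls = assign_origins(demo_cohort)
        res = genetic_poe_association(
            demo_cohort, calls, "snp1", "trait", "6y", "poe", covariates=("age", "sex")
        )
        groups = _analysis_groups(calls[calls["snp_id"] == "snp1"], "poe")
        frame = groups.set_index("family_id").join(
            demo_cohort.offspring_table("trait", "6y"), how="inner"
        ).dropna(subset=["value"])
        y = zscore(log_transform(frame["value"].to_numpy()))
        X = np.column_stack(
            [np.ones(len(frame)), frame["indicator"], frame["age"],
             (frame["sex"] == "F").astype(float)]
        )
        ols = sm.OLS(y, X).fit(cov_type="HC0")
        assert res.estimate == pytest.approx(ols.params[1], abs=1e-8)
        assert res.se == pytest.approx(ols.bse[1], abs=1e-8)

    def test_maternal_allele_effect_recovered(self):
        coh = simulate_cohort(lognormal_snp_config(n_families=1500, effect_m=0.3, seed=21))
        calls = assign_origins(coh)
        poe = genetic_poe_association(coh, calls, "snp1", "trait", "6y", "poe",
                                      covariates=("age", "sex"))
        pat = genetic_poe_association(coh, calls, "snp1", "trait", "6y", "paternal",
                                      covariates=("age", "sex"))
        assert poe.estimate == pytest.approx(0.3, abs=0.1)
        assert abs(pat.estimate) < 2.5 * pat.se  # paternal allele carries no effect

    def test_swapping_origin_labels_negates_poe_estimate(self, demo_cohort):
        calls = assign_origins(demo_cohort)
        swapped = calls.rename(
            columns={"maternal_allele": "paternal_allele", "paternal_allele": "maternal_allele"}
        )
        a = genetic_poe_association(demo_cohort, calls, "snp1", "trait", "6y", "poe",
                                    covariates=("age", "sex"))
        b = genetic_poe_association(demo_cohort, swapped, "snp1", "trait", "6y", "poe",
                                    covariates=("age", "sex"))
        assert a.estimate == pytest.approx(-b.estimate, abs=1e-10)
        assert a.se == pytest.approx(b.se, abs=1e-10)

    def test_small_groups_produce_skip_record(self, demo_cohort):
        from triopoe.cross_sectional import SkipRecord

        calls = assign_origins(demo_cohort)
        res = genetic_poe_association(
            demo_cohort, calls, "snp1", "trait", "6y", "poe",
            covariates=("age", "sex"), min_group=10_000,
        )
        assert isinstance(res, SkipRecord)
        assert "below floor" in res.reason
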