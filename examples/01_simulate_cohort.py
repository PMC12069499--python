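"""Simulate a trio birth cohort and write it to disk.

Builds the bundled ~700-trio design (offspring followed at birth/6/12/24
years, anthropometric + cardiometabolic traits, three imprinted-SNP
analogues) and writes phenotypes.csv, trios.fam, genotypes.vcf and the
generator truth tables.
"""
from triopoe import pmns_like_config, simulate_cohort
from triopoe.io import write_cohort

config = pmns_like_config(n_families=700, seed=1)
cohort = simulate_cohort(config)
paths = write_cohort(cohort, "scratch/example_cohort")

print(f"families: {cohort.n_families}")
print(f"phenotype records: {len(cohort.phenotypes)}")
print(f"SNPs: {list(cohort.genotypes.columns)}")
for name, path in paths.items():
    print(f"wrote {name}: {path}")
# The truth CSVs record, per family and SNP, which parent transmitted the
# minor allele -- the ground truth the association models try to recover.
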