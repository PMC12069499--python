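"""Cross-sectional maternal/paternal regressions and the Wald parent-of-origin Z.

For fasting glucose the generator encodes the maternal-biased slopes seen in
the Pune trio cohorts (e.g. maternal 0.287 vs paternal 0.174 per parental SD
at 6 years), so the Z values lean positive; any single simulated cohort adds
sampling noise of about +-1 on Z.
"""
from triopoe import pmns_like_config, poe_scan, simulate_cohort

cohort = simulate_cohort(pmns_like_config(n_families=700, seed=1))
scan = poe_scan(
    cohort,
    traits=["fasting_glucose"],
    visits=["6y", "12y", "24y"],
    strata=("all",),
    transforms={"fasting_glucose": "log_z"},
)
cols = ["visit", "beta_maternal", "se_maternal", "beta_paternal", "se_paternal", "z", "p_poe"]
print(scan[cols].round(3).to_string(index=False))
# z > 0 means the mother-offspring slope exceeds the father-offspring slope
# (a maternal parent-of-origin bias); p_poe is the two-sided normal p value.
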