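"""Simulate a small multi-site cohort and inspect its phenotypes.

Builds a cohort with site-imbalanced diagnosis prevalence and an IQ gap
between typically developing (TD) and ADHD children, then prints the
site-by-diagnosis table and the group IQ means.
"""

from adhdconn import GeneratorConfig, records_to_frame, simulate_cohort
from adhdconn.phenotypes import prepare_phenotypes

config = GeneratorConfig(
    n_subjects={
        "Peking": {"TD": 60, "COMBINED": 15, "INATTENTIVE": 25},
        "NYU": {"TD": 40, "COMBINED": 30, "INATTENTIVE": 18},
        "WashU": {"TD": 30},
    },
    rng_seed=7,
)
records = simulate_cohort(config)
pheno = prepare_phenotypes(records_to_frame(records))

print("site x diagnosis counts:")
print(pheno.groupby(["site", "dx"]).size().unstack(fill_value=0))

means = pheno.groupby(pheno["dx"].eq("TD").map({True: "TD", False: "ADHD"}))[
    "iq_composite"
].mean()
print("\ncomposite IQ by group (ADHD children average ~10 points lower):")
print(means.round(1))
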