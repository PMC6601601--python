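"""Covariate-adjusted association under the five genetic models.

A synthetic cohort with a true overdominant effect (OR 2.32) is fitted
under codominant, dominant, recessive, overdominant and log-additive
encodings, each adjusted for age and BMI, with likelihood-ratio P-values
against the covariate-only null.
"""

from amplisnp import CohortConfig, DEFAULT_DESIGN, assoc_genetic_models, \
    simulate_cohort
from amplisnp.popgen import geno_codes

cohort = simulate_cohort(CohortConfig(n_case=400, n_control=400), seed=9)
snp = DEFAULT_DESIGN.snps[0]
codes = geno_codes(cohort[f"genotype_{snp.snp_id}"], snp)
y = (cohort["status"] == "case").astype(float)

results = assoc_genetic_models(codes, y, cohort[["age", "bmi"]])
print(f"{snp.snp_id}, adjusted for age + BMI (n={results['dominant'].n}):")
for model, res in results.items():
    for term, or_, lo, hi in res.levels:
        print(f"  {model:<13} {term:<10} OR {or_:.2f} [{lo:.2f}-{hi:.2f}]  "
              f"LRT P={res.lrt_p:.4f} (df={res.df})")
print("The overdominant row should recover an OR near the simulated 2.32;")
print("dominant/additive dilute it, recessive sees almost nothing.")
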