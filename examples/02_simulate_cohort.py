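"""Simulate a study-shaped case-control cohort with planted ground truth.

The generator draws 37 SNPs in Hardy-Weinberg proportions, 14 correlated
continuous risk factors with additive per-allele genetic effects, a binary
exposure, and a follow-up outcome from a liability-threshold model, then
samples exactly 102 cases and 150 controls.  The planted truth names the
indicator columns that genuinely carry outcome signal.
"""

from cohortnet import generate_cohort, nphs2_like_config

config = nphs2_like_config(seed=42)
cohort, truth = generate_cohort(config)

print(f"cohort: {cohort.n} individuals "
      f"({cohort.n_cases} cases / {cohort.n_controls} controls)")
print(f"variables: {len(cohort.variables)} "
      f"({config.n_continuous} continuous + {config.n_binary} binary + {config.n_snps} SNPs)")
print(f"hub variable: {truth.hub_variable} "
      f"(affects {int((config.effect_matrix[0] != 0).sum())} phenotypes)")
print("informative indicator columns (nonzero liability weight, extreme categories):")
for label in truth.informative_indicators:
    print("  ", label)
g = cohort.values["SNP01"]
print("SNP01 genotype class frequencies:",
      [round((g == k).mean(), 3) for k in (0, 1, 2)],
      "~ Hardy-Weinberg p^2, 2pq, q^2 at p =", round(1 - config.allele_freqs[0], 2))
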