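"""Cohort pathology summary from per-animal disease records.

Loads the bundled transgenerational F3 vinclozolin male cohort (one row
per rat, '+'/'-'/blank flags per disease), recomputes the affected /
evaluated tallies per disease, and tests a frequency contrast with
Fisher's exact test.
"""

from epimark import fisher_exact_2x2, load_f3_vinclozolin_males, summarize_cohort

records = load_f3_vinclozolin_males()
summary = summarize_cohort(records)

print(f"{'disease':<15}{'affected':>9}{'evaluated':>11}{'frequency':>11}")
for disease in summary.affected:
    print(
        f"{disease:<15}{summary.affected[disease]:>9}"
        f"{summary.evaluated[disease]:>11}{summary.frequency[disease]:>11.3f}"
    )
print(
    f"{'multiple':<15}{summary.multiple_disease_affected:>9}"
    f"{summary.multiple_disease_evaluated:>11}"
    f"{summary.multiple_disease_affected / summary.multiple_disease_evaluated:>11.3f}"
)

# Fisher's exact test: kidney disease (13/26) against a hypothetical
# unexposed cohort with 2 of 26 affected.
p = fisher_exact_2x2(13, 13, 2, 24)
print(f"\nkidney 13/26 vs control 2/26: Fisher two-sided p = {p:.5f}")
print("Each frequency is affected/evaluated; animals with blank cells were")
print("not evaluated for that tissue and are excluded from its denominator.")
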