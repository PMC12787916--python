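"""Clinical deficit scoring: one patient against the normative table.

Builds norms from a synthetic cohort, then scores a weakened patient:
z-scores, percent-of-norm, and percent deficit per direction.
"""

from stancestrength import CohortGenConfig, build_normative_table, deficit_score, generate_cohort

cohort = generate_cohort(CohortGenConfig(seed=11))
table = build_normative_table(cohort)

patient = cohort[0]  # a young man from the cohort ...
for d in patient.relative:
    patient.relative[d] *= 0.70  # ... after a 30% strength loss

report = deficit_score(patient, table)
print(f"patient {report.patient_id} ({report.sex}, {report.age_group}):")
for d, entry in report.directions.items():
    print(f"  {d:>2}: {entry['value_n_per_kg']:.2f} N/kg vs norm "
          f"{entry['norm_mean']:.2f} -> z = {entry['z']:+.2f}, "
          f"{entry['pct_of_norm']:.0f}% of norm ({entry['pct_deficit']:+.1f}%)")
# A z-score below about -2 flags a direction-specific deficit relative to
# healthy peers of the same sex and age group; pct_deficit is the same
# percent-difference formula used for the group comparisons.
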