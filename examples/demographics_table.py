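"""Descriptive "Table 1" of a target-drug report set.

Samples a synthetic report set and summarizes sex, age group and outcome
distributions the way a pharmacovigilance study reports them: counts and
percentages, with the number of reports as denominator for patient-level
variables and the number of outcome records for outcomes.
"""

from pvsignal import GeneratorConfig, sample_reports, summarize_categorical

reports = sample_reports(GeneratorConfig(n_reports=10_000, seed=7))

for variable in ("sex", "age_group", "outcome"):
    table = summarize_categorical(reports, variable)
    print(f"\n{variable}  (denominator: {table.denominator_description}, "
          f"n={table.denominator})")
    for category, count, percent in table.rows:
        print(f"  {category:<12} {count:>6}  {percent:6.2f}%")

print()
print("Percentages of report-level variables sum to 100 across categories "
      "(unknown included); outcome percentages are shares of outcome "
      "records, since one report can carry several outcomes.")
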