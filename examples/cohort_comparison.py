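"""Simulate a 13-scenario cohort and compare first responders against the team.

Generates unannounced-arrest scenarios with the default calibration
(first-responder NFR median 0.39 [0.32-0.46], team 0.25 [0.19-0.29]; time to
CPR median 29 s, defibrillator arrival 214 s, first rhythm 311 s), then
prints the cohort quality markers and the exact Mann-Whitney comparison.
"""

from noflow import GeneratorConfig, generate_cohort, scenario_metrics
from noflow.report import cohort_summary_table, phase_comparison_table

cohort = [scenario_metrics(log) for log, _ in generate_cohort(GeneratorConfig(seed=7))]

print("Cohort quality markers (n = 13), median [25th-75th percentile]:")
print(cohort_summary_table(cohort).to_string(index=False))
print()
print("First responders vs cardiac arrest team:")
df = phase_comparison_table(cohort)
print(df.drop(columns=["u_statistic", "method"]).to_string(index=False))
print()
print("A p-value below 0.05 marks a significant difference between the groups;")
print("the exact test enumerates the full null distribution of U at n1 = n2 = 13.")
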