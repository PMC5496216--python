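"""Reproduce the evaluation trial's aggregate statistics and simulate one.

First computes the two-arm summary directly from the published query-level
flag counts (arm totals inferred from counts and percentages), then runs a
full synthetic trial whose injection rates were calibrated to those flag
rates, grades every simulated query, and compares arms with Fisher's test.
"""

from meshlingua import (
    SampleSizeSpec,
    build_fixture_thesaurus,
    grade_submissions,
    sample_size_two_proportions,
    simulate_trial,
    summarize,
    summarize_counts,
    table_calibrated_scenario,
)
from meshlingua.fixtures import (
    GOLD_QUESTIONS,
    TRIAL_ARM_TOTALS,
    TRIAL_ARMS,
    TRIAL_FLAG_COUNTS,
)

# the design computation: detect 25% -> 40% perfect queries at
# alpha = 0.05 (two-sided), beta = 0.1, 12 queries per participant
n_obs, subjects = sample_size_two_proportions(SampleSizeSpec(0.25, 0.40))
print(f"sample size: {n_obs} queries per group = {subjects} participants per group")

agg = summarize_counts(TRIAL_FLAG_COUNTS, TRIAL_ARM_TOTALS, TRIAL_ARMS)
p = agg["rows"]["perfect"]
print(
    f"\nreported flag counts: perfect {p['french']['n']} ({p['french']['pct']:.1f}%) "
    f"vs {p['english']['n']} ({p['english']['pct']:.1f}%), Fisher p = {p['p']:.2g}"
)
print(f"pooled perfect rate: {agg['perfect_overall']['n']}/{agg['perfect_overall']['of']}"
      f" = {agg['perfect_overall']['pct']:.1f}%")

# a full synthetic replication: inject errors at calibrated per-arm rates,
# grade all ~492 queries, and summarize
th = build_fixture_thesaurus()
scenario = table_calibrated_scenario(th, seed=7)
subs, _ = simulate_trial(scenario, th)
summary = summarize(grade_submissions(subs, GOLD_QUESTIONS, th), arms=TRIAL_ARMS)
print(f"\nsimulated trial ({len(subs)} queries):")
print(summary.to_frame().to_string(index=False))
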