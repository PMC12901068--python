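"""Covariate-adjusted group comparison of trough durations.

Simulates a cohort whose groups differ in hidden regime-switching rate
(A stays in a covariance regime with probability 0.97 per timepoint, B 0.93)
and in covariate means, then fits

    mean trough duration ~ group + age + brain volume

and reports the group F test and estimated marginal means.
"""

from edgedyn import (
    SyntheticSpec,
    TroughCriterion,
    ancova_group_effect,
    cohort_outcome_table,
    simulate_cohort,
)

spec = SyntheticSpec(
    n_nodes=100,
    n_timepoints=1200,
    group_sizes={"A": 30, "B": 30},
    stay_prob_per_group={"A": 0.97, "B": 0.93},
    seed=0,
)
subjects, covariates = simulate_cohort(spec)
criterion = TroughCriterion(0.05, "adjacent-sample")
table = cohort_outcome_table(subjects, covariates, criterion)
fit = ancova_group_effect(table)

print(f"n = {fit.n}, F(1, {fit.df_denominator}) = {fit.f_statistic:.2f}, p = {fit.p_value:.4f}")
for g in fit.group_levels:
    mean, se = fit.adjusted_means[g]
    print(f"  group {g}: adjusted mean duration {mean:.2f} s (SE {se:.2f})")
print("\ngroup A switches regimes more slowly, so its co-fluctuation events are")
print("rarer and its trough-to-trough durations longer, after adjusting for the")
print("age and brain-volume differences built into the covariates.")
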