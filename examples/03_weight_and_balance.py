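"""Inverse probability weighting of the complete-case cohort.

Fits a logistic model of complete-case inclusion on demographics, weights
included participants by 1/propensity, and shows how the weighted cohort's
demographic composition moves back toward the full cohort (the reference).
"""

import pandas as pd

from sdoh_subtyper import coding, synthetic, weighting

cfg = synthetic.SimulationConfig(n_participants=2000, seed=7)
cohort, observed = synthetic.simulate(cfg)
binary = coding.dichotomize_responses(observed, cohort.codebook)
matrix, _ = coding.filter_complete_cases(
    coding.aggregate_factors(binary, cohort.codebook)
)

demo = cohort.demographics.copy()
demo["included"] = demo["participant_id"].isin(matrix.index)
propensities = weighting.fit_inclusion_model(demo)
weights = weighting.compute_weights(propensities.loc[matrix.index])
print(
    f"weights: n={len(weights)}, min={weights.min():.2f}, "
    f"median={weights.median():.2f}, max={weights.max():.2f}"
)

reference = weighting.reference_distribution(demo)
unit = pd.Series(1.0, index=weights.index)
before = weighting.check_balance(demo, unit, reference)
after = weighting.check_balance(demo, weights, reference)
cmp = before[["variable", "category"]].copy()
cmp["abs_diff_unweighted"] = before["abs_diff"].round(3)
cmp["abs_diff_ipw"] = after["abs_diff"].round(3)
print("\nabsolute difference from full-cohort proportions, before vs after IPW:")
print(cmp[cmp["variable"] == "race"].to_string(index=False))

weighted = weighting.apply_and_normalize(matrix, weights)
print(
    f"\nweighted factor matrix: values in [{weighted.min().min():.2f}, "
    f"{weighted.max().max():.2f}], zeros preserved -> network edge weights."
)
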