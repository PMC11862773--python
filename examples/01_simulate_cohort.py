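"""Generate a synthetic survey cohort with planted SDoH subtypes.

Builds a 2,000-participant cohort under the default study conditions: 110
questions across 4 surveys (two mandatory at enrollment, two rolled out
later), 18 subtyping factors grouped into 4 planted subtypes, demographic
strata with biased engagement in the later surveys, and rollout + item
missingness.
"""

from sdoh_subtyper import coding, synthetic

cfg = synthetic.SimulationConfig(n_participants=2000, seed=7)
cohort, observed = synthetic.simulate(cfg)

print(f"participants: {len(observed)}, questions: {observed.shape[1]}")
print(f"factors (subtyping / outcome): {len(cohort.codebook.factor_names())} / 1")

sentinel_share = observed.isin(coding.SENTINELS).to_numpy().mean()
print(f"share of cells that are invalid-response sentinels: {sentinel_share:.1%}")

by_survey = (
    (~observed.isin(coding.SENTINELS))
    .mean()
    .groupby(cohort.codebook.survey_of())
    .mean()
)
print("\nmean valid-response rate by survey (rollout missingness):")
print(by_survey.round(3).to_string())
print(
    "\nThe two enrollment surveys are answered by everyone; the two later\n"
    "surveys are attempted at the configured rollout rates scaled by each\n"
    "demographic stratum's engagement, which is what biases the complete-case\n"
    "cohort and later motivates inverse probability weighting."
)
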