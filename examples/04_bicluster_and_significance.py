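"""Discover SDoH subtypes as biclusters and test their significance.

Builds the weighted participant-factor bipartite network, maximizes Barber
bipartite modularity Q (the number of biclusters is discovered, not
prescribed), and compares Q against a permutation null that shuffles each
participant's weights across factors while preserving their weight multiset.
"""

import pandas as pd

from sdoh_subtyper import coding, significance, synthetic, weighting
from sdoh_subtyper.bipartite import build_network, maximize_modularity

cfg = synthetic.SimulationConfig(
    n_participants=2000, seed=7,
    attempt_probs={"Basics": 1.0, "OverallHealth": 1.0,
                   "HealthcareAccess": 0.9, "SDoHSurvey": 0.8},
)
cohort, observed = synthetic.simulate(cfg)
binary = coding.dichotomize_responses(observed, cohort.codebook)
matrix, _ = coding.filter_complete_cases(
    coding.aggregate_factors(binary, cohort.codebook)
)
demo = cohort.demographics.copy()
demo["included"] = demo["participant_id"].isin(matrix.index)
weights = weighting.compute_weights(
    weighting.fit_inclusion_model(demo).loc[matrix.index]
)
weighted = weighting.apply_and_normalize(matrix, weights)

network = build_network(weighted)
solution = maximize_modularity(network, n_restarts=20, seed=7)
print(f"discovered K={solution.n_clusters} biclusters, Q={solution.modularity:.3f}")

partition = solution.factor_partition()
for label, members in partition.groupby(partition):
    print(f"  bicluster {label}: {', '.join(members.index)}")

result = significance.significance_of_Q(network, B=99, n_restarts=20, seed=7)
print(
    f"\npermutation test (B={result.B}): Q={result.observed:.3f}, "
    f"random-Q={result.null_mean:.3f}, z={result.z_score:.1f}, p={result.p_value:.3g}"
)
print(
    "A Q clearly above the degree-preserving null means the factor\n"
    "co-occurrence structure is not explained by participant burden alone."
)
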