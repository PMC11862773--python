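# sdoh-subtyper

Subtyping **social determinants of health (SDoH)** from survey data by
biclustering a weighted participant–factor bipartite network.

Population surveys ask dozens of questions about nonmedical drivers of health
— income, education, food and housing security, discrimination, neighborhood
conditions, social support.  These conditions do not occur in isolation: they
co-occur in patterned combinations, and the combination (not any single
factor) is what a clinician or policymaker can act on.  This package
implements a complete analysis pipeline for discovering such **SDoH
subtypes** — subgroups of participants together with their frequently
co-occurring SDoH factors — and estimating each subtype's risk of adverse
outcomes.  Because survey data of this kind are typically controlled-access,
the package ships a first-class synthetic cohort generator with planted
subtypes, so every stage is testable and demonstrable end to end.

It is written for biostatisticians and health-services researchers working
with survey cohorts: the primary interface is the Python API (see
`examples/`), with a thin `sdoh-subtyper` CLI for running the pipeline from a
shell.

## The method

1. **Coding.** Each survey question is dichotomized so that 1 denotes the
   adverse state (reverse-polarity questions are flipped after mapping), and
   questions aggregate to binary SDoH *factors*: a participant has a factor
   if they answered any of its member questions adversely.  Participants
   with an undeterminable factor (no adverse answer, some invalid responses)
   are excluded, giving the complete-case matrix **X** ∈ {0,1}^(n×d).
2. **Weighting.** Complete-case filtering skews demographics, so a logistic
   model of inclusion yields propensities e_i and inverse-probability
   weights w_i = 1/e_i; the weighted values w_i·x_ij are min–max normalized
   within each factor, giving edge weights A_ij ∈ [0,1].
3. **Biclustering.** Participants and factors form the two node sets of a
   weighted bipartite network.  Subtypes are found by maximizing Barber's
   bipartite modularity

   Q = (1/m) Σ_{i∈P, j∈F} ( A_ij − k_i d_j / m ) · δ(g_i, g_j)

   where k_i, d_j are node strengths, m = Σ A_ij, and δ restricts to node
   pairs sharing a cluster.  The maximizer alternates closed-form label
   updates between the two sides over many restarts; the number of
   biclusters K is discovered, not prescribed.
4. **Inference.** Significance of Q is assessed against B permuted networks
   that shuffle each participant's weights across factors (preserving every
   participant's weight multiset); replication splits the cohort in half,
   clusters each, and compares the two factor partitions with the Rand
   index against the same kind of null.
5. **Integration.** Each pair of subtypes is compared by weighted logistic
   regression for each binary outcome (depression, delayed medical care,
   ER visits) and for residence in a Medicaid-nonexpansion state, adjusted
   for demographics, with Benjamini–Hochberg FDR within each outcome.
6. **Translation.** The network is drawn with a Fruchterman–Reingold layout
   plus a rigid radial "explode" step separating biclusters.

## Worked example

`examples/04_bicluster_and_significance.py` simulates a 2,000-participant
cohort (four planted subtypes, rollout missingness, biased survey
engagement), codes and weights it, and biclusters the training network:

```
discovered K=4 biclusters, Q=0.165
  bicluster 1: low_educational_attainment, low_literacy, low_income, not_employed, food_insecurity, housing_insecurity
  bicluster 2: language_barrier, no_health_care_coverage, mismatched_provider_characteristics, disadvantaged_neighborhood, disadvantaged_demographics, low_supportive_relationships
  bicluster 3: difficulty_affording_medical_care, discriminatory_experiences_everyday, discriminatory_experiences_medical, poor_provider_interactions
  bicluster 4: poor_neighborhood_cohesion, poor_relationships_with_others

permutation test (B=99): Q=0.165, random-Q=0.104, z=34.8, p=0.01
```

All four planted subtypes are recovered exactly; the observed modularity sits
far above the degree-preserving permutation null (p = 0.01 is the smallest
value attainable at B = 99), so the factor co-occurrence structure is not an
artifact of participant burden.  The other examples walk through simulation
(`01`), coding and cohort characterization (`02`), IPW balance (`03`),
replication and subtype–outcome odds ratios (`05`), and the network figure
(`06`).

The same analysis runs from a shell:

```bash
sdoh-subtyper run-all --config config.yaml     # all stages, report.json
sdoh-subtyper simulate --n 2000 --out data/    # or stage by stage
```

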