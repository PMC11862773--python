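# Methods

This note documents the models, algorithmic choices, defaults and known
limitations of the package.  It is written for a reader who wants to judge
what the pipeline computes and what passing its tests does and does not
demonstrate.

## Survey coding

Responses arrive as categorical codes per (participant, question) with three
distinct invalid-response sentinels: `NOT_ATTEMPTED` (the whole survey block
is missing — rollout missingness), `SKIP`, and `PNA` ("prefer not to
answer").  All three count as invalid downstream.

**Dichotomization** maps each question's categories through its codebook map
and then flips reverse-polarity questions, so 1 always denotes the adverse
state.  The order (map, then flip) is a fixed convention pinned by tests:
with a raw map `{always: 0, never: 1}` and reverse polarity, `always` codes
to 1.

**Aggregation** codes a factor 1 if any member question is 1.  With partial
missingness the default rule treats a positive answer as definitive: the
factor is `INVALID` only when no member is 1 and at least one member is a
sentinel.  This maximizes the retained cohort without fabricating zeros; the
strict alternative (any sentinel ⇒ `INVALID`) is available as a flag.
**Complete-case filtering** then retains exactly the participants with no
`INVALID` factor.  No imputation is offered anywhere: the dominant
missingness mode (whole survey blocks absent by rollout order) is
systematic, not random, and imputing it would manufacture data.

Characterization utilities report per-question valid counts, the counts of
participants valid-complete in each exact subset of surveys, the
distribution and lower-median of per-participant factor co-occurrences
(lower median because the data are integer-valued), and demographic
proportions to two decimals (round-half-even) with optional small-cell
suppression (counts below 20 reported as 20, percentages computed from the
reported count — the reporting rule of large national cohorts).

The outcome factor (delayed medical care, factor 19) is flagged in the
codebook and excluded from the subtyping matrix; it enters the analysis only
as an outcome.

## Inverse probability weighting

A logistic model of complete-case inclusion on demographic main effects
(age group, sex, race, ethnicity by default; configurable) gives each
participant an inclusion propensity e_i; included participants receive
weight 1/e_i.  Options: stabilized weights (scaled to mean 1), symmetric
quantile truncation (off by default — the analysis this emulates used
untruncated weights), and a saturated (fully stratified) model whose MLE is
the per-cell empirical rate.  Under the saturated model, inverse-propensity
reweighting reproduces the full-cohort demographic proportions exactly; this
algebraic identity is asserted to 1e-6 in the tests and is the calibration
anchor for the whole weighting stage.

Near-zero fitted propensities for *non-included* participants are expected
under strong selection and are not an error; a near-zero propensity for an
*included* participant indicates separation and raises, naming the
covariate pattern.  Included participants whose propensity is numerically 0
or 1 are dropped with a logged count.

The weighted matrix is w_i·x_ij, min–max normalized within each factor using
the observed column minimum (typically 0).  Zeros are preserved; an all-zero
factor column is left unchanged with a warning; an all-equal nonzero column
maps to 1.

## Bipartite biclustering

The network has participants and factors as node sets and one edge per
positive weighted cell.  Participants with all-zero rows are excluded and
reported (a zero-strength node has no place in the configuration-model
null).  Cluster quality is Barber's bipartite modularity with weighted
strengths; the null term is the bipartite configuration model k_i·d_j/m,
not the unipartite k_i·k_j/2m.  Q is invariant to uniform rescaling of all
edge weights (property-tested).

**Maximizer.** Holding factor labels fixed, Q is additive over participants
and each participant's optimal cluster has a closed form (and conversely for
factors).  The maximizer alternates these two exact half-sweeps — a
BRIM-style block ascent — so every sweep is simultaneously the "single-node
label sweep to local optimum" and is provably monotone in Q (asserted at
every iteration).  Labels live in a fixed space of d+2 slots; empty slots
act as zero-contribution singleton refuges, which is how K is discovered
rather than prescribed.  The default 20 restarts seed the factor side with
1..d initial groups (cycling; first two restarts are the all-in-one and
all-singletons partitions, the rest random).  Ties in the argmax resolve to
the lowest cluster index and final labels are renumbered 1..K by first
appearance in node order, so results are deterministic given the seed.
There is no resolution parameter.

At finalization, clusters containing only one node type (which contribute
exactly zero to Q) are folded into the neighboring cluster that maximizes
the resulting Q, so reported biclusters are genuinely mixed.  On 200 random
networks of up to 10 nodes the finalized maximizer attains the
*unconstrained* exhaustive optimum in 99% of cases and never exceeds it, so
this folding costs essentially nothing at these sizes.

**Oracle.** `brute_force_partition` enumerates every set partition of the
node set (restricted-growth strings, vectorized Q evaluation; hard limit 12
nodes) and is used purely as a testing oracle, never in the pipeline.

## Permutation inference

The null for Q shuffles each participant's weight row (including zeros)
across the d factor slots, independently per participant: network size,
every participant strength k_i and the total weight m are preserved
exactly (asserted per draw); factor strengths are not, which follows from
permuting the participant side.  Each of the B null networks is re-clustered
with the same restart budget as the observed network, so the comparison is
optimized-to-optimized and carries no optimism bias.  The empirical p uses
the "+1" rule, p = (1 + #{Q_null ≥ Q_obs}) / (1 + B), hence p ≥ 1/(B+1); z
uses the sample SD (ddof = 1) of the null.  Under row-exchangeable null
data the test is calibrated: the acceptance suite checks a rejection rate
in [0.02, 0.09] at α = 0.05 across 100 runs.

**Replication** splits participants at random (default 50/50), clusters
each half, and compares the two *factor* partitions with the Rand index
(participants differ across halves, so factor co-clustering is the only
well-defined comparison).  The null re-permutes both halves' rows and
re-clusters both, B times.  Default B = 1000 for both tests; desk-scale
runs and tests use B ∈ {49, 99}.

## Subtype–outcome associations

For each unordered subtype pair (a, b) and each outcome, a logistic
regression of the outcome on an indicator of membership in *a* is fitted on
the pooled participants of a ∪ b, adjusted for demographic main effects,
with IPW weights treated as probability weights and robust (HC0 sandwich)
standard errors — the reweighted-pseudo-population reading of IPW-weighted
regression.  OR = exp(β) with Wald 95% CIs.  Outcomes constant in the pooled
pair, or fits with unstable coefficients (|β| > 30 or SE > 10³, the
quasi-separation signature), are flagged non-estimable and excluded from the
FDR family.  Benjamini–Hochberg adjustment is applied within each outcome
(the K(K−1)/2 pairwise comparisons form one family).  With unit weights and
no covariates the OR equals the 2×2 cross-product ratio exactly; enrichment
for Medicaid-nonexpansion residence uses the identical machinery.

## Synthetic cohorts

The generator emulates the structure of a staged national survey program:

- **Questions and factors:** 110 questions in 4 surveys aggregate to 18
  subtyping factors (2–9 questions each) plus a 9-question outcome factor.
  Question templates include yes/no and 4-level frequency scales, with some
  reverse-polarity items so the coding path is exercised.
- **Planted subtypes:** each participant belongs to one of 4 latent
  subtypes; each question of a factor is answered adversely with
  probability `p_in` when the factor belongs to the participant's subtype,
  else `p_out` (defaults 0.6 / 0.1; questions within a factor are
  conditionally independent given the subtype — the simplest structure
  consistent with the any-question aggregation rule, and the documented
  extension point for intra-factor correlation).
- **Missingness:** surveys with attempt probability 1 are mandatory
  (enrollment); optional surveys (defaults 0.4 and 0.15, emulating rollout
  order) are attempted with probability scaled by the participant's
  demographic stratum engagement.  Attempted questions are independently
  replaced by `SKIP` (1%) or `PNA` (0.5%).
- **Selection bias:** five strata with population shares (0.54, 0.197,
  0.033, 0.073, 0.157) and engagement probabilities (1.0, 0.5, 0.8, 0.65,
  0.55).  Engagement gaps of about 2× produce inverse-propensity weight
  ratios near 4 in cohorts of a few thousand — strong enough that the
  unweighted complete-case cohort is visibly skewed, while keeping the
  weighted network's effective sample size usable at desk scale.  (With
  far more extreme gaps, a handful of very heavy rows dominate every factor
  column and no clustering signal survives at small n; that regime needs
  cohort sizes orders of magnitude larger.)
- **Outcomes:** three binary outcomes from logistic models with
  subtype-dependent log-odds (reference subtype 4; e.g. the depression
  contrast for subtype 1 is log 4.2) and a Medicaid-nonexpansion flag with
  per-subtype probabilities (0.30 for subtype 1, 0.25 otherwise).
- **Determinism:** one seed; per-table substreams (cluster assignment,
  responses, demographics, outcomes, missingness) keep each table
  reproducible independently of generation order.

What the generator does **not** emulate: intra-factor and inter-factor
correlation beyond subtype membership, longitudinal or repeated surveys,
outcome dependence on demographics, geographic structure, or item-level
missingness that depends on the answer.  Passing tests on these cohorts
shows the pipeline recovers structure it was designed to detect under
realistic missingness and selection; it does not certify performance on
real cohorts, whose factor prevalences and correlations are unknown.

## Problem sizes and numerical choices

Demo and test runs use cohorts of 300–10,000 participants, d = 18 factors,
B ∈ {49, 99} permutations and 20 optimizer restarts; the pipeline defaults
keep B = 1000.  The end-to-end demo configuration lightens the rollout
missingness (0.9 / 0.8) so that 2,000 simulated participants leave several
hundred complete cases — enough for every stage including the pairwise
association models.  Convergence tolerances: ascent stops when a sweep
improves Q by < 1e-12; oracle-vs-maximizer equality is judged at 1e-9;
IRLS fits run up to 200 iterations.  Degenerate inputs have defined
behavior throughout: all-zero matrices and empty split sides raise;
all-zero factor columns warn; a null distribution with zero SD reports an
infinite-z sentinel with a warning while the empirical p remains valid.

## Limitations

- Modularity maximization is heuristic; the exhaustive oracle certifies it
  only on small networks, and at realistic sizes the restart schedule is
  the only guard against local optima.
- The inclusion model's covariate set is a judgment call (main effects by
  default); misspecification propagates into the weights and everything
  downstream.  Interactions and continuous age are left to configuration.
- The Rand index between K≈4 partitions of 18 factors has a coarse,
  seed-dependent null; the permutation null (not an analytic distribution)
  is the only supported calibration.
- The exploded layout is a rigid radial displacement chosen for its
  isometry guarantee; it makes no claim of fidelity to any particular
  published layout implementation.
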