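"""Synthetic survey cohorts with planted SDoH biclusters.

Real survey data of this kind are controlled-access, so every downstream
stage is exercised on simulated cohorts that emulate the salient structure:

* ~110 questions across 4 surveys aggregating to 18 subtyping factors plus
  one outcome factor;
* planted factor biclusters: a participant belongs to one latent subtype and
  answers each question of a same-subtype factor adversely with probability
  ``p_in``, versus ``p_out`` for other subtypes' factors (questions within a
  factor are conditionally independent given the subtype);
* rollout missingness: the two enrollment surveys are always attempted while
  the two later surveys are attempted with configurable probabilities, scaled
  per demographic stratum to create selection bias into complete-case status;
* item nonresponse: attempted questions are independently replaced by SKIP or
  PNA sentinels;
* three binary outcomes plus a Medicaid-nonexpansion residence flag drawn
  from logistic models with subtype-dependent log-odds.

All randomness flows from a single seed; per-table substreams keep each table
reproducible independently of generation order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .coding import (
    NOT_ATTEMPTED,
    PNA,
    SKIP,
    QuestionCodebook,
    responses_to_long,
)

__all__ = [
    "SimulationConfig",
    "SyntheticCohort",
    "ConfigError",
    "default_codebook",
    "generate_cohort",
    "inject_missingness",
    "simulate",
    "write_cohort",
]


class ConfigError(ValueError):
    """Invalid simulation configuration; the message names the field."""


# The 18 subtyping factors with their planted subtype, survey and HP-30
# domain, in the grouping the demo output is meant to resemble.
_FACTOR_SPEC = [
    # (factor_name, cluster, survey, hp30_domain)
    ("low_educational_attainment", 1, "Basics", "education_access_quality"),
    ("low_literacy", 1, "OverallHealth", "education_access_quality"),
    ("low_income", 1, "Basics", "economic_stability"),
    ("not_employed", 1, "Basics", "economic_stability"),
    ("food_insecurity", 1, "SDoHSurvey", "economic_stability"),
    ("housing_insecurity", 1, "Basics", "economic_stability"),
    ("difficulty_affording_medical_care", 2, "HealthcareAccess", "health_care_access_quality"),
    ("discriminatory_experiences_everyday", 2, "SDoHSurvey", "social_community_context"),
    ("discriminatory_experiences_medical", 2, "SDoHSurvey", "health_care_access_quality"),
    ("poor_provider_interactions", 2, "HealthcareAccess", "health_care_access_quality"),
    ("poor_neighborhood_cohesion", 3, "SDoHSurvey", "neighborhood_built_environment"),
    ("poor_relationships_with_others", 3, "SDoHSurvey", "social_community_context"),
    ("language_barrier", 4, "Basics", "health_care_access_quality"),
    ("no_health_care_coverage", 4, "HealthcareAccess", "health_care_access_quality"),
    ("mismatched_provider_characteristics", 4, "HealthcareAccess", "health_care_access_quality"),
    ("disadvantaged_neighborhood", 4, "SDoHSurvey", "neighborhood_built_environment"),
    ("disadvantaged_demographics", 4, "Basics", "social_community_context"),
    ("low_supportive_relationships", 4, "SDoHSurvey", "social_community_context"),
]
#: question counts per factor (2-9 each); totals 101 + 9 outcome questions = 110
_DEFAULT_QUESTION_COUNTS = [2, 3, 4, 5, 6, 7, 8, 9, 2, 3, 4, 5, 6, 7, 8, 9, 6, 7]

_OUTCOME_FACTOR = ("delayed_medical_care", "HealthcareAccess", "health_care_access_quality", 9)

# three question templates; the reverse template exercises the
# map-then-flip dichotomization convention
_TEMPLATES = [
    {"polarity": "direct", "map": {"yes": 1, "no": 0}},
    {"polarity": "direct", "map": {"always": 1, "often": 1, "sometimes": 0, "never": 0}},
    {"polarity": "reverse", "map": {"always": 1, "often": 1, "sometimes": 0, "never": 0}},
]

DEFAULT_STRATA = [
    # (label, population probability, follow-up survey engagement probability);
    # engagement gaps up to 2x yield inverse-propensity weight ratios of ~4 at
    # cohort sizes in the low thousands — strong enough selection to need
    # correcting, without concentrating the network's weight in a few rows
    ("white", 0.540, 1.00),
    ("black", 0.197, 0.50),
    ("asian", 0.033, 0.80),
    ("other_or_multiple", 0.073, 0.65),
    ("none_indicated", 0.157, 0.55),
]

DEFAULT_OUTCOME_LOGODDS = {
    # per-subtype log-odds shifts relative to subtype 4 (reference); the
    # depression contrast 1-vs-4 is log(4.2) = 1.435
    "depression": {"intercept": -2.2, "effects": {1: 1.435, 2: 0.833, 3: 1.065, 4: 0.0}},
    "delayed_care": {"intercept": -2.0, "effects": {1: 1.253, 2: 1.459, 3: 1.281, 4: 0.0}},
    "er_visit": {"intercept": -2.5, "effects": {1: 0.588, 2: 0.262, 3: 0.336, 4: 0.0}},
}

DEFAULT_MEDICAID_NONEXPANSION_PROB = {1: 0.30, 2: 0.25, 3: 0.25, 4: 0.25}

DEFAULT_ATTEMPT_PROBS = {
    "Basics": 1.0,
    "OverallHealth": 1.0,
    "HealthcareAccess": 0.4,
    "SDoHSurvey": 0.15,
}


def default_codebook(question_counts=None) -> QuestionCodebook:
    """The default fixture codebook: 18 factors + 1 outcome factor, 110 questions."""
    counts = list(question_counts) if question_counts is not None else _DEFAULT_QUESTION_COUNTS
    if len(counts) != len(_FACTOR_SPEC):
        raise ConfigError("n_questions_per_factor: need one count per factor")
    rows = []
    q = 0
    for (fname, _cluster, survey, domain), cnt in zip(_FACTOR_SPEC, counts):
        if cnt < 1:
            raise ConfigError(f"n_questions_per_factor[{fname}] must be >= 1")
        fid = len({r["factor_id"] for r in rows}) + 1
        for i in range(cnt):
            tpl = _TEMPLATES[q % len(_TEMPLATES)]
            rows.append(
                {
                    "question_id": f"Q{q + 1:03d}",
                    "survey": survey,
                    "hp30_domain": domain,
                    "factor_id": fid,
                    "factor_name": fname,
                    "polarity": tpl["polarity"],
                    "is_outcome": False,
                    "dichotomization": dict(tpl["map"]),
                }
            )
            q += 1
    oname, osurvey, odomain, ocnt = _OUTCOME_FACTOR
    ofid = len(_FACTOR_SPEC) + 1
    for i in range(ocnt):
        tpl = _TEMPLATES[q % len(_TEMPLATES)]
        rows.append(
            {
                "question_id": f"Q{q + 1:03d}",
                "survey": osurvey,
                "hp30_domain": odomain,
                "factor_id": ofid,
                "factor_name": oname,
                "polarity": tpl["polarity"],
                "is_outcome": True,
                "dichotomization": dict(tpl["map"]),
            }
        )
        q += 1
    return QuestionCodebook(pd.DataFrame(rows))


def default_factor_to_cluster() -> dict:
    return {fname: cluster for fname, cluster, _s, _d in _FACTOR_SPEC}


@dataclass
class SimulationConfig:
    """Study conditions for a synthetic cohort.

    Defaults emulate a survey program with two always-attempted enrollment
    surveys, two later surveys with rollout missingness, demographic strata
    with biased engagement in the later surveys, four planted subtypes of
    factors, and subtype-dependent outcome risks.
    """

    n_participants: int = 2000
    n_clusters: int = 4
    factor_to_cluster: dict = field(default_factory=default_factor_to_cluster)
    p_in: float = 0.6
    p_out: float = 0.1
    demographic_strata: list = field(default_factory=lambda: list(DEFAULT_STRATA))
    outcome_logodds: dict = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_OUTCOME_LOGODDS.items()}
    )
    medicaid_nonexpansion_prob: dict = field(
        default_factory=lambda: dict(DEFAULT_MEDICAID_NONEXPANSION_PROB)
    )
    attempt_probs: dict = field(default_factory=lambda: dict(DEFAULT_ATTEMPT_PROBS))
    skip_prob: float = 0.01
    pna_prob: float = 0.005
    question_counts: list | None = None
    seed: int = 0

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if self.n_participants < 1:
            raise ConfigError("n_participants must be >= 1")
        for name, p in (("p_in", self.p_in), ("p_out", self.p_out),
                        ("skip_prob", self.skip_prob), ("pna_prob", self.pna_prob)):
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {p}")
        clusters = set(self.factor_to_cluster.values())
        if clusters != set(range(1, self.n_clusters + 1)):
            raise ConfigError(
                "factor_to_cluster must be surjective onto 1..n_clusters; "
                f"found clusters {sorted(clusters)}"
            )
        total = sum(p for _l, p, _i in self.demographic_strata)
        if not np.isclose(total, 1.0, atol=1e-6):
            raise ConfigError(f"demographic_strata population probabilities sum to {total}, not 1")
        for label, pop, incl in self.demographic_strata:
            if not (0 <= pop <= 1 and 0 <= incl <= 1):
                raise ConfigError(f"demographic_strata[{label}] probabilities must be in [0, 1]")
        for survey, p in self.attempt_probs.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"attempt_probs[{survey}] must be in [0, 1], got {p}")
        for c, p in self.medicaid_nonexpansion_prob.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"medicaid_nonexpansion_prob[{c}] must be in [0, 1]")
        for outcome, spec in self.outcome_logodds.items():
            if set(spec["effects"]) != set(range(1, self.n_clusters + 1)):
                raise ConfigError(f"outcome_logodds[{outcome}] must give an effect per cluster")

    def codebook(self) -> QuestionCodebook:
        cb = default_codebook(self.question_counts)
        known = set(cb.factor_names())
        extra = set(self.factor_to_cluster) - known
        if extra:
            raise ConfigError(f"factor_to_cluster references unknown factors {sorted(extra)}")
        if known - set(self.factor_to_cluster):
            raise ConfigError("factor_to_cluster must cover every subtyping factor")
        return cb


@dataclass
class SyntheticCohort:
    """A generated cohort with ground truth attached.

    ``responses`` holds the complete (pre-missingness) categorical answers;
    apply :func:`inject_missingness` to obtain the observed survey surface.
    """

    responses: pd.DataFrame
    demographics: pd.DataFrame
    outcomes: pd.DataFrame
    true_cluster: pd.Series
    true_factor_cluster: pd.Series
    codebook: QuestionCodebook
    config: SimulationConfig


def _substreams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def generate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Generate a complete synthetic cohort (responses, demographics, outcomes).

    Participant ``i`` of subtype ``c`` answers each question of factor ``f``
    adversely with probability ``p_in`` when ``factor_to_cluster[f] == c``,
    else ``p_out``.  Demographics are drawn from the configured strata and
    outcomes from the configured logistic models.  Identical seeds give
    identical cohorts.
    """
    config.validate()
    cb = config.codebook()
    rng_cluster, rng_resp, rng_demo, rng_out = _substreams(config.seed, 4)
    n = config.n_participants
    pids = pd.Index([f"P{i + 1:06d}" for i in range(n)], name="participant_id")

    true_cluster = pd.Series(
        rng_cluster.integers(1, config.n_clusters + 1, size=n), index=pids, name="cluster"
    )

    # adverse indicator per question, then a category consistent with it
    meta = cb.table
    resp = {}
    for _, qrow in meta.iterrows():
        fname = qrow["factor_name"]
        if qrow["is_outcome"]:
            p = np.full(n, config.p_out)  # outcome-factor questions carry no subtype signal
        else:
            own = true_cluster.to_numpy() == config.factor_to_cluster[fname]
            p = np.where(own, config.p_in, config.p_out)
        adverse = rng_resp.random(n) < p
        dmap = dict(qrow["dichotomization"])
        if qrow["polarity"] == "reverse":
            dmap = {cat: 1 - v for cat, v in dmap.items()}
        ones = sorted(cat for cat, v in dmap.items() if v == 1)
        zeros = sorted(cat for cat, v in dmap.items() if v == 0)
        pick_one = rng_resp.integers(0, len(ones), size=n)
        pick_zero = rng_resp.integers(0, len(zeros), size=n)
        values = np.where(
            adverse,
            np.array(ones, dtype=object)[pick_one],
            np.array(zeros, dtype=object)[pick_zero],
        )
        resp[qrow["question_id"]] = values
    responses = pd.DataFrame(resp, index=pids)

    labels = [s[0] for s in config.demographic_strata]
    probs = np.array([s[1] for s in config.demographic_strata], dtype=float)
    probs = probs / probs.sum()
    stratum = rng_demo.choice(len(labels), size=n, p=probs)
    demographics = pd.DataFrame(
        {
            "participant_id": pids,
            "age_group": rng_demo.choice(
                ["18-39", "40-59", "60-79", "80+"], size=n, p=[0.25, 0.35, 0.33, 0.07]
            ),
            "sex": rng_demo.choice(["female", "male", "other"], size=n, p=[0.6, 0.37, 0.03]),
            "race": np.array(labels, dtype=object)[stratum],
            "ethnicity": rng_demo.choice(
                ["not_hispanic", "hispanic", "additional_options"], size=n, p=[0.77, 0.18, 0.05]
            ),
        }
    ).reset_index(drop=True)

    out = {"participant_id": pids}
    cl = true_cluster.to_numpy()
    for outcome, spec in config.outcome_logodds.items():
        effects = np.array([spec["effects"][c] for c in cl])
        logit = spec["intercept"] + effects
        p = 1.0 / (1.0 + np.exp(-logit))
        out[outcome] = (rng_out.random(n) < p).astype(int)
    p_med = np.array([config.medicaid_nonexpansion_prob[c] for c in cl])
    out["no_medicaid_expansion"] = (rng_out.random(n) < p_med).astype(int)
    outcomes = pd.DataFrame(out).reset_index(drop=True)

    true_factor_cluster = pd.Series(config.factor_to_cluster, name="cluster")
    return SyntheticCohort(
        responses=responses,
        demographics=demographics,
        outcomes=outcomes,
        true_cluster=true_cluster,
        true_factor_cluster=true_factor_cluster,
        codebook=cb,
        config=config,
    )


def inject_missingness(
    cohort: SyntheticCohort, config: SimulationConfig | None = None
) -> pd.DataFrame:
    """Overlay rollout and item missingness on a cohort's complete responses.

    Each participant attempts each survey block with the configured
    probability.  A survey with attempt probability 1 is mandatory (attempted
    by everyone); for the optional (later-rollout) surveys the probability is
    multiplied by the participant's stratum engagement probability, which is
    what creates demographic selection into complete-case status.
    Unattempted blocks become NOT_ATTEMPTED wholesale; attempted questions are
    independently replaced by SKIP or PNA.  Returns a new table; the input
    cohort is unchanged.
    """
    config = config or cohort.config
    cb = cohort.codebook
    survey_of = cb.survey_of()
    unknown = set(config.attempt_probs) - set(survey_of.unique())
    if unknown:
        raise ConfigError(f"attempt_probs names unknown survey(s): {sorted(unknown)}")
    missing_surveys = set(survey_of.unique()) - set(config.attempt_probs)
    if missing_surveys:
        raise ConfigError(f"attempt_probs missing survey(s): {sorted(missing_surveys)}")

    (rng,) = _substreams(config.seed, 5)[4:]
    n = len(cohort.responses)
    engagement = dict(
        (label, incl) for label, _pop, incl in config.demographic_strata
    )
    strat_engage = (
        cohort.demographics.set_index("participant_id")["race"].map(engagement).to_numpy()
    )

    out = cohort.responses.copy()
    surveys_in_order = [s for s in survey_of.unique()]
    for survey in surveys_in_order:
        base = config.attempt_probs[survey]
        p_attempt = (
            np.full(n, base)
            if base >= 1.0
            else np.clip(base * strat_engage, 0.0, 1.0)
        )
        attempted = rng.random(n) < p_attempt
        qs = [q for q in out.columns if survey_of.get(q) == survey]
        block = out[qs].to_numpy(dtype=object)
        block[~attempted, :] = NOT_ATTEMPTED
        u = rng.random(block.shape)
        skip_mask = attempted[:, None] & (u < config.skip_prob)
        pna_mask = attempted[:, None] & (u >= config.skip_prob) & (
            u < config.skip_prob + config.pna_prob
        )
        block[skip_mask] = SKIP
        block[pna_mask] = PNA
        out[qs] = block
    return out


def simulate(config: SimulationConfig) -> tuple[SyntheticCohort, pd.DataFrame]:
    """Generate a cohort and its observed (missingness-injected) responses."""
    cohort = generate_cohort(config)
    observed = inject_missingness(cohort, config)
    return cohort, observed


def write_cohort(cohort: SyntheticCohort, observed: pd.DataFrame, out_dir) -> None:
    """Write responses.csv (long), demographics.csv, outcomes.csv, codebook.csv, truth.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    responses_to_long(observed).to_csv(out / "responses.csv", index=False)
    cohort.demographics.to_csv(out / "demographics.csv", index=False)
    cohort.outcomes.to_csv(out / "outcomes.csv", index=False)
    cohort.codebook.to_csv(out / "codebook.csv")
    truth = {
        "true_cluster": {k: int(v) for k, v in cohort.true_cluster.items()},
        "true_factor_cluster": {k: int(v) for k, v in cohort.true_factor_cluster.items()},
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=2))
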