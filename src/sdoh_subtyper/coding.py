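"""Survey response coding: dichotomization, factor aggregation, characterization.

Raw survey answers arrive as categorical codes per (participant, question)
plus three invalid-response sentinels: ``NOT_ATTEMPTED`` (the survey block was
never offered or attempted — rollout missingness), ``SKIP`` and ``PNA``
("prefer not to answer").  Coding proceeds in three steps:

1. *Dichotomize*: each question's categories map to {0, 1} with 1 denoting the
   adverse state; reverse-polarity questions are flipped after mapping.
2. *Aggregate*: a participant scores 1 on an SDoH factor if they answered any
   member question with a 1; all-valid zeros give 0; otherwise the factor is
   INVALID for that participant.
3. *Complete cases*: participants with any INVALID factor are dropped, giving
   the binary participant x factor matrix used for subtyping.

The module also reproduces the cohort characterization summaries: per-question
valid-response counts, survey-completion overlap, co-occurrence distributions,
and demographic comparisons with small-cell suppression.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

NOT_ATTEMPTED = "NOT_ATTEMPTED"
SKIP = "SKIP"
PNA = "PNA"
SENTINELS = frozenset({NOT_ATTEMPTED, SKIP, PNA})
INVALID = "INVALID"

SURVEYS = ("Basics", "OverallHealth", "HealthcareAccess", "SDoHSurvey")
#: surveys completed at enrollment (attempted by everyone); the other two were
#: rolled out later and drive the block missingness
ENROLLMENT_SURVEYS = frozenset({"Basics", "OverallHealth"})

HP30_DOMAINS = (
    "economic_stability",
    "education_access_quality",
    "health_care_access_quality",
    "neighborhood_built_environment",
    "social_community_context",
)


class CodingError(ValueError):
    """A response value or codebook entry that cannot be coded."""


@dataclass
class QuestionCodebook:
    """Question-level coding metadata.

    ``table`` has one row per question with columns ``question_id``,
    ``survey``, ``hp30_domain``, ``factor_id``, ``factor_name``, ``polarity``
    (direct/reverse), ``is_outcome`` (the factor is used as an outcome, not a
    subtyping factor) and a ``dichotomization`` dict mapping every non-sentinel
    category to 0/1 on the question's raw scale.
    """

    table: pd.DataFrame

    def __post_init__(self):
        required = {
            "question_id",
            "survey",
            "hp30_domain",
            "factor_id",
            "factor_name",
            "polarity",
            "is_outcome",
            "dichotomization",
        }
        missing = required - set(self.table.columns)
        if missing:
            raise CodingError(f"codebook missing columns: {sorted(missing)}")
        if self.table["question_id"].duplicated().any():
            raise CodingError("duplicate question_id in codebook")
        bad_survey = set(self.table["survey"]) - set(SURVEYS)
        if bad_survey:
            raise CodingError(f"unknown survey tag(s): {sorted(bad_survey)}")
        bad_domain = set(self.table["hp30_domain"]) - set(HP30_DOMAINS)
        if bad_domain:
            raise CodingError(f"unknown HP-30 domain(s): {sorted(bad_domain)}")
        # one factor, one domain per question is structural: each question is
        # a single codebook row, so only per-factor consistency needs a check
        per_factor = self.table.groupby("factor_id")["factor_name"].nunique()
        if (per_factor > 1).any():
            raise CodingError("factor_id maps to more than one factor_name")

    @property
    def question_ids(self) -> list:
        return list(self.table["question_id"])

    def factor_names(self, include_outcome: bool = False) -> list:
        t = self.table if include_outcome else self.table[~self.table["is_outcome"]]
        return list(t.drop_duplicates("factor_id").sort_values("factor_id")["factor_name"])

    def questions_for_factor(self, factor_name: str) -> list:
        qs = self.table.loc[self.table["factor_name"] == factor_name, "question_id"]
        if qs.empty:
            raise CodingError(f"factor {factor_name!r} has zero member questions")
        return list(qs)

    def sdoh_question_ids(self) -> list:
        """Questions belonging to non-outcome factors."""
        return list(self.table.loc[~self.table["is_outcome"], "question_id"])

    def survey_of(self) -> pd.Series:
        return self.table.set_index("question_id")["survey"]

    def to_csv(self, path) -> None:
        t = self.table.copy()
        t["dichotomization"] = t["dichotomization"].map(json.dumps)
        t.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "QuestionCodebook":
        t = pd.read_csv(path)
        t["dichotomization"] = t["dichotomization"].map(json.loads)
        t["is_outcome"] = t["is_outcome"].astype(bool)
        return cls(t)


def dichotomize_responses(
    responses: pd.DataFrame, codebook: QuestionCodebook
) -> pd.DataFrame:
    """Map raw categorical responses to {0, 1}, preserving sentinels.

    The dichotomization map is applied on the question's raw scale, then
    reverse-polarity questions are flipped, so 1 always denotes the adverse
    state.  ``responses`` is wide (participants x questions).

    Raises
    ------
    CodingError
        If a non-sentinel category is absent from the question's map.
    """
    out = {}
    meta = codebook.table.set_index("question_id")
    for qid in responses.columns:
        if qid not in meta.index:
            raise CodingError(f"question {qid!r} not in codebook")
        dmap = dict(meta.at[qid, "dichotomization"])
        if meta.at[qid, "polarity"] == "reverse":
            dmap = {cat: 1 - v for cat, v in dmap.items()}
        col = responses[qid]
        observed = set(col.unique()) - SENTINELS
        unmapped = observed - set(dmap)
        if unmapped:
            raise CodingError(
                f"question {qid!r}: unmapped categor{'y' if len(unmapped)==1 else 'ies'} "
                f"{sorted(map(str, unmapped))}"
            )
        full_map = {**dmap, **{s: s for s in SENTINELS}}
        out[qid] = col.map(full_map)
    return pd.DataFrame(out, index=responses.index)


def aggregate_factors(
    binary_questions: pd.DataFrame,
    codebook: QuestionCodebook,
    include_outcome: bool = False,
    strict: bool = False,
) -> pd.DataFrame:
    """Roll dichotomized questions up to participant x factor values.

    A factor is 1 if any member question is 1 (a positive answer is
    definitive, even when other members are missing), 0 if every member is a
    valid 0, and INVALID when no member is 1 but at least one is a sentinel.
    With ``strict``, any sentinel member makes the factor INVALID regardless
    of positive answers.
    """
    result = {}
    for fname in codebook.factor_names(include_outcome=include_outcome):
        members = [
            q for q in codebook.questions_for_factor(fname) if q in binary_questions.columns
        ]
        if not members:
            raise CodingError(f"factor {fname!r} has zero member questions in the data")
        sub = binary_questions[members]
        any_one = (sub == 1).any(axis=1).to_numpy()
        any_sent = sub.isin(SENTINELS).any(axis=1).to_numpy()
        vals = np.zeros(len(sub), dtype=object)
        vals[any_one] = 1
        if strict:
            vals[any_sent] = INVALID
        else:
            vals[any_sent & ~any_one] = INVALID
        result[fname] = vals
    out = pd.DataFrame(result, index=binary_questions.index)
    return out[codebook.factor_names(include_outcome=include_outcome)]


def filter_complete_cases(factor_table: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Retain participants with no INVALID factor.

    Returns the binary factor matrix (int dtype, no missing cells) and an
    exclusion report: per-participant first cause of exclusion and the
    retained fraction.

    Raises
    ------
    ValueError
        If no participant survives; typically a sign that the missingness
        settings are too aggressive for the cohort size.
    """
    invalid = factor_table == INVALID
    keep = ~invalid.any(axis=1)
    matrix = factor_table.loc[keep].astype(int)
    excluded = invalid.loc[~keep]
    first_cause = excluded.apply(lambda row: row.index[row.to_numpy()][0], axis=1)
    report = {
        "n_input": int(len(factor_table)),
        "n_retained": int(keep.sum()),
        "retained_fraction": float(keep.mean()) if len(factor_table) else 0.0,
        "first_cause_of_exclusion": first_cause.to_dict(),
    }
    if matrix.empty:
        raise ValueError(
            "no participants retained after complete-case filtering; "
            "consider relaxing missingness or using strict=False aggregation"
        )
    assert not matrix.isin([INVALID]).any().any()
    return matrix, report


def summarize_validity(
    responses: pd.DataFrame, codebook: QuestionCodebook
) -> pd.DataFrame:
    """Per-question valid (non-sentinel) response counts with survey/domain tags."""
    meta = codebook.table.set_index("question_id")
    is_sent = responses.isin(SENTINELS)
    n_valid = (~is_sent).sum(axis=0)
    rows = []
    for qid in responses.columns:
        rows.append(
            {
                "question_id": qid,
                "survey": meta.at[qid, "survey"],
                "hp30_domain": meta.at[qid, "hp30_domain"],
                "n_valid": int(n_valid[qid]),
                "n_sentinel": int(len(responses) - n_valid[qid]),
            }
        )
    out = pd.DataFrame(rows)
    return out.sort_values(["survey", "n_valid"], ascending=[True, False]).reset_index(
        drop=True
    )


def survey_overlap(responses: pd.DataFrame, codebook: QuestionCodebook) -> dict:
    """Counts of participants valid-complete in exactly each survey subset.

    A participant is valid-complete in a survey when every SDoH (non-outcome)
    question of that survey has a non-sentinel response.  Keys are
    '+'-joined survey names in rollout order; participants complete in no
    survey are not counted.
    """
    valid = ~responses.isin(SENTINELS)
    survey_of = codebook.survey_of()
    complete = {}
    for s in SURVEYS:
        qs = [
            q
            for q in codebook.sdoh_question_ids()
            if survey_of.get(q) == s and q in responses.columns
        ]
        if qs:
            complete[s] = valid[qs].all(axis=1)
    if not complete:
        return {}
    comp = pd.DataFrame(complete)
    keys = comp.apply(lambda row: "+".join(s for s in SURVEYS if row.get(s, False)), axis=1)
    counts = keys[keys != ""].value_counts().to_dict()
    return {k: int(v) for k, v in counts.items()}


def cooccurrence_distribution(matrix: pd.DataFrame) -> tuple[pd.Series, int]:
    """Histogram and median of per-participant row sums (co-occurrence counts).

    The median uses the lower-median convention for even counts, matching
    integer-valued reporting.
    """
    sums = matrix.to_numpy().sum(axis=1).astype(int)
    d = matrix.shape[1]
    hist = pd.Series(np.bincount(sums, minlength=d + 1), index=range(d + 1), name="count")
    median = int(np.sort(sums)[(len(sums) - 1) // 2])
    return hist, median


def format_percent(count: float, total: float) -> float:
    """Percentage to 2 decimal places, round-half-even."""
    return round(100.0 * count / total, 2)


def cohort_proportions(
    demographics: pd.DataFrame,
    subset_ids,
    variables=("age_group", "sex", "race", "ethnicity"),
    suppress: bool = False,
    suppression_threshold: int = 20,
) -> pd.DataFrame:
    """Per-category counts and percentages for a subset and its complement.

    Percentages are of the subset (or complement) size, to 2 decimals.  With
    ``suppress``, counts below the threshold are reported as the threshold
    (and flagged), mimicking small-cell reporting rules; percentages are
    computed from the reported counts.
    """
    ids = pd.Index(subset_ids)
    all_ids = pd.Index(demographics["participant_id"])
    if not ids.isin(all_ids).all():
        missing = ids[~ids.isin(all_ids)]
        raise ValueError(f"subset ids not in demographics: {list(missing[:5])}")
    demo = demographics.set_index("participant_id")
    in_subset = demo.index.isin(ids)
    rows = []
    for var in variables:
        for cat in sorted(demo[var].astype(str).unique()):
            cat_mask = demo[var].astype(str) == cat
            for side, mask in (("subset", in_subset), ("complement", ~in_subset)):
                n_side = int(mask.sum())
                count = int((cat_mask & mask).sum())
                suppressed = False
                if suppress and 0 < count < suppression_threshold:
                    count = suppression_threshold
                    suppressed = True
                rows.append(
                    {
                        "variable": var,
                        "category": cat,
                        "side": side,
                        "count": count,
                        "percent": format_percent(count, n_side) if n_side else 0.0,
                        "suppressed": suppressed,
                    }
                )
    return pd.DataFrame(rows)


def responses_to_long(responses: pd.DataFrame) -> pd.DataFrame:
    """Wide participant x question table -> long (participant_id, question_id, value)."""
    long = responses.stack().rename("value").reset_index()
    long.columns = ["participant_id", "question_id", "value"]
    return long


def responses_from_long(long: pd.DataFrame) -> pd.DataFrame:
    """Long response records -> wide participant x question table."""
    if long.duplicated(["participant_id", "question_id"]).any():
        raise CodingError("multiple values for the same (participant, question) pair")
    return long.pivot(index="participant_id", columns="question_id", values="value")
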