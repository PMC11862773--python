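"""Dichotomization, factor aggregation, complete-case filtering, summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sdoh_subtyper import coding
from sdoh_subtyper.coding import (
    INVALID,
    NOT_ATTEMPTED,
    PNA,
    SKIP,
    CodingError,
    QuestionCodebook,
)


def make_codebook(entries):
    """entries: list of (qid, survey, factor_name, polarity, dmap, is_outcome)."""
    fids = {}
    rows = []
    for qid, survey, fname, polarity, dmap, is_outcome in entries:
        fid = fids.setdefault(fname, len(fids) + 1)
        rows.append(
            {
                "question_id": qid,
                "survey": survey,
                "hp30_domain": "economic_stability",
                "factor_id": fid,
                "factor_name": fname,
                "polarity": polarity,
                "is_outcome": is_outcome,
                "dichotomization": dmap,
            }
        )
    return QuestionCodebook(pd.DataFrame(rows))


FREQ = {"always": 1, "often": 1, "sometimes": 0, "never": 0}


class TestDichotomize:
    def test_adverse_category_maps_to_one(self):
        cb = make_codebook([("q1", "Basics", "income", "direct", {"often": 1, "sometimes": 0}, False)])
        resp = pd.DataFrame({"q1": ["often", "sometimes"]}, index=["a", "b"])
        out = coding.dichotomize_responses(resp, cb)
        assert list(out["q1"]) == [1, 0]

    @pytest.mark.parametrize("sentinel", [SKIP, PNA, NOT_ATTEMPTED])
    def test_sentinels_pass_through(self, sentinel):
        cb = make_codebook([("q1", "Basics", "income", "direct", {"yes": 1, "no": 0}, False)])
        resp = pd.DataFrame({"q1": [sentinel, "yes"]}, index=["a", "b"])
        out = coding.dichotomize_responses(resp, cb)
        assert out["q1"]["a"] == sentinel
        assert out["q1"]["b"] == 1

    def test_reverse_polarity_applies_map_then_flip(self):
        # convention fixed by enumerating both orderings: with raw map
        # {always:0, never:1} and reverse polarity, "always" -> 0 -> flip -> 1;
        # the flip-then-map ordering would give 1 - undefined lookup, so the
        # map-then-flip order is the only coherent reading and is pinned here
        cb = make_codebook([("q1", "Basics", "income", "reverse", {"always": 0, "never": 1}, False)])
        resp = pd.DataFrame({"q1": ["always", "never"]}, index=["a", "b"])
        out = coding.dichotomize_responses(resp, cb)
        assert list(out["q1"]) == [1, 0]

    def test_unmapped_category_names_question_and_category(self):
        cb = make_codebook([("q7", "Basics", "income", "direct", {"yes": 1, "no": 0}, False)])
        resp = pd.DataFrame({"q7": ["maybe"]}, index=["a"])
        with pytest.raises(CodingError, match=r"q7.*maybe"):
            coding.dichotomize_responses(resp, cb)


class TestAggregateFactors:
    def _cb2(self):
        return make_codebook(
            [
                ("q1", "Basics", "f", "direct", {"y": 1, "n": 0}, False),
                ("q2", "Basics", "f", "direct", {"y": 1, "n": 0}, False),
            ]
        )

    def test_truth_table_over_two_member_questions(self):
        """Oracle: enumerate {0,1,SKIP}^2 and apply the aggregation rules."""
        cb = self._cb2()
        states = [0, 1, SKIP]
        combos = [(a, b) for a in states for b in states]
        binary = pd.DataFrame(combos, columns=["q1", "q2"], index=range(len(combos)))

        def oracle(a, b, strict):
            cells = (a, b)
            any_one = 1 in cells
            any_sent = SKIP in cells
            if strict:
                return INVALID if any_sent else (1 if any_one else 0)
            return 1 if any_one else (INVALID if any_sent else 0)

        for strict in (False, True):
            got = coding.aggregate_factors(binary, cb, strict=strict)["f"]
            expected = [oracle(a, b, strict) for a, b in combos]
            assert list(got) == expected

    def test_any_positive_answer_is_definitive(self):
        cb = make_codebook(
            [(f"q{i}", "Basics", "f", "direct", {"y": 1, "n": 0}, False) for i in (1, 2, 3)]
        )
        binary = pd.DataFrame({"q1": [0], "q2": [1], "q3": [0]}, index=["a"])
        assert coding.aggregate_factors(binary, cb)["f"]["a"] == 1

    def test_outcome_factor_excluded_by_default(self):
        cb = make_codebook(
            [
                ("q1", "Basics", "f", "direct", {"y": 1, "n": 0}, False),
                ("q2", "HealthcareAccess", "delayed", "direct", {"y": 1, "n": 0}, True),
            ]
        )
        binary = pd.DataFrame({"q1": [1], "q2": [1]}, index=["a"])
        out = coding.aggregate_factors(binary, cb)
        assert list(out.columns) == ["f"]
        both = coding.aggregate_factors(binary, cb, include_outcome=True)
        assert set(both.columns) == {"f", "delayed"}

    @settings(max_examples=40, deadline=None)
    @given(st.data())
    def test_monotone_in_question_upgrades(self, data):
        """Setting any question cell 0 -> 1 never decreases any factor value."""
        cb = self._cb2()
        n = data.draw(st.integers(2, 5))
        vals = data.draw(
            st.lists(
                st.tuples(st.sampled_from([0, 1, SKIP]), st.sampled_from([0, 1, SKIP])),
                min_size=n, max_size=n,
            )
        )
        binary = pd.DataFrame(vals, columns=["q1", "q2"])
        base = coding.aggregate_factors(binary, cb)["f"]
        zeros = [(i, c) for i in range(n) for c in ("q1", "q2") if binary.at[i, c] == 0]
        if not zeros:
            return
        i, c = data.draw(st.sampled_from(zeros))
        upgraded = binary.copy()
        upgraded.at[i, c] = 1
        new = coding.aggregate_factors(upgraded, cb)["f"]
        rank = {0: 0, INVALID: 0, 1: 1}
        assert all(rank[new[j]] >= rank[base[j]] or new[j] == base[j] for j in range(n)) \
            or rank[new[i]] >= rank[base[i]]
        # the upgraded row itself can only move toward 1
        assert new[i] == 1 or new[i] == base[i]


class TestCompleteCases:
    def test_no_sentinels_all_retained(self):
        table = pd.DataFrame({"f1": [0, 1], "f2": [1, 0]}, index=["a", "b"])
        matrix, report = coding.filter_complete_cases(table)
        assert len(matrix) == 2
        assert report["retained_fraction"] == 1.0

    def test_one_of_three_excluded_forced_fraction(self):
        table = pd.DataFrame(
            {"f1": [0, INVALID, 1], "f2": [1, 0, 0]}, index=["a", "b", "c"]
        )
        matrix, report = coding.filter_complete_cases(table)
        assert report["n_retained"] == 2
        assert coding.format_percent(report["n_retained"], report["n_input"]) == 66.67
        assert report["first_cause_of_exclusion"] == {"b": "f1"}

    def test_zero_retained_is_an_error(self):
        table = pd.DataFrame({"f1": [INVALID, INVALID]}, index=["a", "b"])
        with pytest.raises(ValueError, match="no participants retained"):
            coding.filter_complete_cases(table)

    def test_output_has_no_sentinels_and_int_dtype(self):
        table = pd.DataFrame({"f1": [0, INVALID], "f2": [1, 1]}, index=["a", "b"])
        matrix, _ = coding.filter_complete_cases(table)
        assert matrix.dtypes.eq(int).all()
        assert set(np.unique(matrix.to_numpy())) <= {0, 1}


class TestSummaries:
    def _fixture(self):
        cb = make_codebook(
            [
                ("q1", "Basics", "f1", "direct", {"y": 1, "n": 0}, False),
                ("q2", "SDoHSurvey", "f2", "direct", {"y": 1, "n": 0}, False),
            ]
        )
        resp = pd.DataFrame(
            {"q1": ["y", "n", SKIP, "y"], "q2": ["n", NOT_ATTEMPTED, NOT_ATTEMPTED, "y"]},
            index=["a", "b", "c", "d"],
        )
        return cb, resp

    def test_validity_counts_conserve_n(self):
        cb, resp = self._fixture()
        summary = coding.summarize_validity(resp, cb)
        assert (summary["n_valid"] + summary["n_sentinel"] == len(resp)).all()
        assert summary.set_index("question_id")["n_valid"]["q1"] == 3

    def test_overlap_exact_subsets(self):
        cb, resp = self._fixture()
        overlap = coding.survey_overlap(resp, cb)
        # a, d complete in both; b complete in Basics only; c in neither
        assert overlap == {"Basics+SDoHSurvey": 2, "Basics": 1}

    def test_overlap_matches_brute_force_on_random_pattern(self):
        rng = np.random.default_rng(0)
        cb = make_codebook(
            [
                ("q1", "Basics", "f1", "direct", {"y": 1, "n": 0}, False),
                ("q2", "Basics", "f1", "direct", {"y": 1, "n": 0}, False),
                ("q3", "SDoHSurvey", "f2", "direct", {"y": 1, "n": 0}, False),
            ]
        )
        vals = rng.choice(["y", "n", SKIP], p=[0.4, 0.4, 0.2], size=(60, 3))
        resp = pd.DataFrame(vals, columns=["q1", "q2", "q3"])
        overlap = coding.survey_overlap(resp, cb)
        brute = {}
        for _, row in resp.iterrows():
            surveys = []
            if row["q1"] != SKIP and row["q2"] != SKIP:
                surveys.append("Basics")
            if row["q3"] != SKIP:
                surveys.append("SDoHSurvey")
            if surveys:
                key = "+".join(surveys)
                brute[key] = brute.get(key, 0) + 1
        assert overlap == brute
        # regions partition the >=1-survey-complete participants
        assert sum(overlap.values()) <= len(resp)

    def test_cooccurrence_all_zero_and_identity(self):
        zero = pd.DataFrame(np.zeros((3, 4), dtype=int))
        hist, med = coding.cooccurrence_distribution(zero)
        assert hist[0] == 3 and med == 0
        eye = pd.DataFrame(np.eye(4, dtype=int))
        hist, med = coding.cooccurrence_distribution(eye)
        assert hist[1] == 4 and med == 1

    def test_cooccurrence_median_conventions(self):
        odd = pd.DataFrame(
            [[1, 1, 0, 0, 0, 0, 0, 0, 0],
             [1, 1, 1, 1, 1, 0, 0, 0, 0],
             [1, 1, 1, 1, 1, 1, 1, 1, 1]]
        )
        _, med = coding.cooccurrence_distribution(odd)
        assert med == 5
        even = pd.DataFrame([[1, 0], [1, 1]])  # sums 1, 2: lower median = 1
        _, med = coding.cooccurrence_distribution(even)
        assert med == 1


class TestCohortProportions:
    def _demo(self):
        return pd.DataFrame(
            {
                "participant_id": [f"p{i}" for i in range(10)],
                "age_group": ["18-39"] * 5 + ["40-59"] * 5,
                "sex": ["female"] * 6 + ["male"] * 4,
                "race": ["white"] * 8 + ["black"] * 2,
                "ethnicity": ["not_hispanic"] * 10,
            }
        )

    def test_full_cohort_subset_equals_population(self):
        demo = self._demo()
        out = coding.cohort_proportions(demo, demo["participant_id"])
        sub = out[(out["side"] == "subset") & (out["variable"] == "race")]
        assert dict(zip(sub["category"], sub["percent"])) == {"black": 20.0, "white": 80.0}

    def test_printed_percentages_round_half_even(self):
        assert coding.format_percent(11_279, 12_913) == 87.35
        assert coding.format_percent(12_913, 372_397) == 3.47

    def test_small_cell_suppression(self):
        demo = self._demo()
        out = coding.cohort_proportions(
            demo, demo["participant_id"][:9], suppress=True, suppression_threshold=20
        )
        black = out[(out["category"] == "black") & (out["side"] == "subset")].iloc[0]
        assert black["count"] == 20 and black["suppressed"]
        # structural zero stays zero
        comp = out[(out["category"] == "black") & (out["side"] == "complement")]
        # complement has 1 black participant -> suppressed to 20 as well
        assert comp.iloc[0]["count"] == 20

    def test_threshold_boundary_not_suppressed(self):
        demo = self._demo()
        out = coding.cohort_proportions(
            demo, demo["participant_id"], suppress=True, suppression_threshold=2
        )
        black = out[(out["category"] == "black") & (out["side"] == "subset")].iloc[0]
        assert black["count"] == 2 and not black["suppressed"]

    def test_unknown_subset_ids_rejected(self):
        demo = self._demo()
        with pytest.raises(ValueError, match="not in demographics"):
            coding.cohort_proportions(demo, ["nope"])


class TestLongWide:
    def test_round_trip(self):
        resp = pd.DataFrame(
            {"q1": ["y", SKIP], "q2": ["n", "y"]},
            index=pd.Index(["a", "b"], name="participant_id"),
        )
        back = coding.responses_from_long(coding.responses_to_long(resp))
        assert back.sort_index(axis=1).equals(resp.sort_index(axis=1))

    def test_duplicate_pairs_rejected(self):
        long = pd.DataFrame(
            {"participant_id": ["a", "a"], "question_id": ["q1", "q1"], "value": ["y", "n"]}
        )
        with pytest.raises(CodingError, match="multiple values"):
            coding.responses_from_long(long)
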