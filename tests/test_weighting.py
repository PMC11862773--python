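"""IPW propensities, weights, weighted matrix normalization, balance."""

import numpy as np
import pandas as pd
import pytest

from sdoh_subtyper import weighting


def make_demo(n, rng, include_rule):
    demo = pd.DataFrame(
        {
            "participant_id": [f"p{i}" for i in range(n)],
            "age_group": rng.choice(["young", "old"], n),
            "sex": rng.choice(["female", "male"], n),
            "race": rng.choice(["a", "b", "c"], n, p=[0.5, 0.3, 0.2]),
            "ethnicity": rng.choice(["x", "y"], n),
        }
    )
    demo["included"] = include_rule(demo, rng)
    return demo


class TestInclusionModel:
    def test_independent_inclusion_recovers_marginal_rate(self):
        rng = np.random.default_rng(0)
        demo = make_demo(10_000, rng, lambda d, r: r.random(len(d)) < 0.25)
        prop = weighting.fit_inclusion_model(demo, covariates=("race",))
        assert prop.between(0.23, 0.27).all()

    def test_saturated_model_equals_empirical_cell_rates(self):
        rng = np.random.default_rng(1)
        demo = make_demo(
            4000, rng, lambda d, r: r.random(len(d)) < np.where(d["race"] == "a", 0.5, 0.1)
        )
        prop = weighting.fit_inclusion_model(demo, covariates=("race",), saturated=True)
        demo_idx = demo.set_index("participant_id")
        for race in ("a", "b", "c"):
            ids = demo_idx.index[demo_idx["race"] == race]
            expected = demo_idx.loc[ids, "included"].mean()
            assert np.allclose(prop.loc[ids], expected)

    def test_saturated_main_effect_propensities_close_to_rates(self):
        rng = np.random.default_rng(2)
        demo = make_demo(
            4000, rng, lambda d, r: r.random(len(d)) < np.where(d["race"] == "a", 0.5, 0.1)
        )
        prop = weighting.fit_inclusion_model(demo, covariates=("race",))
        demo_idx = demo.set_index("participant_id")
        rate_a = demo_idx.loc[demo_idx["race"] == "a", "included"].mean()
        # logistic MLE on a saturated (single categorical) design = empirical rates
        assert np.isclose(prop.loc[demo_idx.index[demo_idx["race"] == "a"]].iloc[0], rate_a, atol=1e-6)

    def test_all_included_rejected(self):
        rng = np.random.default_rng(3)
        demo = make_demo(100, rng, lambda d, r: np.ones(len(d), dtype=bool))
        with pytest.raises(ValueError, match="no contrast"):
            weighting.fit_inclusion_model(demo)

    def test_degenerate_saturated_cell_named(self):
        rng = np.random.default_rng(4)
        demo = make_demo(
            500, rng, lambda d, r: np.where(d["race"] == "a", r.random(len(d)) < 0.5, False)
        )
        with pytest.raises(ValueError, match="degenerate"):
            weighting.fit_inclusion_model(demo, covariates=("race",), saturated=True)


class TestWeights:
    def test_reciprocal(self):
        w = weighting.compute_weights(pd.Series([0.25, 0.5], index=["a", "b"]))
        assert w["a"] == 4.0 and w["b"] == 2.0

    def test_uniform_propensity_equal_weights(self):
        w = weighting.compute_weights(pd.Series([0.2] * 5))
        assert (w == 5.0).all()

    def test_out_of_range_propensity_rejected(self):
        for bad in (0.0, 1.0, -0.2, 1.3):
            with pytest.raises(ValueError, match="strictly"):
                weighting.compute_weights(pd.Series([0.5, bad]))

    def test_truncation_caps_at_quantile(self):
        rng = np.random.default_rng(5)
        p = pd.Series(rng.uniform(0.02, 0.9, 500))
        raw = 1.0 / p
        w = weighting.compute_weights(p, truncation_quantile=0.99)
        assert np.isclose(w.max(), np.quantile(raw, 0.99))
        assert np.isclose(w.min(), np.quantile(raw, 0.01))

    def test_stabilized_weights_mean_one(self):
        rng = np.random.default_rng(6)
        p = pd.Series(rng.uniform(0.1, 0.9, 200))
        w = weighting.compute_weights(p, stabilized=True)
        assert np.isclose(w.mean(), 1.0)


class TestApplyAndNormalize:
    def test_equal_weights_reduce_to_binary(self):
        mat = pd.DataFrame({"f1": [0, 1, 1], "f2": [1, 0, 1]}, index=["a", "b", "c"])
        w = pd.Series(3.0, index=mat.index)
        out = weighting.apply_and_normalize(mat, w)
        assert out.equals(mat.astype(float))

    def test_minmax_arithmetic(self):
        mat = pd.DataFrame({"f": [0, 1, 1]}, index=["a", "b", "c"])
        w = pd.Series({"a": 1.0, "b": 2.0, "c": 4.0})
        out = weighting.apply_and_normalize(mat, w)
        assert list(out["f"]) == [0.0, 0.5, 1.0]

    def test_all_zero_column_warned_and_unchanged(self):
        mat = pd.DataFrame({"f1": [1, 1], "f2": [0, 0]}, index=["a", "b"])
        w = pd.Series({"a": 2.0, "b": 3.0})
        with pytest.warns(UserWarning, match="all-zero"):
            out = weighting.apply_and_normalize(mat, w)
        assert (out["f2"] == 0).all()

    def test_all_equal_nonzero_column_becomes_one(self):
        mat = pd.DataFrame({"f": [1, 1]}, index=["a", "b"])
        w = pd.Series({"a": 2.0, "b": 2.0})
        out = weighting.apply_and_normalize(mat, w)
        assert (out["f"] == 1.0).all()

    def test_bounds_and_zero_preservation(self):
        rng = np.random.default_rng(7)
        mat = pd.DataFrame(
            rng.integers(0, 2, (50, 6)), index=[f"p{i}" for i in range(50)]
        )
        mat.iloc[0] = 1  # keep every participant's row from being all zero
        w = pd.Series(rng.uniform(1, 10, 50), index=mat.index)
        out = weighting.apply_and_normalize(mat, w)
        assert ((out >= 0) & (out <= 1)).all().all()
        assert ((mat == 0) == (out == 0)).all().all()
        nonzero_cols = mat.columns[(mat == 0).any() & (mat == 1).any()]
        assert np.allclose(out[nonzero_cols].max(), 1.0)

    def test_missing_weight_rejected(self):
        mat = pd.DataFrame({"f": [1, 1]}, index=["a", "b"])
        with pytest.raises(ValueError, match="undefined"):
            weighting.apply_and_normalize(mat, pd.Series({"a": 1.0}))


class TestBalance:
    def test_saturated_ipw_recovers_reference_exactly(self):
        rng = np.random.default_rng(8)
        demo = make_demo(
            6000, rng,
            lambda d, r: r.random(len(d))
            < np.where(d["race"] == "a", 0.6, np.where(d["race"] == "b", 0.2, 0.05)),
        )
        prop = weighting.fit_inclusion_model(demo, covariates=("race",), saturated=True)
        inc = demo.set_index("participant_id")["included"]
        w = weighting.compute_weights(prop, included=inc)
        ref = weighting.reference_distribution(demo, covariates=("race",))
        balance = weighting.check_balance(demo, w, ref, covariates=("race",))
        assert (balance["abs_diff"] < 1e-6).all()

    def test_unit_weights_reproduce_raw_differences(self):
        rng = np.random.default_rng(9)
        demo = make_demo(
            2000, rng, lambda d, r: r.random(len(d)) < np.where(d["race"] == "a", 0.5, 0.1)
        )
        inc = demo.set_index("participant_id")["included"]
        unit = pd.Series(1.0, index=inc.index[inc])
        ref = weighting.reference_distribution(demo, covariates=("race",))
        balance = weighting.check_balance(demo, unit, ref, covariates=("race",))
        demo_idx = demo.set_index("participant_id")
        raw_a = (demo_idx.loc[inc[inc].index, "race"] == "a").mean()
        row = balance[balance["category"] == "a"].iloc[0]
        assert np.isclose(row["weighted_prop"], raw_a)
        assert np.isclose(row["abs_diff"], abs(raw_a - ref["race"]["a"]))

    def test_category_absent_from_subset_diff_equals_reference(self):
        demo = pd.DataFrame(
            {
                "participant_id": ["p1", "p2", "p3", "p4"],
                "race": ["a", "a", "b", "b"],
            }
        )
        w = pd.Series({"p1": 1.0, "p2": 1.0})  # only race 'a' included
        ref = {"race": {"a": 0.5, "b": 0.5}}
        balance = weighting.check_balance(demo, w, ref, covariates=("race",))
        row = balance[balance["category"] == "b"].iloc[0]
        assert row["weighted_prop"] == 0.0
        assert np.isclose(row["abs_diff"], 0.5)

    def test_reference_mismatch_rejected(self):
        demo = pd.DataFrame({"participant_id": ["p1"], "race": ["z"]})
        w = pd.Series({"p1": 1.0})
        with pytest.raises(ValueError, match="missing categories"):
            weighting.check_balance(demo, w, {"race": {"a": 1.0}}, covariates=("race",))
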