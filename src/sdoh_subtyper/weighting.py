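"""Inverse probability weighting for complete-case selection bias.

Dropping participants with invalid survey responses skews the retained cohort
away from the full-cohort demographics.  To rebalance, a logistic model of
complete-case inclusion on demographic covariates yields a propensity for
every participant; each included participant is weighted by the reciprocal of
their propensity, boosting the contribution of groups underrepresented among
complete cases.  The weights then multiply the binary factor values, and each
factor column is min-max normalized so edge weights live in [0, 1].
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger(__name__)

DEFAULT_COVARIATES = ("age_group", "sex", "race", "ethnicity")


def _design(demographics: pd.DataFrame, covariates) -> pd.DataFrame:
    X = pd.get_dummies(
        demographics[list(covariates)].astype(str), drop_first=True, dtype=float
    )
    X.insert(0, "const", 1.0)
    return X


def fit_inclusion_model(
    demographics: pd.DataFrame,
    covariates=DEFAULT_COVARIATES,
    saturated: bool = False,
) -> pd.Series:
    """Fit a logistic model of complete-case inclusion on demographics.

    ``demographics`` needs a boolean ``included`` column covering both
    included and non-included participants.  With ``saturated``, one
    parameter per joint covariate cell is used, whose MLE equals the
    empirical inclusion rate per cell — the form under which IPW exactly
    recovers the reference distribution.

    Returns the fitted inclusion propensity (in (0, 1)) for every
    participant, indexed by participant_id.

    Raises
    ------
    ValueError
        If there is no contrast (everyone or no one included), or a joint
        covariate cell is perfectly separated (its rate is 0 or 1 under the
        saturated model), naming the offending category.
    """
    if "included" not in demographics.columns:
        raise ValueError("demographics must carry an 'included' boolean column")
    inc = demographics["included"].astype(bool)
    if inc.all():
        raise ValueError("all participants included: inclusion model has no contrast")
    if not inc.any():
        raise ValueError("no participants included: inclusion model has no contrast")

    idx = pd.Index(demographics["participant_id"])
    if saturated:
        cells = demographics[list(covariates)].astype(str).agg("|".join, axis=1)
        rates = inc.groupby(cells.values).mean()
        degenerate = rates[(rates <= 0.0) | (rates >= 1.0)]
        # cells with rate 0 are fine for weighting (they contain no included
        # participant) but violate the propensity-in-(0,1) contract; flag both
        if len(degenerate):
            raise ValueError(
                "saturated inclusion model is degenerate in cell(s): "
                f"{list(degenerate.index[:5])}"
            )
        prop = cells.map(rates)
    else:
        X = _design(demographics, covariates)
        model = sm.GLM(inc.to_numpy(dtype=float), X, family=sm.families.Binomial())
        res = model.fit(maxiter=200)
        prop = pd.Series(res.predict(X), index=demographics.index)
        # a fitted probability of ~0 for an *included* participant means the
        # model declares their inclusion impossible: complete separation
        eps = 1e-10
        sep = (prop <= eps) & inc
        if sep.any():
            bad = demographics.loc[sep, list(covariates)]
            raise ValueError(
                "inclusion model is perfectly separated for categories like "
                f"{bad.iloc[0].to_dict()}"
            )
        logger.info(
            "inclusion model: n=%d, included=%d, deviance=%.2f",
            len(inc), int(inc.sum()), res.deviance,
        )
    out = pd.Series(np.asarray(prop, dtype=float), index=idx, name="propensity")
    return out


def compute_weights(
    propensities: pd.Series,
    included: pd.Series | None = None,
    truncation_quantile: float | None = None,
    stabilized: bool = False,
) -> pd.Series:
    """Inverse-propensity weights for the included participants.

    weight = 1 / propensity (optionally times the marginal inclusion rate if
    ``stabilized``).  With ``truncation_quantile`` q, weights are clipped
    symmetrically to their [1-q, q] quantiles.

    Raises
    ------
    ValueError
        If any propensity lies outside (0, 1).
    """
    p = propensities.astype(float)
    if included is not None:
        p = p[np.asarray(included, dtype=bool)]
    if (p <= 0).any() or (p >= 1).any():
        raise ValueError("propensities must lie strictly in (0, 1)")
    w = 1.0 / p
    if stabilized:
        w = w * (len(p) / w.sum())
    if truncation_quantile is not None:
        if not 0.5 < truncation_quantile < 1.0:
            raise ValueError("truncation_quantile must be in (0.5, 1)")
        hi = float(np.quantile(w, truncation_quantile))
        lo = float(np.quantile(w, 1.0 - truncation_quantile))
        w = w.clip(lo, hi)
    logger.info(
        "IPW weights: n=%d min=%.3f median=%.3f max=%.3f",
        len(w), w.min(), float(np.median(w)), w.max(),
    )
    return w.rename("weight")


def apply_and_normalize(matrix: pd.DataFrame, weights: pd.Series) -> pd.DataFrame:
    """Weight the binary factor matrix and min-max normalize per factor.

    Each cell becomes weight_i * x_ij; each column is then rescaled by its
    observed min and max to [0, 1].  Zeros are preserved (a non-expressed
    factor stays 0).  Degenerate columns: an all-zero column is left as zeros
    with a warning; an all-equal nonzero column maps to 1.
    """
    missing = matrix.index.difference(weights.index)
    if len(missing):
        raise ValueError(f"weights undefined for participants like {list(missing[:5])}")
    w = weights.loc[matrix.index].to_numpy(dtype=float)
    vals = matrix.to_numpy(dtype=float) * w[:, None]
    lo = vals.min(axis=0)
    hi = vals.max(axis=0)
    out = np.zeros_like(vals)
    for j in range(vals.shape[1]):
        if hi[j] == 0.0:
            warnings.warn(
                f"factor {matrix.columns[j]!r} is all-zero; left unnormalized",
                stacklevel=2,
            )
        elif hi[j] == lo[j]:
            out[:, j] = 1.0
        else:
            out[:, j] = (vals[:, j] - lo[j]) / (hi[j] - lo[j])
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def reference_distribution(demographics: pd.DataFrame, covariates=DEFAULT_COVARIATES) -> dict:
    """Full-cohort category proportions per covariate (the IPW target)."""
    return {
        var: demographics[var].astype(str).value_counts(normalize=True).to_dict()
        for var in covariates
    }


def check_balance(
    demographics: pd.DataFrame,
    weights: pd.Series,
    reference: dict,
    covariates=DEFAULT_COVARIATES,
) -> pd.DataFrame:
    """Compare weighted demographic proportions of the included cohort to a reference.

    Returns one row per (variable, category) with the weighted proportion,
    the reference proportion, their absolute difference, and the standardized
    difference.  Categories present in the included cohort must all appear in
    the reference.
    """
    demo = demographics.set_index("participant_id")
    sub = demo.loc[weights.index]
    w = weights.to_numpy(dtype=float)
    rows = []
    for var in covariates:
        if var not in reference:
            raise ValueError(f"reference distribution missing variable {var!r}")
        ref = reference[var]
        observed = set(sub[var].astype(str).unique())
        extra = observed - set(ref)
        if extra:
            raise ValueError(f"reference for {var!r} missing categories {sorted(extra)}")
        for cat, p_ref in ref.items():
            mask = (sub[var].astype(str) == cat).to_numpy()
            p_w = float(w[mask].sum() / w.sum())
            denom = np.sqrt((p_w * (1 - p_w) + p_ref * (1 - p_ref)) / 2.0)
            rows.append(
                {
                    "variable": var,
                    "category": cat,
                    "weighted_prop": p_w,
                    "reference_prop": float(p_ref),
                    "abs_diff": abs(p_w - p_ref),
                    "std_diff": (p_w - p_ref) / denom if denom > 0 else 0.0,
                }
            )
    return pd.DataFrame(rows)
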