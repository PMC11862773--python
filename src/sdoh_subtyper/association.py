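"""Subtype-outcome associations: pairwise weighted logistic odds ratios.

For every unordered pair of subtypes (a, b) and each binary outcome, a
logistic regression of the outcome on an indicator for membership in subtype
``a`` is fitted on the participants of ``a`` union ``b``, optionally adjusted
for demographic covariates and weighted by the IPW weights (treated as
probability weights, with robust sandwich standard errors).  OR = exp(beta),
with Wald 95% CIs.  p values are Benjamini-Hochberg adjusted within each
outcome family.  The same machinery serves the Medicaid-nonexpansion
enrichment analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "AssociationResult",
    "pairwise_cluster_or",
    "fdr_adjust",
    "medicaid_enrichment",
    "association_table",
]

DEFAULT_COVARIATES = ("age_group", "sex", "race", "ethnicity")


@dataclass
class AssociationResult:
    """Pairwise-subtype odds ratio for one outcome."""

    cluster_pair: tuple
    outcome: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_raw: float
    p_fdr: float | None = None
    estimable: bool = True
    note: str = ""


def _fit_pair(
    y: np.ndarray, indicator: np.ndarray, covars: pd.DataFrame | None, w: np.ndarray
):
    X = pd.DataFrame({"const": 1.0, "cluster_a": indicator.astype(float)})
    if covars is not None and covars.shape[1]:
        dummies = pd.get_dummies(covars.astype(str), drop_first=True, dtype=float)
        dummies.index = X.index
        X = pd.concat([X, dummies], axis=1)
    model = sm.GLM(y, X, family=sm.families.Binomial(), var_weights=w)
    with warnings.catch_warnings():
        # near-separated fits emit divide-by-zero noise from the IRLS
        # internals; the resulting estimates are screened for stability below
        warnings.simplefilter("ignore", RuntimeWarning)
        res = model.fit(maxiter=200, cov_type="HC0")
    beta = res.params["cluster_a"]
    se = res.bse["cluster_a"]
    return beta, se


def pairwise_cluster_or(
    membership: pd.Series,
    outcomes: pd.DataFrame,
    outcome: str,
    demographics: pd.DataFrame | None = None,
    covariates=(),
    weights: pd.Series | None = None,
    fdr: bool = True,
) -> list[AssociationResult]:
    """Pairwise subtype odds ratios for one outcome, FDR-adjusted as a family.

    Parameters
    ----------
    membership : Series mapping participant_id -> cluster label (clustered
        participants only; the unclustered are excluded upstream).
    outcomes : DataFrame with a ``participant_id`` column and binary outcome
        columns.
    outcome : name of the outcome column.
    demographics : participant-level covariate table (needed when
        ``covariates`` is nonempty).
    weights : IPW weights per participant (defaults to 1).
    fdr : adjust the estimable results as one BH family (default).

    Outcomes constant within a pair's pooled participants are flagged
    non-estimable and excluded from the FDR family.
    """
    out = outcomes.set_index("participant_id")[outcome]
    demo = demographics.set_index("participant_id") if demographics is not None else None
    clusters = sorted(pd.unique(membership))
    if len(clusters) < 2:
        raise ValueError("need at least two clusters for pairwise comparisons")
    results = []
    for i, a in enumerate(clusters):
        for b in clusters[i + 1 :]:
            ids = membership.index[membership.isin([a, b])]
            y = out.loc[ids].to_numpy(dtype=float)
            ind = (membership.loc[ids] == a).to_numpy()
            w = (
                weights.loc[ids].to_numpy(dtype=float)
                if weights is not None
                else np.ones(len(ids))
            )
            if len(np.unique(y)) < 2:
                results.append(
                    AssociationResult(
                        (a, b), outcome, np.nan, np.nan, np.nan, np.nan,
                        estimable=False, note="outcome constant in pooled clusters",
                    )
                )
                continue
            covars = demo.loc[ids, list(covariates)] if covariates else None
            try:
                beta, se = _fit_pair(y, ind, covars, w)
            except Exception as err:  # separation / convergence failure
                results.append(
                    AssociationResult(
                        (a, b), outcome, np.nan, np.nan, np.nan, np.nan,
                        estimable=False, note=f"fit failed: {err}",
                    )
                )
                continue
            if not np.isfinite(se) or se > 1e3 or abs(beta) > 30:
                results.append(
                    AssociationResult(
                        (a, b), outcome, float(np.exp(beta)), np.nan, np.nan, np.nan,
                        estimable=False, note="quasi-separation: unstable standard error",
                    )
                )
                continue
            zcrit = stats.norm.ppf(0.975)
            # floor at the smallest positive float: Wald p underflows to 0
            # for extreme z, but the p-value scale is (0, 1]
            p = max(2 * stats.norm.sf(abs(beta / se)), 5e-324)
            results.append(
                AssociationResult(
                    cluster_pair=(a, b),
                    outcome=outcome,
                    odds_ratio=float(np.exp(beta)),
                    ci_low=float(np.exp(beta - zcrit * se)),
                    ci_high=float(np.exp(beta + zcrit * se)),
                    p_raw=float(p),
                )
            )
    if fdr:
        _adjust_family(results)
    return results


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values (monotonicity enforced)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _adjust_family(results: list[AssociationResult]) -> None:
    est = [r for r in results if r.estimable]
    if not est:
        return
    adj = fdr_adjust([r.p_raw for r in est])
    for r, q in zip(est, adj):
        r.p_fdr = float(q)


def medicaid_enrichment(
    membership: pd.Series,
    outcomes: pd.DataFrame,
    demographics: pd.DataFrame | None = None,
    covariates=(),
    weights: pd.Series | None = None,
) -> list[AssociationResult]:
    """Subtype enrichment for residence in a Medicaid-nonexpansion state.

    Identical machinery to :func:`pairwise_cluster_or` with the
    ``no_medicaid_expansion`` flag as the outcome; its pairwise comparisons
    form their own FDR family.
    """
    return pairwise_cluster_or(
        membership,
        outcomes,
        "no_medicaid_expansion",
        demographics=demographics,
        covariates=covariates,
        weights=weights,
    )


def _round_sig(x: float, sig: int = 2) -> float:
    if not np.isfinite(x) or x == 0:
        return x
    return float(np.format_float_positional(x, precision=sig, fractional=False))


def association_table(results: list[AssociationResult]) -> pd.DataFrame:
    """Tidy table of association results (full precision plus a display column)."""
    rows = []
    for r in results:
        disp = (
            f"{_round_sig(r.odds_ratio)} ({_round_sig(r.ci_low)}-{_round_sig(r.ci_high)})"
            if r.estimable
            else "NE"
        )
        rows.append(
            {
                "pair": f"{r.cluster_pair[0]} vs {r.cluster_pair[1]}",
                "outcome": r.outcome,
                "odds_ratio": r.odds_ratio,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "p_raw": r.p_raw,
                "p_fdr": r.p_fdr,
                "estimable": r.estimable,
                "display": disp,
            }
        )
    return pd.DataFrame(rows)
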