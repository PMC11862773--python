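"""End-to-end orchestration: simulate -> code -> weight -> cluster -> test ->
replicate -> associate -> visualize, from one validated config.

The config is strict YAML (unknown keys are errors) with a ``version`` key;
all randomness flows from the single master seed via derived per-stage
substreams, so identical configs reproduce identical reports.  Each stage
appends its parameters and key outputs to a machine-readable run report whose
JSON schema ships with the package (``report_schema()``).
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import association as assoc
from . import coding, significance, synthetic, viz, weighting
from .bipartite import build_network, maximize_modularity

logger = logging.getLogger("sdoh_subtyper.pipeline")


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SimulateSection(_Strict):
    n_participants: int = 2000
    p_in: float = 0.6
    p_out: float = 0.1
    attempt_probs: dict[str, float] = Field(
        default_factory=lambda: dict(synthetic.DEFAULT_ATTEMPT_PROBS)
    )
    skip_prob: float = 0.01
    pna_prob: float = 0.005
    uniform_strata: bool = False


class WeightingSection(_Strict):
    covariates: list[str] = Field(default_factory=lambda: list(weighting.DEFAULT_COVARIATES))
    saturated: bool = False
    truncation_quantile: Optional[float] = None
    stabilized: bool = False


class ClusteringSection(_Strict):
    n_restarts: int = 20


class SignificanceSection(_Strict):
    B: int = 1000


class ReplicationSection(_Strict):
    B: int = 1000
    fraction: float = 0.5


class AssociationSection(_Strict):
    outcomes: list[str] = Field(
        default_factory=lambda: ["depression", "delayed_care", "er_visit"]
    )
    enrichment: Optional[str] = "no_medicaid_expansion"
    covariates: list[str] = Field(default_factory=lambda: list(assoc.DEFAULT_COVARIATES))


class VisualizationSection(_Strict):
    enabled: bool = True
    separation: float = 0.5
    iterations: int = 50


class RunConfig(_Strict):
    """Full pipeline configuration (strict: unknown keys are rejected)."""

    version: int = 1
    seed: int = 7
    out_dir: str = "sdoh_run"
    strict_aggregation: bool = False
    suppress_small_cells: bool = True
    simulate: SimulateSection = Field(default_factory=SimulateSection)
    weighting: WeightingSection = Field(default_factory=WeightingSection)
    clustering: ClusteringSection = Field(default_factory=ClusteringSection)
    significance: SignificanceSection = Field(default_factory=SignificanceSection)
    replication: ReplicationSection = Field(default_factory=ReplicationSection)
    association: AssociationSection = Field(default_factory=AssociationSection)
    visualization: VisualizationSection = Field(default_factory=VisualizationSection)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.model_validate(raw)


class RunReport(_Strict):
    """Machine-readable pipeline report; one entry per executed stage."""

    format_version: int = 1
    seed: int
    stages: dict[str, dict] = Field(default_factory=dict)
    warnings: list[str] = Field(default_factory=list)
    failed_stage: Optional[str] = None
    error: Optional[str] = None


def report_schema() -> dict:
    """JSON schema of the run report."""
    return RunReport.model_json_schema()


def demo_config(n_participants: int = 2000, seed: int = 7, B: int = 99, out_dir: str = "demo_run") -> RunConfig:
    """The desk-scale demo configuration.

    Uses light rollout missingness (0.9/0.8 on the two later surveys) so that
    a cohort of 2,000 yields several hundred complete cases — enough to
    exercise every stage including the pairwise association models — while
    still producing the demographic selection the IPW stage corrects.
    """
    return RunConfig(
        seed=seed,
        out_dir=out_dir,
        simulate=SimulateSection(
            n_participants=n_participants,
            attempt_probs={
                "Basics": 1.0,
                "OverallHealth": 1.0,
                "HealthcareAccess": 0.9,
                "SDoHSurvey": 0.8,
            },
        ),
        significance=SignificanceSection(B=B),
        replication=ReplicationSection(B=B),
    )


def suppress_small_cells(report: dict, threshold: int = 20) -> dict:
    """Replace reported participant counts below the threshold by the threshold.

    Applies to any key named ``*count*`` (or entries of a ``counts`` mapping)
    nested in the report; suppressed entries are flagged alongside.  Zero
    counts are structural zeros and exempt.
    """

    def walk(obj):
        if isinstance(obj, dict):
            out = {}
            for key, val in obj.items():
                if (
                    isinstance(val, (int, np.integer))
                    and not isinstance(val, bool)
                    and "count" in str(key).lower()
                    and 0 < val < threshold
                ):
                    out[key] = threshold
                    out[f"{key}_suppressed"] = True
                elif str(key).lower() == "counts" and isinstance(val, dict):
                    new = {}
                    flagged = []
                    for k2, v2 in val.items():
                        if (
                            isinstance(v2, (int, np.integer))
                            and not isinstance(v2, bool)
                            and 0 < v2 < threshold
                        ):
                            new[k2] = threshold
                            flagged.append(k2)
                        else:
                            new[k2] = walk(v2)
                    out[key] = new
                    if flagged:
                        out["counts_suppressed"] = flagged
                else:
                    out[key] = walk(val)
            return out
        if isinstance(obj, list):
            return [walk(v) for v in obj]
        return obj

    return walk(report)


class StageError(RuntimeError):
    def __init__(self, stage: str, err: Exception):
        super().__init__(f"stage {stage!r} failed: {err}")
        self.stage = stage


def run_pipeline(config: RunConfig, write_outputs: bool = True) -> dict:
    """Execute all stages in order and return the run report as a dict.

    A failure in any stage aborts the run; the partial report (with
    ``failed_stage`` set) is still written to ``out_dir`` and the StageError
    re-raised for the caller / CLI to convert into a nonzero exit status.
    """
    out_dir = Path(config.out_dir)
    if write_outputs:
        out_dir.mkdir(parents=True, exist_ok=True)
    report = RunReport(seed=config.seed)
    stage_seeds = np.random.SeedSequence(config.seed).generate_state(16) % (2**31)
    state: dict = {}

    stages = [
        ("simulate", _stage_simulate),
        ("code_factors", _stage_code),
        ("characterize", _stage_characterize),
        ("weight", _stage_weight),
        ("cluster", _stage_cluster),
        ("significance", _stage_significance),
        ("replicate", _stage_replicate),
        ("associate", _stage_associate),
        ("visualize", _stage_visualize),
    ]
    try:
        for i, (name, fn) in enumerate(stages):
            t0 = time.perf_counter()
            try:
                entry = fn(config, state, int(stage_seeds[i]), out_dir if write_outputs else None)
            except Exception as err:
                raise StageError(name, err) from err
            entry["elapsed_s"] = round(time.perf_counter() - t0, 3)
            report.stages[name] = entry
            logger.info("stage %s done in %.2fs", name, entry["elapsed_s"])
    except StageError as err:
        report.failed_stage = err.stage
        report.error = str(err)
        if write_outputs:
            _write_report(report, config, out_dir)
        raise
    if write_outputs:
        _write_report(report, config, out_dir)
    return _final_report_dict(report, config)


def _final_report_dict(report: RunReport, config: RunConfig) -> dict:
    d = report.model_dump()
    if config.suppress_small_cells:
        d = suppress_small_cells(d)
    return d


def _write_report(report: RunReport, config: RunConfig, out_dir: Path) -> None:
    d = _final_report_dict(report, config)
    (out_dir / "report.json").write_text(json.dumps(d, indent=2, default=float))
    (out_dir / "report_schema.json").write_text(json.dumps(report_schema(), indent=2))


def _stage_simulate(config: RunConfig, state: dict, seed: int, out_dir) -> dict:
    sim = config.simulate
    strata = (
        [(lab, pop, 1.0) for lab, pop, _ in synthetic.DEFAULT_STRATA]
        if sim.uniform_strata
        else list(synthetic.DEFAULT_STRATA)
    )
    sc = synthetic.SimulationConfig(
        n_participants=sim.n_participants,
        p_in=sim.p_in,
        p_out=sim.p_out,
        attempt_probs=dict(sim.attempt_probs),
        skip_prob=sim.skip_prob,
        pna_prob=sim.pna_prob,
        demographic_strata=strata,
        seed=seed,
    )
    cohort, observed = synthetic.simulate(sc)
    state["cohort"], state["observed"] = cohort, observed
    if out_dir is not None:
        synthetic.write_cohort(cohort, observed, out_dir)
    return {
        "params": sim.model_dump(),
        "n_participants": sim.n_participants,
        "n_questions": observed.shape[1],
    }


def _stage_code(config: RunConfig, state: dict, seed: int, out_dir) -> dict:
    cohort, observed = state["cohort"], state["observed"]
    binary = coding.dichotomize_responses(observed, cohort.codebook)
    factors = coding.aggregate_factors(binary, cohort.codebook, strict=config.strict_aggregation)
    matrix, excl = coding.filter_complete_cases(factors)
    state["binary"], state["matrix"] = binary, matrix
    if out_dir is not None:
        matrix.to_csv(out_dir / "factor_matrix.csv")
    return {
        "rows_in": excl["n_input"],
        "rows_out": excl["n_retained"],
        "retained_fraction": excl["retained_fraction"],
        "n_factors": matrix.shape[1],
    }


def _stage_characterize(config: RunConfig, state: dict, seed: int, out_dir) -> dict:
    cohort, observed, matrix = state["cohort"], state["observed"], state["matrix"]
    validity = coding.summarize_validity(observed, cohort.codebook)
    overlap = coding.survey_overlap(observed, cohort.codebook)
    hist, median = coding.cooccurrence_distribution(matrix)
    demo_cmp = coding.cohort_proportions(
        cohort.demographics, matrix.index, suppress=config.suppress_small_cells
    )
    if out_dir is not None:
        validity.to_csv(out_dir / "validity_summary.csv", index=False)
        (out_dir / "overlap.json").write_text(json.dumps(overlap, indent=2))
        hist.rename_axis("n_cooccurring").to_csv(out_dir / "cooccurrence.csv")
        demo_cmp.to_csv(out_dir / "demographics_comparison.csv", index=False)
    return {
        "median_factor_cooccurrence": median,
        "survey_overlap_counts": overlap,
        "n_questions_summarized": int(len(validity)),
    }


def _stage_weight(config: RunConfig, state: dict, seed: int, out_dir) -> dict:
    cohort, matrix = state["cohort"], state["matrix"]
    wc = config.weighting
    demo = cohort.demographics.copy()
    demo["included"] = demo["participant_id"].isin(matrix.index)
    prop = weighting.fit_inclusion_model(demo, wc.covariates, saturated=wc.saturated)
    # participants whose propensity is numerically 0/1 have no valid weight
    # and are dropped (with the count logged in the report)
    eps = 1e-10
    p_inc = prop.loc[matrix.index]
    valid = (p_inc > eps) & (p_inc < 1 - eps)
    matrix = matrix.loc[valid[valid].index]
    weights = weighting.compute_weights(
        p_inc[valid],
        truncation_quantile=wc.truncation_quantile,
        stabilized=wc.stabilized,
    )
    weighted = weighting.apply_and_normalize(matrix, weights)
    reference = weighting.reference_distribution(demo, wc.covariates)
    balance = weighting.check_balance(demo, weights, reference, wc.covariates)
    state["weights"], state["weighted"] = weights, weighted
    if out_dir is not None:
        weights.rename_axis("participant_id").to_csv(out_dir / "weights.csv")
        weighted.to_csv(out_dir / "weighted_matrix.csv")
        balance.to_csv(out_dir / "balance_report.csv", index=False)
    return {
        "params": wc.model_dump(),
        "n_weighted": int(len(weights)),
        "n_dropped_degenerate_propensity": int((~valid).sum()),
        "max_abs_std_diff": float(balance["std_diff"].abs().max()),
    }


def _stage_cluster(config: RunConfig, state: dict, seed: int, out_dir) -> dict:
    weighted = state["weighted"]
    train, repl = significance.split_cohort(
        weighted, fraction=config.replication.fraction, seed=seed
    )
    net = build_network(train)
    sol = maximize_modularity(net, n_restarts=config.clustering.n_restarts, seed=seed)
    state["train"], state["repl"] = train, repl
    state["train_network"], state["train_solution"] = net, sol
    if out_dir is not None:
        net.edges().to_csv(out_dir / "train_edges.tsv", sep="\t", index=False)
        payload = {"labels": sol.labels, "K": sol.n_clusters, "Q": sol.modularity}
        (out_dir / "biclusters.json").write_text(json.dumps(payload, indent=2))
    return {
        "n_restarts": config.clustering.n_restarts,
        "train_size": int(len(train)),
        "replication_size": int(len(repl)),
        "n_biclusters": sol.n_clusters,
        "Q": sol.modularity,
        "unclustered_participant_count": len(net.excluded_participants),
    }


def _stage_significance(config: RunConfig, state: dict, seed: int, out_dir) -> dict:
    res = significance.significance_of_Q(
        state["train_network"],
        B=config.significance.B,
        n_restarts=config.clustering.n_restarts,
        seed=seed,
    )
    state["significance"] = res
    entry = {
        "Q": res.observed,
        "null_mean": res.null_mean,
        "null_sd": res.null_sd,
        "z": res.z_score,
        "p": res.p_value,
        "B": res.B,
    }
    if out_dir is not None:
        (out_dir / "significance.json").write_text(json.dumps(entry, indent=2, default=float))
    return entry


def _stage_replicate(config: RunConfig, state: dict, seed: int, out_dir) -> dict:
    res = significance.replication_test(
        state["train"],
        state["repl"],
        B=config.replication.B,
        n_restarts=config.clustering.n_restarts,
        seed=seed,
    )
    state["replication"] = res
    entry = {
        "RI": res.rand_index,
        "null_mean": res.null_mean,
        "p": res.p_value,
        "B": res.B,
        "train_factor_labels": {
            str(k): int(v) for k, v in res.train_solution.factor_partition().items()
        },
        "replication_factor_labels": {
            str(k): int(v) for k, v in res.replication_solution.factor_partition().items()
        },
    }
    if out_dir is not None:
        (out_dir / "replication.json").write_text(json.dumps(entry, indent=2, default=float))
    return entry


def _stage_associate(config: RunConfig, state: dict, seed: int, out_dir) -> dict:
    cohort = state["cohort"]
    sol = state["train_solution"]
    ac = config.association
    membership = pd.Series(
        sol.participant_labels, index=sol.participant_ids, name="cluster"
    )
    weights = state["weights"]
    all_results = []
    for outcome in ac.outcomes:
        all_results.extend(
            assoc.pairwise_cluster_or(
                membership,
                cohort.outcomes,
                outcome,
                demographics=cohort.demographics,
                covariates=ac.covariates,
                weights=weights,
            )
        )
    if ac.enrichment:
        all_results.extend(
            assoc.pairwise_cluster_or(
                membership,
                cohort.outcomes,
                ac.enrichment,
                demographics=cohort.demographics,
                covariates=ac.covariates,
                weights=weights,
            )
        )
    table = assoc.association_table(all_results)
    state["associations"] = table
    if out_dir is not None:
        table.to_csv(out_dir / "associations.csv", index=False)
    return {
        "outcomes": list(ac.outcomes) + ([ac.enrichment] if ac.enrichment else []),
        "n_comparisons": int(len(table)),
        "n_estimable": int(table["estimable"].sum()),
        "rows": table.drop(columns=["display"]).to_dict(orient="records"),
    }


def _stage_visualize(config: RunConfig, state: dict, seed: int, out_dir) -> dict:
    if not config.visualization.enabled:
        return {"skipped": True}
    net, sol = state["train_network"], state["train_solution"]
    coords = viz.layout_fr(net, seed=seed, iterations=config.visualization.iterations)
    exploded = viz.explode_layout(coords, sol.labels, config.visualization.separation)
    entry = {"separation": config.visualization.separation, "n_nodes": len(exploded)}
    if out_dir is not None:
        files = viz.render_network(
            net, exploded, sol.labels, out_prefix=str(out_dir / "network"), seed=seed
        )
        viz.save_coords(exploded, sol.labels, out_dir / "coords.csv")
        entry["files"] = files
    return entry
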