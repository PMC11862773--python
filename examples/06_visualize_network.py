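"""Render the bicluster network figure.

Force-directed (Fruchterman-Reingold) layout, then a rigid radial "explode"
that separates the biclusters for legibility; participants are circles,
factors labeled triangles, colors follow biclusters.  Writes SVG + PNG next
to this script's working directory under example_output/.
"""

from pathlib import Path

from sdoh_subtyper import coding, synthetic, viz, weighting
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
solution = maximize_modularity(network, seed=7)
coords = viz.layout_fr(network, seed=7)
exploded = viz.explode_layout(coords, solution.labels, separation=0.6)

out = Path("example_output")
out.mkdir(exist_ok=True)
files = viz.render_network(
    network, exploded, solution.labels,
    annotations={1: "cluster 1", 2: "cluster 2", 3: "cluster 3", 4: "cluster 4"},
    out_prefix=str(out / "network"),
)
viz.save_coords(exploded, solution.labels, out / "coords.csv")
print(f"K={solution.n_clusters} biclusters rendered to: " + ", ".join(files))
print("Triangles = SDoH factors (labeled), circles = participants, color = bicluster.")
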