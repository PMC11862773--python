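"""Bipartite network figures: force-directed layout with cluster separation.

The layout pipeline is Fruchterman-Reingold force direction followed by an
"explode" step that rigidly translates each cluster's nodes radially outward
from the global centroid, visually separating the biclusters while preserving
within-cluster geometry exactly.  Participants render as circles, factors as
labeled triangles, colors follow cluster labels.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import networkx as nx
import numpy as np
import pandas as pd

from .bipartite import BipartiteNetwork

__all__ = ["layout_fr", "explode_layout", "render_network", "save_coords"]


def layout_fr(
    network: BipartiteNetwork, seed: int = 7, iterations: int = 50
) -> dict:
    """Fruchterman-Reingold coordinates, rescaled into the unit square."""
    g = network.to_networkx()
    pos = nx.spring_layout(g, seed=seed, iterations=iterations, weight="weight")
    xy = np.array(list(pos.values()))
    lo = xy.min(axis=0)
    span = xy.max(axis=0) - lo
    span[span == 0] = 1.0
    return {node: tuple((np.asarray(p) - lo) / span) for node, p in pos.items()}


def explode_layout(coords: dict, labels: dict, separation: float) -> dict:
    """Translate each cluster rigidly outward from the global centroid.

    Every cluster's centroid moves radially away from the centroid of all
    nodes by ``separation`` times its current distance; within-cluster
    geometry is preserved exactly (a per-cluster isometry).
    """
    if separation < 0:
        raise ValueError("separation must be nonnegative")
    missing = [n for n in coords if n not in labels]
    if missing:
        raise ValueError(f"labels missing for nodes like {missing[:5]}")
    xy = np.array([coords[n] for n in coords])
    global_c = xy.mean(axis=0)
    out = {}
    for lab in sorted({labels[n] for n in coords}):
        nodes = [n for n in coords if labels[n] == lab]
        pts = np.array([coords[n] for n in nodes])
        centroid = pts.mean(axis=0)
        shift = (centroid - global_c) * separation
        for n, p in zip(nodes, pts):
            out[n] = tuple(p + shift)
    return out


_CLUSTER_COLORS = [
    "#e377c2", "#2ca02c", "#1f77b4", "#7f7f7f", "#ff7f0e",
    "#9467bd", "#8c564b", "#bcbd22", "#17becf", "#d62728",
]


def render_network(
    network: BipartiteNetwork,
    coords: dict,
    labels: dict,
    annotations: dict | None = None,
    out_prefix="network",
    max_participants_drawn: int = 2000,
    seed: int = 0,
) -> list[str]:
    """Render the bipartite network to SVG and PNG.

    Circles are participants and triangles are factors, colored by cluster;
    factor nodes carry their factor names and ``annotations`` (cluster ->
    string, e.g. an OR summary) are drawn at cluster centroids.  Participant
    *rendering* may be down-sampled above ``max_participants_drawn`` for
    legibility; the underlying network is never altered.

    Returns the written file paths.
    """
    missing = [n for n in list(network.participant_ids) + list(network.factor_ids)
               if n not in coords]
    if missing:
        raise ValueError(f"coordinates missing for nodes like {missing[:5]}")
    pids = list(network.participant_ids)
    if len(pids) > max_participants_drawn:
        rng = np.random.default_rng(seed)
        pids = list(rng.choice(pids, size=max_participants_drawn, replace=False))

    fig, ax = plt.subplots(figsize=(9, 9))
    for kind, nodes, marker, size in (
        ("participant", pids, "o", 12),
        ("factor", list(network.factor_ids), "^", 260),
    ):
        xy = np.array([coords[n] for n in nodes])
        colors = [_CLUSTER_COLORS[(labels[n] - 1) % len(_CLUSTER_COLORS)] for n in nodes]
        ax.scatter(
            xy[:, 0], xy[:, 1], s=size, c=colors, marker=marker,
            edgecolors="black" if kind == "factor" else "none",
            linewidths=0.8, zorder=3 if kind == "factor" else 2,
            alpha=1.0 if kind == "factor" else 0.45,
        )
    for fid in network.factor_ids:
        x, y = coords[fid]
        ax.annotate(str(fid), (x, y), textcoords="offset points", xytext=(6, 6), fontsize=7)
    if annotations:
        by_cluster: dict = {}
        for n, lab in labels.items():
            by_cluster.setdefault(lab, []).append(coords[n])
        for lab, text in annotations.items():
            if lab in by_cluster:
                cx, cy = np.array(by_cluster[lab]).mean(axis=0)
                ax.annotate(
                    str(text), (cx, cy), fontsize=10, fontweight="bold",
                    ha="center", color="black",
                    bbox={"boxstyle": "round", "fc": "white", "alpha": 0.7},
                )
    ax.set_axis_off()
    written = []
    for ext in ("svg", "png"):
        path = str(Path(f"{out_prefix}.{ext}"))
        fig.savefig(path, bbox_inches="tight", dpi=150)
        written.append(path)
    plt.close(fig)
    return written


def save_coords(coords: dict, labels: dict, path) -> None:
    df = pd.DataFrame(
        [
            {"node": n, "x": x, "y": y, "cluster": labels.get(n)}
            for n, (x, y) in coords.items()
        ]
    )
    df.to_csv(path, index=False)
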