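"""Weighted bipartite participant-factor networks and modularity biclustering.

The subtyping step models participants and SDoH factors as the two node sets
of a weighted bipartite network and searches for *biclusters*: joint groups of
participants and the factors that co-occur in them.  Cluster quality is scored
with Barber's bipartite modularity

    Q = (1/m) * sum_{i in P, j in F} (A_ij - k_i d_j / m) * [g_i == g_j]

where ``A_ij`` is the (weighted) incidence matrix, ``k_i`` and ``d_j`` are the
participant and factor strengths, ``m`` the total edge weight, and the
indicator restricts the sum to node pairs sharing a cluster.  The null term
``k_i d_j / m`` is the bipartite configuration model, i.e. the expected weight
between ``i`` and ``j`` when edges are rewired preserving strengths.

Maximization uses a BRIM-style alternating scheme: holding factor labels
fixed, every participant's optimal cluster has a closed form (and is
independent of the other participants), and symmetrically for factors; the two
half-sweeps are alternated to a local optimum and repeated over random
restarts.  A small exhaustive search over all set partitions serves as an
exact oracle for networks of up to 12 nodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BipartiteNetwork",
    "BiclusterSolution",
    "build_network",
    "barber_modularity",
    "maximize_modularity",
    "brute_force_partition",
]


@dataclass
class BipartiteNetwork:
    """Weighted bipartite network held as a dense participant x factor matrix.

    Participants with zero strength are excluded at construction (modularity
    is undefined for them) and reported in ``excluded_participants``.
    """

    participant_ids: np.ndarray
    factor_ids: np.ndarray
    matrix: np.ndarray  # (n, d) nonnegative weights
    excluded_participants: list = field(default_factory=list)

    @property
    def n_participants(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_factors(self) -> int:
        return self.matrix.shape[1]

    @property
    def participant_strengths(self) -> np.ndarray:
        """k_i: row sums of the incidence matrix."""
        return self.matrix.sum(axis=1)

    @property
    def factor_strengths(self) -> np.ndarray:
        """d_j: column sums of the incidence matrix."""
        return self.matrix.sum(axis=0)

    @property
    def total_weight(self) -> float:
        """m: total edge weight."""
        return float(self.matrix.sum())

    def edges(self) -> pd.DataFrame:
        """Edge list (source participant, target factor, weight > 0)."""
        rows, cols = np.nonzero(self.matrix)
        return pd.DataFrame(
            {
                "source": np.asarray(self.participant_ids)[rows],
                "target": np.asarray(self.factor_ids)[cols],
                "weight": self.matrix[rows, cols],
            }
        )

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        for pid in self.participant_ids:
            g.add_node(pid, node_type="participant", bipartite=0)
        for fid in self.factor_ids:
            g.add_node(fid, node_type="factor", bipartite=1)
        for _, row in self.edges().iterrows():
            g.add_edge(row["source"], row["target"], weight=float(row["weight"]))
        return g


@dataclass
class BiclusterSolution:
    """Joint labeling of participants and factors into 1..K biclusters."""

    participant_ids: np.ndarray
    factor_ids: np.ndarray
    participant_labels: np.ndarray  # ints in 1..K
    factor_labels: np.ndarray
    modularity: float

    @property
    def n_clusters(self) -> int:
        return int(
            len(
                np.union1d(
                    np.unique(self.participant_labels), np.unique(self.factor_labels)
                )
            )
        )

    @property
    def labels(self) -> dict:
        """Mapping node id -> cluster label over all nodes."""
        out = dict(zip(self.participant_ids, (int(v) for v in self.participant_labels)))
        out.update(zip(self.factor_ids, (int(v) for v in self.factor_labels)))
        return out

    def factor_partition(self) -> pd.Series:
        return pd.Series(self.factor_labels, index=self.factor_ids, name="cluster")


def build_network(weighted: pd.DataFrame) -> BipartiteNetwork:
    """Build the bipartite network from a weighted participant x factor matrix.

    One edge per strictly positive cell.  All-zero rows (participants
    expressing no factor) are excluded and reported, because a zero-strength
    node has no defined place in the configuration-model null.

    Raises
    ------
    ValueError
        If the matrix has no positive cell.
    """
    mat = weighted.to_numpy(dtype=float)
    if mat.size == 0 or not (mat > 0).any():
        raise ValueError("cannot build a network from an all-zero matrix")
    if (mat < 0).any():
        raise ValueError("edge weights must be nonnegative")
    keep = mat.sum(axis=1) > 0
    excluded = list(weighted.index[~keep])
    return BipartiteNetwork(
        participant_ids=np.asarray(weighted.index[keep]),
        factor_ids=np.asarray(weighted.columns),
        matrix=mat[keep],
        excluded_participants=excluded,
    )


def _coerce_labels(network: BipartiteNetwork, labels) -> tuple[np.ndarray, np.ndarray]:
    """Accept a node->label mapping or a (participant, factor) array pair."""
    if isinstance(labels, Mapping):
        try:
            pl = np.array([labels[p] for p in network.participant_ids])
            fl = np.array([labels[f] for f in network.factor_ids])
        except KeyError as err:
            raise ValueError(f"node {err.args[0]!r} is unlabeled") from err
    else:
        pl, fl = (np.asarray(a) for a in labels)
        if pl.shape[0] != network.n_participants or fl.shape[0] != network.n_factors:
            raise ValueError("label arrays do not cover all network nodes")
    return pl, fl


def _modularity_arrays(
    A: np.ndarray, k: np.ndarray, d: np.ndarray, m: float, pl: np.ndarray, fl: np.ndarray
) -> float:
    labels = np.union1d(np.unique(pl), np.unique(fl))
    q = 0.0
    for c in labels:
        pm = pl == c
        fm = fl == c
        if not (pm.any() and fm.any()):
            continue  # one-type clusters contribute nothing
        within = A[np.ix_(pm, fm)].sum()
        q += within - k[pm].sum() * d[fm].sum() / m
    return q / m


def barber_modularity(network: BipartiteNetwork, labels) -> float:
    """Barber bipartite modularity Q of a joint node labeling.

    ``labels`` may be a mapping from every node id to a cluster label, or a
    pair of arrays (participant labels, factor labels) aligned with the
    network's node order.  The sum runs over all participant-factor pairs,
    counting non-edges with A_ij = 0.
    """
    pl, fl = _coerce_labels(network, labels)
    return _modularity_arrays(
        network.matrix,
        network.participant_strengths,
        network.factor_strengths,
        network.total_weight,
        pl,
        fl,
    )


def _brim_once(
    A: np.ndarray,
    k: np.ndarray,
    d: np.ndarray,
    m: float,
    f_init: np.ndarray,
    max_sweeps: int = 200,
) -> tuple[np.ndarray, np.ndarray, float]:
    """One alternating ascent from an initial factor labeling.

    Labels live in a fixed space 0..K-1 with K = d + 2 slots; empty slots act
    as singleton refuges (joining an empty cluster contributes zero, exactly
    like standing alone).  Each half-sweep maximizes Q over one side's labels
    in closed form, so Q is monotone non-decreasing across sweeps.
    """
    n, dn = A.shape
    K = dn + 2
    fl = f_init.copy()
    pl = np.zeros(n, dtype=np.intp)
    q = -np.inf
    eye = np.eye(K)
    for _ in range(max_sweeps):
        # participants given factor labels
        T = eye[fl]  # (dn, K)
        D = T.T @ d
        score_p = A @ T - np.outer(k, D) / m
        pl = np.argmax(score_p, axis=1)
        # factors given participant labels
        R = eye[pl]
        Kc = R.T @ k
        score_f = A.T @ R - np.outer(d, Kc) / m
        fl = np.argmax(score_f, axis=1)
        q_new = float(np.take_along_axis(score_f, fl[:, None], axis=1).sum() / m)
        if not q_new >= q - 1e-9:  # pragma: no cover - ascent guarantee
            raise AssertionError("modularity decreased during refinement sweep")
        if q_new - q < 1e-12:
            q = q_new
            break
        q = q_new
    return pl, fl, q


def _canonical_relabel(pl: np.ndarray, fl: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Relabel clusters 1..K by first appearance (participants, then factors)."""
    order: dict[int, int] = {}
    for lab in list(pl) + list(fl):
        if lab not in order:
            order[lab] = len(order) + 1
    return (
        np.array([order[v] for v in pl], dtype=int),
        np.array([order[v] for v in fl], dtype=int),
    )


def _merge_single_type_clusters(
    A: np.ndarray, k: np.ndarray, d: np.ndarray, m: float, pl: np.ndarray, fl: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Fold clusters containing only one node type into the neighbor that
    maximizes Q, repeating until every remaining cluster is mixed."""
    pl = pl.copy()
    fl = fl.copy()
    while True:
        labels = sorted(set(pl.tolist()) | set(fl.tolist()))
        if len(labels) <= 1:
            break
        single = [
            c
            for c in labels
            if not ((pl == c).any() and (fl == c).any())
        ]
        if not single:
            break
        s = single[0]
        ps, fs = pl == s, fl == s
        Ks, Ds = k[ps].sum(), d[fs].sum()
        best_c, best_dq = None, -np.inf
        for c in labels:
            if c == s:
                continue
            pc, fc = pl == c, fl == c
            dq = (
                A[np.ix_(ps, fc)].sum()
                + A[np.ix_(pc, fs)].sum()
                - (Ks * d[fc].sum() + k[pc].sum() * Ds) / m
            ) / m
            if dq > best_dq:
                best_c, best_dq = c, dq
        pl[ps] = best_c
        fl[fs] = best_c
    return pl, fl


def maximize_modularity(
    network: BipartiteNetwork,
    n_restarts: int = 20,
    seed: int | None = None,
    merge_single_type: bool = True,
) -> BiclusterSolution:
    """Find a high-modularity bicluster assignment by multi-restart ascent.

    The number of clusters K is discovered, not prescribed: restarts seed the
    factor side with 1..d initial groups (cycling), each followed by
    alternating closed-form half-sweeps to a local optimum.  The best solution
    over restarts is returned; with ``merge_single_type`` (default), clusters
    that ended up containing only participants or only factors are folded into
    the neighboring cluster that maximizes Q, so that reported biclusters are
    genuinely mixed.  Deterministic given ``seed``.
    """
    A = network.matrix
    k = network.participant_strengths
    d = network.factor_strengths
    m = network.total_weight
    dn = network.n_factors
    rng = np.random.default_rng(seed)

    best = None
    for r in range(max(1, n_restarts)):
        K0 = (r % dn) + 1
        if r == 0:
            f_init = np.zeros(dn, dtype=np.intp)  # all-in-one start
        elif r == 1 and dn > 1:
            f_init = np.arange(dn, dtype=np.intp)  # all-singletons start
        else:
            f_init = rng.integers(0, K0, size=dn).astype(np.intp)
        pl, fl, q = _brim_once(A, k, d, m, f_init)
        if best is None or q > best[2] + 1e-12:
            best = (pl, fl, q)
    pl, fl, q = best
    if merge_single_type:
        pl, fl = _merge_single_type_clusters(A, k, d, m, pl, fl)
        q = _modularity_arrays(A, k, d, m, pl, fl)
    pl, fl = _canonical_relabel(pl, fl)
    return BiclusterSolution(
        participant_ids=network.participant_ids,
        factor_ids=network.factor_ids,
        participant_labels=pl,
        factor_labels=fl,
        modularity=float(q),
    )


def _restricted_growth_strings(n: int):
    """Yield every set partition of n items as a label vector (RGS order)."""
    a = [0] * n
    while True:
        yield np.array(a, dtype=np.intp)
        # rightmost position that can still be incremented: a[i] <= max(a[:i])
        i = n - 1
        while i > 0 and a[i] > max(a[:i]):
            i -= 1
        if i == 0:
            return
        a[i] += 1
        for j in range(i + 1, n):
            a[j] = 0


def brute_force_partition(
    network: BipartiteNetwork, mixed_only: bool = False
) -> BiclusterSolution:
    """Exact maximum-modularity partition by exhaustive enumeration.

    Enumerates every set partition of the node set (participants + factors)
    and returns the one with the largest Q; intended as a testing oracle and
    limited to at most 12 nodes.  With ``mixed_only`` the search is restricted
    to partitions in which every cluster contains both node types, i.e. the
    solution space of finalized bicluster assignments.
    """
    n_p = network.n_participants
    n_f = network.n_factors
    n = n_p + n_f
    if n > 12:
        raise ValueError(f"brute force limited to 12 nodes, got {n}")
    A = network.matrix
    k = network.participant_strengths
    d = network.factor_strengths
    m = network.total_weight

    L = np.array(list(_restricted_growth_strings(n)), dtype=np.intp)
    q = np.zeros(L.shape[0])
    for i in range(n_p):
        for j in range(n_f):
            coeff = A[i, j] - k[i] * d[j] / m
            if coeff != 0.0:
                q += coeff * (L[:, i] == L[:, n_p + j])
    q /= m
    if mixed_only:
        bad = np.zeros(L.shape[0], dtype=bool)
        for c in range(n):
            p_has = (L[:, :n_p] == c).any(axis=1)
            f_has = (L[:, n_p:] == c).any(axis=1)
            bad |= p_has ^ f_has
        q = np.where(bad, -np.inf, q)
    idx = int(np.argmax(q))
    pl, fl = _canonical_relabel(L[idx, :n_p], L[idx, n_p:])
    return BiclusterSolution(
        participant_ids=network.participant_ids,
        factor_ids=network.factor_ids,
        participant_labels=pl,
        factor_labels=fl,
        modularity=float(q[idx]),
    )
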