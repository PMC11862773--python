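"""Permutation significance of biclustering and split-sample replication.

Two permutation machines:

* significance of Q — the observed modularity is compared against the same
  statistic on B networks in which every participant's weight row (including
  zeros) is independently shuffled across the factor slots.  This preserves
  network size, each participant's weighted-edge multiset (hence every k_i
  and m) while destroying factor co-occurrence structure.  The empirical p
  applies the usual "+1" rule, so p >= 1/(B+1).

* replication — the cohort is split into training and replication halves;
  each is clustered and the agreement between the two *factor* partitions is
  measured with the Rand index.  Its null re-clusters row-permuted copies of
  both halves, so the comparison is optimized-vs-optimized throughout.

The Rand index is computed on factor nodes only: the participant sets of the
two halves are disjoint, so factor co-clustering is the only well-defined
comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import rand_score

from .bipartite import BiclusterSolution, BipartiteNetwork, build_network, maximize_modularity

__all__ = [
    "SignificanceResult",
    "ReplicationResult",
    "permute_network",
    "significance_of_Q",
    "split_cohort",
    "factor_rand_index",
    "replication_test",
]


@dataclass
class SignificanceResult:
    """Observed statistic against its permutation null."""

    observed: float
    null_mean: float
    null_sd: float
    z_score: float
    p_value: float
    B: int
    null_values: np.ndarray = field(repr=False, default=None)


@dataclass
class ReplicationResult:
    """Split-sample factor-partition agreement against its permutation null."""

    rand_index: float
    null_mean: float
    p_value: float
    B: int
    train_solution: BiclusterSolution
    replication_solution: BiclusterSolution
    null_values: np.ndarray = field(repr=False, default=None)


def _permute_rows(matrix: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Independently permute each row across the factor slots."""
    order = np.argsort(rng.random(matrix.shape), axis=1)
    return np.take_along_axis(matrix, order, axis=1)


def permute_network(network: BipartiteNetwork, rng: np.random.Generator) -> BipartiteNetwork:
    """Null network: each participant's weight row shuffled across factors.

    Node sets are unchanged and each participant's weight multiset (hence
    k_i and m) is preserved exactly; factor strengths are not.
    """
    return BipartiteNetwork(
        participant_ids=network.participant_ids,
        factor_ids=network.factor_ids,
        matrix=_permute_rows(network.matrix, rng),
        excluded_participants=list(network.excluded_participants),
    )


def _empirical_p(null: np.ndarray, observed: float) -> float:
    return float((1 + int((null >= observed - 1e-12).sum())) / (1 + len(null)))


def significance_of_Q(
    network: BipartiteNetwork,
    B: int = 1000,
    n_restarts: int = 20,
    seed: int | None = None,
) -> SignificanceResult:
    """Permutation test of bicluster modularity.

    The maximizer is re-run on each permuted network with the same restart
    budget as the observed fit, so observed and null statistics are both
    optimized quantities.  z uses the sample SD of the null (ddof=1).
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(seed)
    fit_seeds = rng.integers(0, 2**31 - 1, size=B + 1)
    observed = maximize_modularity(network, n_restarts=n_restarts, seed=int(fit_seeds[0])).modularity
    null = np.empty(B)
    for b in range(B):
        perm = permute_network(network, rng)
        null[b] = maximize_modularity(
            perm, n_restarts=n_restarts, seed=int(fit_seeds[b + 1])
        ).modularity
    mean = float(null.mean())
    sd = float(null.std(ddof=1)) if B > 1 else 0.0
    if sd == 0.0:
        warnings.warn("null distribution of Q is degenerate; z reported as inf", stacklevel=2)
        z = np.inf if observed > mean else -np.inf if observed < mean else 0.0
    else:
        z = (observed - mean) / sd
    return SignificanceResult(
        observed=observed,
        null_mean=mean,
        null_sd=sd,
        z_score=float(z),
        p_value=_empirical_p(null, observed),
        B=B,
        null_values=null,
    )


def split_cohort(
    matrix: pd.DataFrame, fraction: float = 0.5, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Random participant split into training and replication matrices.

    Disjoint and exhaustive; deterministic given seed.  Raises if either
    side would be empty.
    """
    n = len(matrix)
    n_train = int(round(n * fraction))
    if n_train < 1 or n - n_train < 1:
        raise ValueError(f"split fraction {fraction} leaves an empty side for n={n}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    train = matrix.iloc[np.sort(order[:n_train])]
    repl = matrix.iloc[np.sort(order[n_train:])]
    return train, repl


def factor_rand_index(a: BiclusterSolution, b: BiclusterSolution) -> float:
    """Rand index between the factor partitions of two bicluster solutions.

    Fraction of factor pairs on which the two partitions agree (co-clustered
    in both or separated in both).  Both solutions must label the same
    factor set.
    """
    fa = pd.Series(a.factor_labels, index=a.factor_ids)
    fb = pd.Series(b.factor_labels, index=b.factor_ids)
    if set(fa.index) != set(fb.index):
        raise ValueError("solutions label different factor sets")
    fb = fb.loc[fa.index]
    return float(rand_score(fa.to_numpy(), fb.to_numpy()))


def replication_test(
    train_matrix: pd.DataFrame,
    replication_matrix: pd.DataFrame,
    B: int = 1000,
    n_restarts: int = 20,
    seed: int | None = None,
) -> ReplicationResult:
    """Split-sample replication of factor co-clustering.

    Both matrices are clustered and compared by the factor Rand index; the
    null re-clusters independently row-permuted copies of both matrices B
    times.  p applies the "+1" rule.
    """
    if list(train_matrix.columns) != list(replication_matrix.columns):
        raise ValueError("train and replication matrices must share factor ids")
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(seed)
    fit_seeds = rng.integers(0, 2**31 - 1, size=2 * (B + 1))

    def _cluster(mat: pd.DataFrame, s: int) -> BiclusterSolution:
        return maximize_modularity(build_network(mat), n_restarts=n_restarts, seed=s)

    train_sol = _cluster(train_matrix, int(fit_seeds[0]))
    repl_sol = _cluster(replication_matrix, int(fit_seeds[1]))
    observed = factor_rand_index(train_sol, repl_sol)

    t_arr = train_matrix.to_numpy(dtype=float)
    r_arr = replication_matrix.to_numpy(dtype=float)
    null = np.empty(B)
    for b in range(B):
        t_perm = pd.DataFrame(
            _permute_rows(t_arr, rng), index=train_matrix.index, columns=train_matrix.columns
        )
        r_perm = pd.DataFrame(
            _permute_rows(r_arr, rng),
            index=replication_matrix.index,
            columns=replication_matrix.columns,
        )
        null[b] = factor_rand_index(
            _cluster(t_perm, int(fit_seeds[2 * b + 2])),
            _cluster(r_perm, int(fit_seeds[2 * b + 3])),
        )
    return ReplicationResult(
        rand_index=observed,
        null_mean=float(null.mean()),
        p_value=_empirical_p(null, observed),
        B=B,
        train_solution=train_sol,
        replication_solution=repl_sol,
        null_values=null,
    )
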