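import numpy as np
import pandas as pd
import pytest

from sdoh_subtyper import bipartite as bp


@pytest.fixture
def two_components():
    """Two disconnected complete K2,2 blocks with unit weights."""
    mat = np.zeros((4, 4))
    mat[:2, :2] = 1.0
    mat[2:, 2:] = 1.0
    df = pd.DataFrame(
        mat, index=[f"p{i}" for i in range(4)], columns=[f"f{j}" for j in range(4)]
    )
    return bp.build_network(df)


@pytest.fixture
def k22():
    """Single complete K2,2 with unit weights."""
    df = pd.DataFrame(np.ones((2, 2)), index=["p1", "p2"], columns=["f1", "f2"])
    return bp.build_network(df)


def random_network(rng, n_p=None, n_f=None, density=0.6):
    """Random small weighted bipartite network (every participant connected)."""
    n_p = n_p if n_p is not None else int(rng.integers(2, 6))
    n_f = n_f if n_f is not None else int(rng.integers(2, 6))
    mat = np.where(rng.random((n_p, n_f)) < density, rng.uniform(0.1, 1.0, (n_p, n_f)), 0.0)
    for i in np.where(mat.sum(axis=1) == 0)[0]:
        mat[i, rng.integers(0, n_f)] = rng.uniform(0.1, 1.0)
    df = pd.DataFrame(
        mat, index=[f"p{i}" for i in range(n_p)], columns=[f"f{j}" for j in range(n_f)]
    )
    return bp.build_network(df)


def planted_matrix(rng, n=500, p_in=0.9, p_out=0.05, blocks=(5, 5, 4, 4)):
    """Binary planted-bicluster participant x factor matrix plus truths."""
    f2c = np.repeat(np.arange(1, len(blocks) + 1), blocks)
    pc = rng.integers(1, len(blocks) + 1, size=n)
    P = np.where(f2c[None, :] == pc[:, None], p_in, p_out)
    mat = (rng.random((n, len(f2c))) < P).astype(float)
    df = pd.DataFrame(
        mat,
        index=[f"p{i}" for i in range(n)],
        columns=[f"f{j}" for j in range(len(f2c))],
    )
    return df, pc, f2c
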