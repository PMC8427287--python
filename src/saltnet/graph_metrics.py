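"""Node centrality surfaces: degree, clustering coefficients, weighted degree.

Two local-density measures are computed per node. The binary (small-world)
clustering coefficient is

    C(i) = sum_j sum_{q != j} a_ij * a_iq * a_jq / (k_i (k_i - 1)),

the fraction of realized links among node i's neighbors; the ordered
double sum counts each neighbor pair twice, which the denominator
k_i (k_i - 1) matches, so C(i) lies in [0, 1]. Its weighted (geometric
mean) generalization is

    C_w(i) = sum_j sum_{q != j} |w_ij * w_iq * w_jq|^(1/3) / (k_i (k_i - 1)),

where k_i counts neighbors with nonzero weight; with all edge weights in
[0, 1] it also lies in [0, 1], and with all-unit weights it reduces
exactly to C(i). Both coefficients are defined as 0 for nodes of degree
less than 2, where the denominator degenerates. Weighted degree is the
plain sum of a node's edge weights.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io_formats import ContractError, SaltnetError
from .network_builder import StateNetwork


class DomainError(SaltnetError):
    """A metric's numeric preconditions are violated (e.g. a weight > 1)."""


# ---------------------------------------------------------------------------
# whole-network (vectorized) surfaces
# ---------------------------------------------------------------------------


def degree_all(net: StateNetwork) -> np.ndarray:
    """Binary degree of every node, in panel order."""
    return net.binary_adjacency.sum(axis=1).astype(np.int64)


def clustering_coefficient_all(net: StateNetwork) -> np.ndarray:
    """Binary clustering coefficient of every node, in panel order.

    The ordered double sum over neighbor pairs (j, q) equals the diagonal
    of A^3, computed here as the row sums of (A @ A) * A.
    """
    A = net.binary_adjacency.astype(np.float64)  # float matmul; counts stay exact
    k = A.sum(axis=1)
    closed = ((A @ A) * A).sum(axis=1)  # = diag(A^3)
    out = np.zeros(len(k), dtype=float)
    valid = k >= 2
    out[valid] = closed[valid] / (k[valid] * (k[valid] - 1))
    return out


def weighted_degree_all(net: StateNetwork) -> np.ndarray:
    """Sum of edge weights per node, in panel order."""
    return net.weighted_adjacency.sum(axis=1)


def weighted_clustering_coefficient_all(net: StateNetwork) -> np.ndarray:
    """Geometric-mean weighted clustering coefficient per node.

    Requires every |weight| <= 1 (absolute correlations guarantee this
    upstream); otherwise the coefficient's [0, 1] range would not hold.
    """
    W = np.abs(net.weighted_adjacency.astype(float))
    if (W > 1 + 1e-12).any():
        raise DomainError("edge weights must satisfy |w| <= 1")
    W13 = np.cbrt(W)
    k = (W != 0).sum(axis=1)
    closed = ((W13 @ W13) * W13).sum(axis=1)  # = diag(W13^3)
    out = np.zeros(len(k), dtype=float)
    valid = k >= 2
    out[valid] = closed[valid] / (k[valid] * (k[valid] - 1))
    return out


# ---------------------------------------------------------------------------
# single-node accessors
# ---------------------------------------------------------------------------


def degree(net: StateNetwork, gene: str) -> int:
    """Number of neighbors of ``gene`` in the binary network."""
    return int(net.binary_adjacency[net.index_of(gene)].sum())


def clustering_coefficient(net: StateNetwork, gene: str) -> float:
    """Binary clustering coefficient of ``gene`` (0 when degree < 2)."""
    i = net.index_of(gene)
    A = net.binary_adjacency
    neighbors = np.flatnonzero(A[i])
    k = len(neighbors)
    if k < 2:
        return 0.0
    links_twice = int(A[np.ix_(neighbors, neighbors)].sum())
    return links_twice / (k * (k - 1))


def weighted_degree(net: StateNetwork, gene: str) -> float:
    """Sum of the weights of ``gene``'s edges."""
    return float(net.weighted_adjacency[net.index_of(gene)].sum())


def weighted_clustering_coefficient(net: StateNetwork, gene: str) -> float:
    """Geometric-mean weighted clustering coefficient of ``gene``."""
    i = net.index_of(gene)
    W = np.abs(net.weighted_adjacency.astype(float))
    if (W[i] > 1 + 1e-12).any():
        raise DomainError("edge weights must satisfy |w| <= 1")
    neighbors = np.flatnonzero(W[i])
    k = len(neighbors)
    if k < 2:
        return 0.0
    sub = W[np.ix_(neighbors, neighbors)]
    if (sub > 1 + 1e-12).any():
        raise DomainError("edge weights must satisfy |w| <= 1")
    wi = W[i, neighbors]
    total = float(np.cbrt(np.outer(wi, wi) * sub).sum())  # diag of sub is 0
    return total / (k * (k - 1))


# ---------------------------------------------------------------------------
# metrics table
# ---------------------------------------------------------------------------

METRIC_TABLE_COLUMNS = ("gene_id", "state", "degree", "cc", "wdegree", "wcc")


def compute_metrics_table(normal: StateNetwork, stress: StateNetwork) -> pd.DataFrame:
    """All four node metrics for both states, one row per gene per state.

    Both networks must share one gene panel. Rows are ordered by state
    (normal first) then panel order, so the table is deterministic.
    """
    if normal.gene_ids != stress.gene_ids:
        raise ContractError("normal and stress networks have different gene panels")
    frames = []
    for net in (normal, stress):
        frames.append(
            pd.DataFrame(
                {
                    "gene_id": net.gene_ids,
                    "state": net.state,
                    "degree": degree_all(net),
                    "cc": clustering_coefficient_all(net),
                    "wdegree": weighted_degree_all(net),
                    "wcc": weighted_clustering_coefficient_all(net),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def write_metrics_table(metrics: pd.DataFrame, path) -> None:
    metrics.to_csv(path, sep="\t", index=False, columns=list(METRIC_TABLE_COLUMNS))


def read_metrics_table(path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "state": str})
    missing = set(METRIC_TABLE_COLUMNS) - set(frame.columns)
    if missing:
        raise ContractError(f"metrics table missing columns {sorted(missing)}")
    return frame
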