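"""Per-state co-expression networks from Pearson correlations.

For each condition the pairwise Pearson correlation r is computed over
that condition's samples only. The binary network places an edge wherever
r >= threshold (signed mode, the default, matching the printed edge rule)
or |r| >= threshold (absolute mode); the weighted network carries |r| as
edge weight. By default only supra-threshold edges keep their weight, so
the binary and weighted graphs share one topology; a dense-weights option
instead keeps every |r| as a weight.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import ContractError, ExpressionMatrix, SaltnetError

logger = logging.getLogger(__name__)

EDGE_MODES = ("signed", "absolute")


class InsufficientDataError(SaltnetError):
    """Too few samples to estimate correlations."""


@dataclass
class CorrelationMatrix:
    """Symmetric gene-gene Pearson correlations for one condition.

    Zero-variance genes carry r = 0 against every partner (including the
    diagonal) and are flagged in the log; all other diagonal entries are
    exactly 1.
    """

    gene_ids: list[str]
    r_values: np.ndarray
    n_samples: int


@dataclass
class StateNetwork:
    """One condition's co-expression graph: binary and weighted adjacency.

    ``binary_adjacency`` is a symmetric 0/1 matrix with zero diagonal;
    ``weighted_adjacency`` holds edge weights in [0, 1] (absolute
    correlations), also symmetric with zero diagonal. Wherever a binary
    edge exists the corresponding weight is positive.
    """

    state: str
    gene_ids: list[str]
    binary_adjacency: np.ndarray
    weighted_adjacency: np.ndarray
    edge_threshold: float

    def index_of(self, gene: str) -> int:
        try:
            return self.gene_ids.index(gene)
        except ValueError:
            raise KeyError(f"gene {gene!r} not in network") from None

    @property
    def n_edges(self) -> int:
        return int(self.binary_adjacency.sum()) // 2


def pearson_correlation_matrix(expr: ExpressionMatrix, state: str) -> CorrelationMatrix:
    """Pairwise Pearson r over the samples carrying ``state``.

    Requires at least 3 samples in the state. Genes with zero variance
    across those samples get r = 0 against all partners.
    """
    samples = expr.samples_in_state(state)
    if len(samples) < 3:
        raise InsufficientDataError(
            f"state {state!r} has {len(samples)} sample(s); need at least 3"
        )
    X = expr.values[samples].to_numpy(dtype=float)
    n_genes = X.shape[0]
    if n_genes == 0:
        return CorrelationMatrix([], np.zeros((0, 0)), len(samples))
    sd = X.std(axis=1)
    degenerate = sd == 0
    if degenerate.any():
        logger.warning(
            "state %s: %d zero-variance gene(s) set to r = 0 against all partners",
            state, int(degenerate.sum()),
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(X)
    r = np.atleast_2d(r)
    r[degenerate, :] = 0.0
    r[:, degenerate] = 0.0
    r = np.clip(r, -1.0, 1.0)
    diag = np.where(degenerate, 0.0, 1.0)
    np.fill_diagonal(r, diag)
    return CorrelationMatrix(list(expr.values.index), r, len(samples))


def build_state_network(
    corr: CorrelationMatrix,
    state: str,
    edge_threshold: float = 0.9,
    edge_mode: str = "signed",
    dense_weights: bool = False,
) -> StateNetwork:
    """Threshold a correlation matrix into a binary + weighted network.

    The threshold is inclusive (an edge at exactly r = threshold is kept).
    Signed mode applies the rule to r itself; absolute mode to |r|. The
    weighted adjacency is |r| on supra-threshold edges (or everywhere off
    the diagonal when ``dense_weights`` is set).
    """
    if not (0 < edge_threshold <= 1):
        raise ContractError("edge_threshold must lie in (0, 1]")
    if edge_mode not in EDGE_MODES:
        raise ContractError(f"edge_mode must be one of {EDGE_MODES}")
    r = corr.r_values
    if edge_mode == "signed":
        adjacency = (r >= edge_threshold).astype(np.int8)
    else:
        adjacency = (np.abs(r) >= edge_threshold).astype(np.int8)
    np.fill_diagonal(adjacency, 0)
    if dense_weights:
        weights = np.abs(r).astype(float)
    else:
        weights = np.abs(r) * adjacency
    np.fill_diagonal(weights, 0.0)
    return StateNetwork(
        state=state,
        gene_ids=list(corr.gene_ids),
        binary_adjacency=adjacency,
        weighted_adjacency=weights,
        edge_threshold=edge_threshold,
    )


def build_two_state_networks(
    expr: ExpressionMatrix,
    edge_threshold: float = 0.9,
    edge_mode: str = "signed",
    dense_weights: bool = False,
) -> tuple[StateNetwork, StateNetwork]:
    """Build the normal- and stress-state networks over one gene panel.

    The normal network uses only normal-state samples and the stress
    network only stress-state samples; both share the matrix's gene panel.
    """
    networks = []
    for state in ("normal", "stress"):
        corr = pearson_correlation_matrix(expr, state)
        networks.append(
            build_state_network(corr, state, edge_threshold, edge_mode, dense_weights)
        )
    return networks[0], networks[1]


# ---------------------------------------------------------------------------
# Edge-list serialization
# ---------------------------------------------------------------------------


def write_network(net: StateNetwork, path, corr: CorrelationMatrix | None = None) -> None:
    """Serialize a network as an edge-list TSV plus a ``<path>.nodes`` list.

    Edge rows carry both the signed correlation (when a correlation matrix
    is supplied; otherwise the unsigned weight) and the edge weight. The
    node list keeps isolated genes so the panel survives a round trip.
    """
    path = Path(path)
    gene_ids = net.gene_ids
    rows = []
    upper = np.triu(net.binary_adjacency, k=1)
    for i, j in zip(*np.nonzero(upper)):
        r = corr.r_values[i, j] if corr is not None else net.weighted_adjacency[i, j]
        rows.append(
            (gene_ids[i], gene_ids[j], f"{r:.10g}", f"{net.weighted_adjacency[i, j]:.10g}")
        )
    pd.DataFrame(rows, columns=["gene_a", "gene_b", "r", "weight"]).to_csv(
        path, sep="\t", index=False
    )
    with open(path.with_suffix(path.suffix + ".nodes"), "w") as handle:
        handle.write("gene_id\tstate\tedge_threshold\n")
        for gene in gene_ids:
            handle.write(f"{gene}\t{net.state}\t{net.edge_threshold:.10g}\n")


def read_network(path) -> StateNetwork:
    """Rebuild a StateNetwork from :func:`write_network` output."""
    path = Path(path)
    nodes = pd.read_csv(path.with_suffix(path.suffix + ".nodes"), sep="\t", dtype=str)
    gene_ids = list(nodes["gene_id"])
    state = nodes["state"].iloc[0] if len(nodes) else "normal"
    threshold = float(nodes["edge_threshold"].iloc[0]) if len(nodes) else 0.9
    index = {g: i for i, g in enumerate(gene_ids)}
    n = len(gene_ids)
    adjacency = np.zeros((n, n), dtype=np.int8)
    weights = np.zeros((n, n), dtype=float)
    edges = pd.read_csv(path, sep="\t", dtype={"gene_a": str, "gene_b": str})
    for row in edges.itertuples():
        i, j = index[row.gene_a], index[row.gene_b]
        adjacency[i, j] = adjacency[j, i] = 1
        weights[i, j] = weights[j, i] = float(row.weight)
    return StateNetwork(state, gene_ids, adjacency, weights, threshold)
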