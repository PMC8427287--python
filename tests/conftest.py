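"""Shared fixtures: small networks, oracle helpers, synthetic configs."""

from __future__ import annotations

import numpy as np
import pytest

from saltnet.network_builder import StateNetwork
from saltnet.synthetic_data import SimulationConfig


def network_from_edges(nodes, edges, state="stress", weights=None, threshold=0.9):
    """Build a StateNetwork from an explicit node and edge list.

    ``weights`` maps an edge tuple to its weight; unweighted edges get 1.
    """
    index = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    adjacency = np.zeros((n, n), dtype=np.int8)
    weight_matrix = np.zeros((n, n), dtype=float)
    for edge in edges:
        a, b = edge
        i, j = index[a], index[b]
        w = 1.0 if weights is None else weights.get(edge, weights.get((b, a), 1.0))
        adjacency[i, j] = adjacency[j, i] = 1
        weight_matrix[i, j] = weight_matrix[j, i] = w
    return StateNetwork(state, list(nodes), adjacency, weight_matrix, threshold)


def random_binary_network(rng, n_nodes, p=0.3, state="stress"):
    nodes = [f"n{i:02d}" for i in range(n_nodes)]
    upper = rng.random((n_nodes, n_nodes)) < p
    adjacency = np.triu(upper, k=1)
    adjacency = (adjacency | adjacency.T).astype(np.int8)
    return StateNetwork(state, nodes, adjacency, adjacency.astype(float), 0.9)


def random_weighted_network(rng, n_nodes, p=0.4, state="stress"):
    net = random_binary_network(rng, n_nodes, p, state)
    weights = rng.uniform(0.05, 1.0, size=net.weighted_adjacency.shape)
    weights = np.triu(weights, k=1)
    weights = (weights + weights.T) * net.binary_adjacency
    net.weighted_adjacency = weights
    return net


# --- independent brute-force oracles (never share code with the package) ---


def brute_force_cc(net: StateNetwork, node: str) -> float:
    """Ordered triple enumeration of the binary clustering coefficient."""
    A = net.binary_adjacency
    i = net.gene_ids.index(node)
    neighbors = [j for j in range(len(net.gene_ids)) if A[i, j]]
    k = len(neighbors)
    if k < 2:
        return 0.0
    total = 0
    for j in neighbors:
        for q in neighbors:
            if q != j and A[j, q]:
                total += 1
    return total / (k * (k - 1))


def brute_force_wcc(net: StateNetwork, node: str) -> float:
    """Ordered triple enumeration of the geometric-mean weighted coefficient."""
    W = np.abs(net.weighted_adjacency)
    i = net.gene_ids.index(node)
    neighbors = [j for j in range(len(net.gene_ids)) if W[i, j] != 0]
    k = len(neighbors)
    if k < 2:
        return 0.0
    total = 0.0
    for j in neighbors:
        for q in neighbors:
            if q != j:
                total += (W[i, j] * W[i, q] * W[j, q]) ** (1.0 / 3.0)
    return total / (k * (k - 1))


@pytest.fixture
def worked_example_network():
    """The three-hub illustration graph: G1 and G3 each with four mutually
    unconnected neighbors, G2 with six neighbors exactly one pair of which
    is linked (so C(G2) = 1/15), embedded among thirteen background genes."""
    nodes = ["G1", "G2", "G3"] + [f"n{i:02d}" for i in range(1, 14)]
    edges = [
        ("G2", "G1"), ("G2", "G3"),
        ("G2", "n01"), ("G2", "n02"), ("G2", "n03"), ("G2", "n04"),
        ("n01", "n02"),  # the single link among G2's neighbors
        ("G1", "n05"), ("G1", "n06"), ("G1", "n07"),
        ("G3", "n08"), ("G3", "n09"), ("G3", "n10"),
        ("n11", "n12"),
    ]
    return network_from_edges(nodes, edges)


@pytest.fixture
def small_sim_config():
    """A desk-scale simulation: 80 genes, four 10-gene modules, 10 planted."""
    return SimulationConfig(
        n_genes=80, n_samples_per_state=20, n_modules=4, module_size=10,
        n_planted=10, seed=7,
    )
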