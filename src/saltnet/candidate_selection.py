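"""Differential (stress-high / normal-low) candidate selection.

Each of the three methods reads one centrality surface off the node
metrics table — GCN the binary degree, CC the clustering coefficient,
WGCN the weighted degree (with the weighted clustering coefficient
available as an alternative ranking key) — and keeps genes whose value is
high under stress and low under normal. Three explicit parameterizations
of "high"/"low" are offered:

percentile (default)
    stress value >= the ``stress_min_percentile`` of the stress-state
    distribution AND normal value <= the ``normal_max_percentile`` of the
    normal-state distribution (defaults 90 / 50).
threshold
    absolute cutoffs ``stress_min_value`` / ``normal_max_value``.
top_k
    the k largest stress-minus-normal differences, ties broken by
    lexicographic gene id.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import ContractError

METHODS = ("gcn_degree", "cc", "wgcn")
MODES = ("percentile", "threshold", "top_k")

_SURFACE = {"gcn_degree": "degree", "cc": "cc", "wgcn": "wdegree"}


@dataclass(frozen=True)
class SelectionParams:
    method: str
    mode: str = "percentile"
    stress_min_percentile: float = 90.0
    normal_max_percentile: float = 50.0
    stress_min_value: float | None = None
    normal_max_value: float | None = None
    k: int | None = None
    rank_weighted_cc: bool = False  # WGCN ranks on wcc instead of wdegree

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ContractError(f"method must be one of {METHODS}")
        if self.mode not in MODES:
            raise ContractError(f"mode must be one of {MODES}")
        if self.mode == "percentile":
            for name in ("stress_min_percentile", "normal_max_percentile"):
                value = getattr(self, name)
                if not (0 < value < 100):
                    raise ContractError(f"{name} must lie in (0, 100)")
        elif self.mode == "threshold":
            if self.stress_min_value is None or self.normal_max_value is None:
                raise ContractError("threshold mode needs stress_min_value and normal_max_value")
        else:
            if self.k is None or self.k <= 0:
                raise ContractError("top_k mode needs a positive k")

    @property
    def surface(self) -> str:
        if self.method == "wgcn" and self.rank_weighted_cc:
            return "wcc"
        return _SURFACE[self.method]


@dataclass
class CandidateSets:
    """The three method-specific candidate gene sets."""

    gcn: set[str]
    cc: set[str]
    wgcn: set[str]

    def union(self) -> set[str]:
        return self.gcn | self.cc | self.wgcn


def _paired_surface(metrics: pd.DataFrame, surface: str) -> pd.DataFrame:
    """One row per gene with its normal and stress values of ``surface``."""
    if surface not in metrics.columns:
        raise ContractError(f"metrics table has no column {surface!r}")
    wide = metrics.pivot(index="gene_id", columns="state", values=surface)
    for state in ("normal", "stress"):
        if state not in wide.columns or wide[state].isna().any():
            raise ContractError(f"metrics table lacks {state!r} rows for some genes")
    return wide


def select_differential(metrics: pd.DataFrame, params: SelectionParams) -> set[str]:
    """Apply the stress-high / normal-low rule to one centrality surface.

    Deterministic for a given table and parameters, independent of gene
    ordering.
    """
    if len(metrics) == 0:
        return set()
    wide = _paired_surface(metrics, params.surface)
    stress = wide["stress"].to_numpy(dtype=float)
    normal = wide["normal"].to_numpy(dtype=float)
    genes = np.asarray(wide.index, dtype=object)

    if params.mode == "percentile":
        stress_cut = np.percentile(stress, params.stress_min_percentile)
        normal_cut = np.percentile(normal, params.normal_max_percentile)
        mask = (stress >= stress_cut) & (normal <= normal_cut)
        return set(genes[mask])
    if params.mode == "threshold":
        mask = (stress >= params.stress_min_value) & (normal <= params.normal_max_value)
        return set(genes[mask])
    # top_k on the stress-minus-normal difference, lexicographic tie-break
    if params.k > len(genes):
        raise ContractError(f"k = {params.k} exceeds the {len(genes)}-gene panel")
    diff = stress - normal
    order = sorted(range(len(genes)), key=lambda i: (-diff[i], genes[i]))
    return {genes[i] for i in order[: params.k]}


def select_all_methods(
    metrics: pd.DataFrame,
    gcn_params: SelectionParams | None = None,
    cc_params: SelectionParams | None = None,
    wgcn_params: SelectionParams | None = None,
) -> CandidateSets:
    """Run all three selections; defaults are percentile 90/50 per method."""
    gcn_params = gcn_params or SelectionParams(method="gcn_degree")
    cc_params = cc_params or SelectionParams(method="cc")
    wgcn_params = wgcn_params or SelectionParams(method="wgcn")
    if (gcn_params.method, cc_params.method, wgcn_params.method) != METHODS:
        raise ContractError("params must target gcn_degree, cc and wgcn respectively")
    return CandidateSets(
        gcn=select_differential(metrics, gcn_params),
        cc=select_differential(metrics, cc_params),
        wgcn=select_differential(metrics, wgcn_params),
    )


def write_gene_set(genes: set[str], path) -> None:
    with open(path, "w") as handle:
        for gene in sorted(genes):
            handle.write(gene + "\n")


def read_gene_set(path) -> set[str]:
    with open(path) as handle:
        return {line.strip() for line in handle if line.strip()}
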