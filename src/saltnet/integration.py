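"""Candidate-set integration: Venn partition, SNP filter, QTL-interval filter.

The three method-specific candidate sets are first partitioned into the
seven disjoint Venn regions. Candidates are then intersected with two
independent lines of evidence: presence of at least one sequence variant
between the tolerant and susceptible lines, and location within the
marker-delimited QTL interval. Both filters are pure membership filters,
so their order of application does not matter.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import yaml

from . import candidate_selection as cs
from . import graph_metrics as gm
from . import network_builder as nb
from . import normalization as norm
from .io_formats import (
    VENN_LABELS,
    GeneAnnotation,
    GenomicInterval,
    SaltnetError,
    SNPTable,
    read_expression_matrix,
    read_gene_annotation,
    read_snp_table,
    write_candidates,
    write_expression_matrix,
)

logger = logging.getLogger(__name__)

VENN_REGIONS = tuple(VENN_LABELS.values())


class PipelineError(SaltnetError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class VennPartition:
    """The seven disjoint membership regions of the three candidate sets."""

    regions: dict[str, set[str]]
    union_size: int

    def region_sizes(self) -> dict[str, int]:
        return {label: len(self.regions[label]) for label in VENN_REGIONS}


def venn_partition(sets: cs.CandidateSets) -> VennPartition:
    """Partition the union of the three sets by membership pattern."""
    regions: dict[str, set[str]] = {label: set() for label in VENN_REGIONS}
    union = sets.union()
    for gene in union:
        pattern = (gene in sets.gcn, gene in sets.cc, gene in sets.wgcn)
        regions[VENN_LABELS[pattern]].add(gene)
    return VennPartition(regions=regions, union_size=len(union))


@dataclass
class SnpFilterResult:
    """Candidates surviving the variant-evidence filter."""

    per_method: dict[str, set[str]]  # keys: gcn, cc, wgcn
    combined: set[str]
    region_class_counts: dict[str, int]  # SNP records on surviving genes


def filter_by_snp(
    sets: cs.CandidateSets,
    snps: SNPTable,
    region_classes: tuple[str, ...] | None = None,
) -> SnpFilterResult:
    """Keep candidates carrying at least one SNP record.

    ``region_classes`` optionally restricts the evidence to chosen classes
    (e.g. promoter-only); by default any record counts.
    """
    if region_classes is None:
        usable = snps.records
    else:
        wanted = set(region_classes)
        usable = [rec for rec in snps.records if rec.region_class in wanted]
    evidenced = {rec.gene_id for rec in usable}
    per_method = {
        "gcn": sets.gcn & evidenced,
        "cc": sets.cc & evidenced,
        "wgcn": sets.wgcn & evidenced,
    }
    combined = sets.union() & evidenced
    breakdown: dict[str, int] = {}
    for rec in usable:
        if rec.gene_id in combined:
            breakdown[rec.region_class] = breakdown.get(rec.region_class, 0) + 1
    return SnpFilterResult(per_method=per_method, combined=combined,
                           region_class_counts=breakdown)


def filter_by_interval(
    genes: set[str],
    annotation: GeneAnnotation,
    interval: GenomicInterval,
    containment: bool = False,
) -> set[str]:
    """Keep genes located in the query interval.

    A gene is kept when its annotated interval overlaps the query on the
    same chromosome (half-open overlap: gene.start < q.end and q.start <
    gene.end); with ``containment`` the gene must lie entirely inside.
    Genes absent from the annotation are dropped with a logged warning.
    """
    missing = sorted(g for g in genes if g not in annotation.entries)
    if missing:
        logger.warning("%d gene(s) missing from annotation, dropped: %s",
                       len(missing), ", ".join(missing[:10]))
    kept = set()
    for gene in genes:
        entry = annotation.entries.get(gene)
        if entry is None:
            continue
        chrom, start, end = entry
        if chrom != interval.chromosome:
            continue
        if containment:
            inside = interval.start <= start and end <= interval.end
        else:
            inside = start < interval.end and interval.start < end
        if inside:
            kept.add(gene)
    return kept


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------


def _selection_params(method: str, section: dict) -> cs.SelectionParams:
    return cs.SelectionParams(
        method=method,
        mode=section.get("mode", "percentile"),
        stress_min_percentile=float(section.get("stress_min_percentile", 90.0)),
        normal_max_percentile=float(section.get("normal_max_percentile", 50.0)),
        stress_min_value=section.get("stress_min_value"),
        normal_max_value=section.get("normal_max_value"),
        k=section.get("k"),
        rank_weighted_cc=bool(section.get("rank_weighted_cc", False)),
    )


def run_full_pipeline(config_path) -> dict:
    """Execute normalize -> networks -> metrics -> select x3 -> venn ->
    SNP filter -> interval filter from a YAML config.

    Writes every intermediate table plus a JSON run summary into the
    configured output directory and returns the summary dict. Fully
    deterministic given the inputs. Any stage failure aborts with the
    stage name.
    """
    config_path = Path(config_path)
    with open(config_path) as handle:
        config = yaml.safe_load(handle)

    out_dir = Path(config["out_dir"])
    if not out_dir.is_absolute():
        out_dir = config_path.parent / out_dir
    out_dir.mkdir(parents=True, exist_ok=True)
    inputs = config["inputs"]

    def _resolve(path_str):
        path = Path(path_str)
        return path if path.is_absolute() else config_path.parent / path

    stage = "read inputs"
    try:
        counts = read_expression_matrix(_resolve(inputs["counts"]),
                                        _resolve(inputs["samples"]))
        snps = read_snp_table(_resolve(inputs["snps"]))
        annotation = read_gene_annotation(_resolve(inputs["annotation"]))
        interval_cfg = config["interval"]
        interval = GenomicInterval(
            chromosome=str(interval_cfg["chromosome"]),
            start=int(interval_cfg["start"]),
            end=int(interval_cfg["end"]),
            label=str(interval_cfg.get("label", "")),
        )
        gene_list_path = inputs.get("gene_list")
        if gene_list_path:
            panel = cs.read_gene_set(_resolve(gene_list_path))
            counts = counts.subset_genes(panel)

        stage = "normalization"
        norm_cfg = config.get("normalization", {})
        factors = norm.estimate_size_factors(counts)
        normalized = norm.normalize_and_transform(
            counts, factors, pseudocount=float(norm_cfg.get("pseudocount", 1.0))
        )
        write_expression_matrix(normalized, out_dir / "normalized.tsv",
                                out_dir / "samples.tsv")

        stage = "network construction"
        net_cfg = config.get("network", {})
        threshold = float(net_cfg.get("edge_threshold", 0.9))
        edge_mode = net_cfg.get("edge_mode", "signed")
        dense = bool(net_cfg.get("dense_weights", False))
        networks = {}
        for state in ("normal", "stress"):
            corr = nb.pearson_correlation_matrix(normalized, state)
            net = nb.build_state_network(corr, state, threshold, edge_mode, dense)
            nb.write_network(net, out_dir / f"network_{state}.tsv", corr)
            networks[state] = net

        stage = "node metrics"
        metrics = gm.compute_metrics_table(networks["normal"], networks["stress"])
        gm.write_metrics_table(metrics, out_dir / "metrics.tsv")

        stage = "candidate selection"
        sel_cfg = config.get("selection", {})
        sets = cs.select_all_methods(
            metrics,
            _selection_params("gcn_degree", sel_cfg.get("gcn", sel_cfg)),
            _selection_params("cc", sel_cfg.get("cc", sel_cfg)),
            _selection_params("wgcn", sel_cfg.get("wgcn", sel_cfg)),
        )
        for name, genes in (("gcn", sets.gcn), ("cc", sets.cc), ("wgcn", sets.wgcn)):
            cs.write_gene_set(genes, out_dir / f"candidates_{name}.txt")

        stage = "venn partition"
        venn = venn_partition(sets)
        write_candidates(sets, metrics, out_dir / "candidates.tsv")

        stage = "snp filter"
        snp_cfg = config.get("snp_filter", {})
        classes = snp_cfg.get("region_classes")
        snp_result = filter_by_snp(sets, snps,
                                   tuple(classes) if classes else None)

        stage = "interval filter"
        int_cfg = config.get("interval_filter", {})
        final = filter_by_interval(
            snp_result.combined, annotation, interval,
            containment=bool(int_cfg.get("containment", False)),
        )
        cs.write_gene_set(final, out_dir / "final_candidates.txt")
    except SaltnetError as exc:
        raise PipelineError(f"stage '{stage}' failed: {exc}") from exc

    summary = {
        "parameters": {
            "pseudocount": float(norm_cfg.get("pseudocount", 1.0)),
            "edge_threshold": threshold,
            "edge_mode": edge_mode,
            "dense_weights": dense,
            "selection": {
                m: {
                    "mode": p.mode,
                    "stress_min_percentile": p.stress_min_percentile,
                    "normal_max_percentile": p.normal_max_percentile,
                }
                for m, p in (
                    ("gcn", _selection_params("gcn_degree", sel_cfg.get("gcn", sel_cfg))),
                    ("cc", _selection_params("cc", sel_cfg.get("cc", sel_cfg))),
                    ("wgcn", _selection_params("wgcn", sel_cfg.get("wgcn", sel_cfg))),
                )
            },
            "snp_region_classes": list(classes) if classes else None,
            "interval": {
                "chromosome": interval.chromosome,
                "start": interval.start,
                "end": interval.end,
                "label": interval.label,
            },
        },
        "counts": {
            "genes": len(counts.gene_ids),
            "samples": len(counts.sample_ids),
            "edges_normal": networks["normal"].n_edges,
            "edges_stress": networks["stress"].n_edges,
            "candidates_gcn": len(sets.gcn),
            "candidates_cc": len(sets.cc),
            "candidates_wgcn": len(sets.wgcn),
            "candidates_union": venn.union_size,
            "venn": venn.region_sizes(),
            "snp_filtered_gcn": len(snp_result.per_method["gcn"]),
            "snp_filtered_cc": len(snp_result.per_method["cc"]),
            "snp_filtered_wgcn": len(snp_result.per_method["wgcn"]),
            "snp_filtered_combined": len(snp_result.combined),
            "snp_region_class_counts": dict(sorted(snp_result.region_class_counts.items())),
            "final_in_interval": len(final),
        },
        "final_candidates": sorted(final),
    }
    with open(out_dir / "summary.json", "w") as handle:
        json.dump(summary, handle, indent=2, sort_keys=True)
        handle.write("\n")
    return summary
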