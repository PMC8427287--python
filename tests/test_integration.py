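"""Venn partition, evidence filters and the end-to-end pipeline."""

import json

import numpy as np
import pytest
import yaml
from hypothesis import given, settings, strategies as st

from saltnet.candidate_selection import CandidateSets
from saltnet.integration import (
    PipelineError,
    filter_by_interval,
    filter_by_snp,
    run_full_pipeline,
    venn_partition,
)
from saltnet.io_formats import (
    GeneAnnotation,
    GenomicInterval,
    SNPRecord,
    SNPTable,
    write_expression_matrix,
    write_gene_annotation,
    write_snp_table,
)
from saltnet.synthetic_data import (
    SimulationConfig,
    generate_annotation,
    generate_snp_table,
    generate_two_state_expression,
)

GENE_IDS = st.text(alphabet="abcdefgh", min_size=1, max_size=3)
GENE_SETS = st.sets(GENE_IDS, max_size=12)


class TestVennPartition:
    def test_explicit_enumeration(self):
        sets = CandidateSets(gcn={"a", "b"}, cc={"b", "c"}, wgcn={"c", "d"})
        venn = venn_partition(sets)
        assert venn.regions["gcn_only"] == {"a"}
        assert venn.regions["cc_only"] == set()
        assert venn.regions["wgcn_only"] == {"d"}
        assert venn.regions["gcn_cc"] == {"b"}
        assert venn.regions["cc_wgcn"] == {"c"}
        assert venn.regions["gcn_wgcn"] == set()
        assert venn.regions["all_three"] == set()
        assert venn.union_size == 4

    def test_identical_sets_fall_in_all_three(self):
        genes = {f"g{i}" for i in range(9)}
        venn = venn_partition(CandidateSets(set(genes), set(genes), set(genes)))
        assert venn.regions["all_three"] == genes
        assert venn.union_size == 9
        assert sum(len(r) for label, r in venn.regions.items()
                   if label != "all_three") == 0

    @settings(deadline=None, derandomize=True)
    @given(gcn=GENE_SETS, cc=GENE_SETS, wgcn=GENE_SETS)
    def test_partition_identities(self, gcn, cc, wgcn):
        """Disjointness, union conservation and the inclusion-exclusion
        identities hold for arbitrary candidate sets."""
        sets = CandidateSets(gcn, cc, wgcn)
        venn = venn_partition(sets)
        regions = list(venn.regions.values())
        union = set().union(*regions)
        assert union == gcn | cc | wgcn
        assert sum(len(r) for r in regions) == venn.union_size == len(union)
        for a, b in zip(regions, regions[1:]):
            assert not (a & b)
        assert len(venn.regions["gcn_only"]) == (
            len(gcn) - len(gcn & cc) - len(gcn & wgcn) + len(gcn & cc & wgcn)
        )
        assert len(venn.regions["gcn_cc"]) == len(gcn & cc) - len(gcn & cc & wgcn)


def _snps(genes):
    return SNPTable([SNPRecord(g, 10, "A", "G", "exon") for g in genes])


class TestSnpFilter:
    sets = CandidateSets(gcn={"a", "b"}, cc={"b", "c"}, wgcn={"d"})

    def test_no_snps_empties_everything(self):
        result = filter_by_snp(self.sets, SNPTable([]))
        assert result.combined == set()
        assert all(not s for s in result.per_method.values())

    def test_universal_snps_is_identity(self):
        result = filter_by_snp(self.sets, _snps("abcd"))
        assert result.per_method == {"gcn": {"a", "b"}, "cc": {"b", "c"},
                                     "wgcn": {"d"}}
        assert result.combined == {"a", "b", "c", "d"}

    def test_region_class_restriction(self):
        snps = SNPTable([
            SNPRecord("a", 5, "A", "G", "promoter"),
            SNPRecord("b", 9, "C", "T", "exon"),
        ])
        result = filter_by_snp(self.sets, snps, region_classes=("promoter",))
        assert result.combined == {"a"}
        assert result.region_class_counts == {"promoter": 1}

    def test_filters_are_contractive(self):
        result = filter_by_snp(self.sets, _snps("abq"))
        assert result.combined <= self.sets.union()
        for name, genes in result.per_method.items():
            assert genes <= getattr(self.sets, name)


class TestIntervalFilter:
    interval = GenomicInterval("chr1", 100, 200)
    annotation = GeneAnnotation({
        "overlapping": ("chr1", 150, 250),
        "other_chrom": ("chr2", 150, 250),
        "abutting": ("chr1", 200, 300),
        "inside": ("chr1", 120, 180),
    })

    def test_half_open_overlap_semantics(self):
        kept = filter_by_interval(
            {"overlapping", "other_chrom", "abutting", "inside"},
            self.annotation, self.interval)
        assert kept == {"overlapping", "inside"}

    def test_containment_mode(self):
        kept = filter_by_interval({"overlapping", "inside"}, self.annotation,
                                  self.interval, containment=True)
        assert kept == {"inside"}

    def test_unannotated_genes_dropped(self):
        kept = filter_by_interval({"inside", "ghost"}, self.annotation,
                                  self.interval)
        assert kept == {"inside"}

    def test_snp_and_interval_filters_commute(self):
        rng = np.random.default_rng(13)
        genes = [f"g{i:02d}" for i in range(30)]
        sets = CandidateSets(
            gcn={g for g in genes if rng.random() < 0.5},
            cc={g for g in genes if rng.random() < 0.5},
            wgcn={g for g in genes if rng.random() < 0.5},
        )
        snps = _snps([g for g in genes if rng.random() < 0.5])
        annotation = GeneAnnotation({
            g: ("chr1", int(rng.integers(0, 400)), int(rng.integers(400, 800)))
            for g in genes
        })
        interval = GenomicInterval("chr1", 100, 300)
        snp_then_interval = filter_by_interval(
            filter_by_snp(sets, snps).combined, annotation, interval)
        interval_first = filter_by_interval(sets.union(), annotation, interval)
        interval_then_snp = filter_by_snp(
            CandidateSets(sets.gcn & interval_first, sets.cc & interval_first,
                          sets.wgcn & interval_first),
            snps).combined
        assert snp_then_interval == interval_then_snp


# ---------------------------------------------------------------------------
# end-to-end pipeline
# ---------------------------------------------------------------------------


def _write_dataset(tmp_path, config, snp_table=None, interval_fraction=1.0):
    normal, stress, truth = generate_two_state_expression(config)
    combined = normal.concat_samples(stress)
    write_expression_matrix(combined, tmp_path / "counts.tsv",
                            tmp_path / "samples.tsv")
    snps = snp_table if snp_table is not None else generate_snp_table(
        truth, combined.gene_ids, config)
    write_snp_table(snps, tmp_path / "snps.tsv")
    interval = GenomicInterval("chr1", 0, 10_000_000, label="qtl")
    annotation = generate_annotation(combined.gene_ids, interval, truth,
                                     interval_fraction, config.seed)
    write_gene_annotation(annotation, tmp_path / "genes.bed")
    config_path = tmp_path / "run.yaml"
    config_path.write_text(yaml.safe_dump({
        "out_dir": "out",
        "inputs": {
            "counts": "counts.tsv", "samples": "samples.tsv",
            "snps": "snps.tsv", "annotation": "genes.bed",
        },
        "interval": {"chromosome": "chr1", "start": 0, "end": 10_000_000,
                     "label": "qtl"},
    }))
    return config_path, truth


class TestFullPipeline:
    def test_summary_satisfies_partition_identity(self, tmp_path):
        config = SimulationConfig(n_genes=120, n_samples_per_state=15,
                                  n_modules=4, module_size=10, n_planted=12,
                                  seed=1)
        config_path, _ = _write_dataset(tmp_path, config)
        summary = run_full_pipeline(config_path)
        counts = summary["counts"]
        assert sum(counts["venn"].values()) == counts["candidates_union"]
        assert counts["snp_filtered_combined"] <= counts["candidates_union"]
        assert counts["final_in_interval"] <= counts["snp_filtered_combined"]
        assert (tmp_path / "out" / "metrics.tsv").exists()
        assert (tmp_path / "out" / "candidates.tsv").exists()

    def test_rerun_is_byte_identical(self, tmp_path):
        config = SimulationConfig(n_genes=80, n_samples_per_state=12,
                                  n_modules=3, module_size=8, n_planted=8,
                                  seed=2)
        config_path, _ = _write_dataset(tmp_path, config)
        run_full_pipeline(config_path)
        first = (tmp_path / "out" / "summary.json").read_bytes()
        run_full_pipeline(config_path)
        assert (tmp_path / "out" / "summary.json").read_bytes() == first

    def test_empty_snp_table_completes_with_empty_final_list(self, tmp_path):
        config = SimulationConfig(n_genes=80, n_samples_per_state=12,
                                  n_modules=3, module_size=8, n_planted=8,
                                  seed=3)
        config_path, _ = _write_dataset(tmp_path, config, snp_table=SNPTable([]))
        summary = run_full_pipeline(config_path)
        assert summary["counts"]["snp_filtered_combined"] == 0
        assert summary["final_candidates"] == []

    def test_stage_failure_names_the_stage(self, tmp_path):
        config = SimulationConfig(n_genes=40, n_samples_per_state=12,
                                  n_modules=2, module_size=8, n_planted=4,
                                  seed=4)
        config_path, _ = _write_dataset(tmp_path, config)
        # corrupt the counts so normalization has no reference gene
        counts_path = tmp_path / "counts.tsv"
        lines = counts_path.read_text().splitlines()
        header, rows = lines[0], lines[1:]
        broken = [header]
        for i, row in enumerate(rows):
            fields = row.split("\t")
            fields[1 + i % (len(fields) - 1)] = "0"  # a zero in every gene
            broken.append("\t".join(fields))
        counts_path.write_text("\n".join(broken) + "\n")
        with pytest.raises(PipelineError, match="normalization"):
            run_full_pipeline(config_path)
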