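"""Readers and writers for every on-disk artifact of the pipeline.

All tabular artifacts are tab-separated. Genomic coordinate conventions
follow the named standards: gene annotations and query intervals are
0-based half-open (BED), SNP positions are 1-based (VCF).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd

logger = logging.getLogger(__name__)

STATES = ("normal", "stress")

REGION_CLASSES = (
    "promoter",
    "five_prime_utr",
    "exon",
    "intron",
    "three_prime_utr",
    "unknown",
)

#: The seven disjoint membership regions of three gene sets, keyed by the
#: (in_gcn, in_cc, in_wgcn) membership pattern.
VENN_LABELS: dict[tuple[bool, bool, bool], str] = {
    (True, False, False): "gcn_only",
    (False, True, False): "cc_only",
    (False, False, True): "wgcn_only",
    (True, True, False): "gcn_cc",
    (True, False, True): "gcn_wgcn",
    (False, True, True): "cc_wgcn",
    (True, True, True): "all_three",
}


class SaltnetError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(SaltnetError):
    """An on-disk artifact violates its expected format."""


class ConfigurationError(SaltnetError):
    """A configuration object violates its invariants."""


class ContractError(SaltnetError):
    """Inputs to an operation violate its preconditions."""


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """A genes x samples expression matrix with per-sample metadata.

    Parameters
    ----------
    values
        Numeric DataFrame, one row per gene, one column per sample.
        Values are raw counts or normalized abundances; never negative.
    sample_state
        Maps every sample id to ``"normal"`` or ``"stress"``.
    sample_stage
        Maps every sample id to a free-text tissue/stage label.
    sample_replicate
        Maps every sample id to a positive replicate index.
    """

    values: pd.DataFrame
    sample_state: dict[str, str]
    sample_stage: dict[str, str] = field(default_factory=dict)
    sample_replicate: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        genes = self.values.index
        if genes.has_duplicates:
            dup = genes[genes.duplicated()][0]
            raise FormatError(f"duplicate gene id: {dup!r}")
        for sample in self.values.columns:
            if sample not in self.sample_state:
                raise FormatError(f"sample {sample!r} has no state assignment")
        bad = set(self.sample_state.values()) - set(STATES)
        if bad:
            raise FormatError(
                f"unknown state labels {sorted(bad)}; expected one of {STATES}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_in_state(self, state: str) -> list[str]:
        """Sample ids carrying ``state``, in column order."""
        return [s for s in self.values.columns if self.sample_state[s] == state]

    def subset_genes(self, gene_ids: Iterable[str]) -> "ExpressionMatrix":
        """Restrict to the given genes, preserving their order in the panel."""
        keep = set(gene_ids)
        rows = [g for g in self.values.index if g in keep]
        return ExpressionMatrix(
            self.values.loc[rows],
            dict(self.sample_state),
            dict(self.sample_stage),
            dict(self.sample_replicate),
        )

    def concat_samples(self, other: "ExpressionMatrix") -> "ExpressionMatrix":
        """Join two matrices over the same gene panel, disjoint samples."""
        if list(self.values.index) != list(other.values.index):
            raise ContractError("gene panels differ; cannot concatenate samples")
        overlap = set(self.values.columns) & set(other.values.columns)
        if overlap:
            raise ContractError(f"sample ids shared by both matrices: {sorted(overlap)}")
        return ExpressionMatrix(
            pd.concat([self.values, other.values], axis=1),
            {**self.sample_state, **other.sample_state},
            {**self.sample_stage, **other.sample_stage},
            {**self.sample_replicate, **other.sample_replicate},
        )


def read_expression_matrix(matrix_path, sample_sheet_path) -> ExpressionMatrix:
    """Read a gene x sample TSV plus its sample sheet.

    The matrix file carries a header row of sample ids and a first column of
    gene ids. The sample sheet is a TSV with columns ``sample_id``,
    ``state``, ``stage``, ``replicate``; every matrix column must appear in
    the sheet.
    """
    raw = pd.read_csv(matrix_path, sep="\t", index_col=0, dtype=str)
    raw.index = raw.index.astype(str)
    if raw.index.has_duplicates:
        dup = raw.index[raw.index.duplicated()][0]
        raise FormatError(f"{matrix_path}: duplicate gene id {dup!r}")
    values = raw.apply(pd.to_numeric, errors="coerce")
    bad = values.isna() & raw.notna()
    if bad.to_numpy().any():
        gene = bad.index[bad.any(axis=1)][0]
        sample = bad.columns[bad.loc[gene]][0]
        raise FormatError(
            f"{matrix_path}: non-numeric value {raw.loc[gene, sample]!r} "
            f"at gene {gene!r}, sample {sample!r}"
        )

    sheet = pd.read_csv(sample_sheet_path, sep="\t", dtype=str)
    required = {"sample_id", "state", "stage", "replicate"}
    missing_cols = required - set(sheet.columns)
    if missing_cols:
        raise FormatError(
            f"{sample_sheet_path}: missing columns {sorted(missing_cols)}"
        )
    sheet = sheet.set_index("sample_id")
    for sample in values.columns:
        if sample not in sheet.index:
            raise FormatError(
                f"{sample_sheet_path}: sample {sample!r} present in matrix "
                "but absent from sample sheet"
            )
    try:
        replicates = {s: int(sheet.loc[s, "replicate"]) for s in values.columns}
    except ValueError as exc:
        raise FormatError(f"{sample_sheet_path}: non-integer replicate: {exc}") from exc
    return ExpressionMatrix(
        values=values,
        sample_state={s: sheet.loc[s, "state"] for s in values.columns},
        sample_stage={s: str(sheet.loc[s, "stage"]) for s in values.columns},
        sample_replicate=replicates,
    )


def write_expression_matrix(expr: ExpressionMatrix, matrix_path, sample_sheet_path) -> None:
    expr.values.to_csv(matrix_path, sep="\t", index_label="gene_id")
    sheet = pd.DataFrame(
        {
            "sample_id": expr.sample_ids,
            "state": [expr.sample_state[s] for s in expr.sample_ids],
            "stage": [expr.sample_stage.get(s, "NA") for s in expr.sample_ids],
            "replicate": [expr.sample_replicate.get(s, 1) for s in expr.sample_ids],
        }
    )
    sheet.to_csv(sample_sheet_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# SNP evidence
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SNPRecord:
    gene_id: str
    position: int  # 1-based
    ref_allele: str
    alt_allele: str
    region_class: str = "unknown"


@dataclass
class SNPTable:
    """Variant evidence between the tolerant and susceptible lines."""

    records: list[SNPRecord]

    def __post_init__(self) -> None:
        for rec in self.records:
            if rec.ref_allele == rec.alt_allele:
                raise FormatError(f"ref == alt for record {rec}")
            if rec.position <= 0:
                raise FormatError(f"non-positive SNP position in record {rec}")

    def genes_with_snps(self) -> set[str]:
        return {rec.gene_id for rec in self.records}

    def region_class_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for rec in self.records:
            counts[rec.region_class] = counts.get(rec.region_class, 0) + 1
        return counts


def _normalize_region_class(value: str) -> str:
    value = value.strip().lower()
    return value if value in REGION_CLASSES else "unknown"


def _snp_from_fields(gene_id: str, pos: str, ref: str, alt: str, region: str,
                     where: str) -> SNPRecord | None:
    """Build one record; None (with a warning) for a rejected ref==alt line."""
    try:
        position = int(pos)
    except ValueError:
        raise FormatError(f"{where}: malformed position {pos!r}") from None
    if position <= 0:
        raise FormatError(f"{where}: non-positive position {position}")
    if ref == alt:
        return None
    return SNPRecord(gene_id, position, ref, alt, _normalize_region_class(region))


def read_snp_table(path) -> SNPTable:
    """Read SNP evidence from a TSV or a minimal VCF dialect.

    The TSV dialect has header columns ``gene_id``, ``position``, ``ref``,
    ``alt``, ``region_class``. The VCF dialect is recognized by leading
    ``#`` header lines; the five mandatory columns are honored and the gene
    (and optionally the region class) are taken from ``GENE=``/``REGION=``
    keys of the INFO column. Records with identical ref and alt alleles are
    dropped; the number dropped is logged.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    non_blank = [ln for ln in lines if ln.strip()]
    is_vcf = bool(non_blank) and non_blank[0].startswith("#")

    records: list[SNPRecord] = []
    n_dropped = 0
    if is_vcf:
        for lineno, line in enumerate(lines, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 5:
                raise FormatError(f"{path}:{lineno}: expected >= 5 VCF columns")
            _, pos, _, ref, alt = fields[:5]
            info = fields[7] if len(fields) >= 8 else fields[-1]
            kv = dict(
                item.split("=", 1) for item in info.split(";") if "=" in item
            )
            gene = kv.get("GENE")
            if gene is None:
                raise FormatError(f"{path}:{lineno}: no GENE= key in INFO column")
            rec = _snp_from_fields(gene, pos, ref, alt, kv.get("REGION", "unknown"),
                                   f"{path}:{lineno}")
            if rec is None:
                n_dropped += 1
            else:
                records.append(rec)
    else:
        frame = pd.read_csv(path, sep="\t", dtype=str)
        required = {"gene_id", "position", "ref", "alt", "region_class"}
        missing = required - set(frame.columns)
        if missing:
            raise FormatError(f"{path}: missing columns {sorted(missing)}")
        for i, row in frame.iterrows():
            rec = _snp_from_fields(
                row["gene_id"], row["position"], row["ref"], row["alt"],
                row["region_class"], f"{path}: row {i}",
            )
            if rec is None:
                n_dropped += 1
            else:
                records.append(rec)
    if n_dropped:
        logger.warning("%s: dropped %d record(s) with ref == alt", path, n_dropped)
    return SNPTable(records=records)


def write_snp_table(table: SNPTable, path) -> None:
    frame = pd.DataFrame(
        [
            (r.gene_id, r.position, r.ref_allele, r.alt_allele, r.region_class)
            for r in table.records
        ],
        columns=["gene_id", "position", "ref", "alt", "region_class"],
    )
    frame.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Gene annotation and genomic intervals
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval, e.g. a marker-delimited QTL."""

    chromosome: str
    start: int
    end: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise FormatError(
                f"interval start must precede end: {self.chromosome}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @classmethod
    def parse(cls, text: str, label: str = "") -> "GenomicInterval":
        """Parse ``chrom:start-end`` region notation."""
        try:
            chrom, span = text.rsplit(":", 1)
            start_s, end_s = span.split("-", 1)
            return cls(chrom, int(start_s), int(end_s), label)
        except ValueError as exc:
            raise FormatError(f"cannot parse interval {text!r}") from exc


@dataclass
class GeneAnnotation:
    """Genomic coordinates per gene: gene_id -> (chromosome, start, end)."""

    entries: dict[str, tuple[str, int, int]]

    def __post_init__(self) -> None:
        for gene, (_, start, end) in self.entries.items():
            if start >= end:
                raise FormatError(f"gene {gene!r}: start {start} >= end {end}")


def read_gene_annotation(path) -> GeneAnnotation:
    """Read a BED4 file (chromosome, start, end, gene_id; 0-based half-open).

    A gene id appearing on several lines keeps the last line's coordinates;
    each override is logged.
    """
    path = Path(path)
    entries: dict[str, tuple[str, int, int]] = {}
    n_overrides = 0
    for lineno, line in enumerate(path.read_text().splitlines(), 1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 4:
            raise FormatError(f"{path}:{lineno}: expected 4 BED columns")
        chrom, start_s, end_s, gene = fields[:4]
        try:
            start, end = int(start_s), int(end_s)
        except ValueError:
            raise FormatError(f"{path}:{lineno}: malformed coordinates") from None
        if start >= end:
            raise FormatError(f"{path}:{lineno}: start {start} >= end {end}")
        if gene in entries:
            n_overrides += 1
        entries[gene] = (chrom, start, end)
    if n_overrides:
        logger.warning("%s: %d duplicate gene line(s) overrode earlier entries",
                       path, n_overrides)
    return GeneAnnotation(entries=entries)


def write_gene_annotation(annotation: GeneAnnotation, path) -> None:
    with open(path, "w") as handle:
        for gene, (chrom, start, end) in annotation.entries.items():
            handle.write(f"{chrom}\t{start}\t{end}\t{gene}\n")


# ---------------------------------------------------------------------------
# Candidate tables
# ---------------------------------------------------------------------------

_METRIC_COLUMNS = ("degree", "cc", "wdegree", "wcc")


def write_candidates(sets, metrics: pd.DataFrame | None, path) -> None:
    """Write the union of the three candidate sets as a TSV.

    One row per gene in the union, lexicographic gene order, with membership
    flags, the gene's Venn region, and (when a metrics table is given) the
    per-state values of all four node metrics.

    Parameters
    ----------
    sets
        A :class:`~saltnet.candidate_selection.CandidateSets`.
    metrics
        Node metrics table with columns ``gene_id``, ``state``, ``degree``,
        ``cc``, ``wdegree``, ``wcc``; may be None.
    path
        Output TSV path.
    """
    union = sorted(sets.gcn | sets.cc | sets.wgcn)
    rows = []
    lookup: dict[tuple[str, str], pd.Series] = {}
    if metrics is not None and len(metrics):
        lookup = {
            (row.gene_id, row.state): row for row in metrics.itertuples()
        }
    for gene in union:
        pattern = (gene in sets.gcn, gene in sets.cc, gene in sets.wgcn)
        row: dict[str, object] = {
            "gene_id": gene,
            "in_gcn": int(pattern[0]),
            "in_cc": int(pattern[1]),
            "in_wgcn": int(pattern[2]),
            "venn_region": VENN_LABELS[pattern],
        }
        for state in STATES:
            rec = lookup.get((gene, state))
            for col in _METRIC_COLUMNS:
                row[f"{col}_{state}"] = getattr(rec, col) if rec is not None else ""
        rows.append(row)
    columns = ["gene_id", "in_gcn", "in_cc", "in_wgcn", "venn_region"] + [
        f"{col}_{state}" for state in STATES for col in _METRIC_COLUMNS
    ]
    pd.DataFrame(rows, columns=columns).to_csv(path, sep="\t", index=False)


def read_candidates(path):
    """Re-read a candidates TSV into a CandidateSets (inverse of writing)."""
    from .candidate_selection import CandidateSets

    frame = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    gcn = set(frame.loc[frame["in_gcn"] == 1, "gene_id"]) if len(frame) else set()
    cc = set(frame.loc[frame["in_cc"] == 1, "gene_id"]) if len(frame) else set()
    wgcn = set(frame.loc[frame["in_wgcn"] == 1, "gene_id"]) if len(frame) else set()
    return CandidateSets(gcn=gcn, cc=cc, wgcn=wgcn)
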