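"""Exon target-set construction from gene annotations.

Capture designs start from transcript annotations of two providers
(labelled ``refseq`` and ``ensembl`` throughout).  The exons of both are
merged into a non-redundant set of genomic target intervals:

* exact-duplicate exons across sources collapse into one record,
* non-coding (lncRNA/miRNA) exons of the second source that overlap any
  exon of the first are dropped,
* exons completely contained in a longer exon are removed, with their
  gene labels transferred to the containing exon.

All coordinates are 0-based half-open internally.  GTF/GFF3 input is
converted from the 1-based closed convention at the parsing boundary;
BED12 is already half-open.
"""

from __future__ import annotations

import csv
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

from intervaltree import IntervalTree

from .genome import GenomeAssembly

Interval = Tuple[int, int]


class AnnotationParseError(ValueError):
    """Raised for a malformed annotation line; carries the line number."""

    def __init__(self, path, line_number: int, message: str):
        super().__init__(f"{path}:{line_number}: {message}")
        self.line_number = line_number


_BIOTYPE_ALIASES = {
    "protein_coding": "protein_coding",
    "mrna": "protein_coding",
    "lncrna": "lncRNA",
    "lnc_rna": "lncRNA",
    "lincrna": "lncRNA",
    "mirna": "miRNA",
}


def _normalise_biotype(raw: str) -> str:
    return _BIOTYPE_ALIASES.get(raw.strip().lower(), "other")


@dataclass
class TranscriptAnnotation:
    """One transcript: its exon structure and optional CDS."""

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    exons: List[Interval]
    cds: Optional[List[Interval]] = None
    source: str = "refseq"
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")
        self.exons = sorted(self.exons)
        prev_end = -1
        for start, end in self.exons:
            if end <= start:
                raise ValueError(
                    f"{self.transcript_id}: empty exon interval [{start}, {end})"
                )
            if start < prev_end:
                raise ValueError(
                    f"{self.transcript_id}: overlapping exons within transcript"
                )
            prev_end = end
        if self.cds is not None:
            self.cds = sorted(self.cds)

    @property
    def cds_length(self) -> int:
        if not self.cds:
            return 0
        return sum(e - s for s, e in self.cds)


# ---------------------------------------------------------------------------
# Parsing


def _parse_gtf_attributes(attr_field: str) -> Dict[str, str]:
    attrs: Dict[str, str] = {}
    for chunk in attr_field.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if " " in chunk:
            key, _, value = chunk.partition(" ")
            attrs[key] = value.strip().strip('"')
    return attrs


def _parse_gff3_attributes(attr_field: str) -> Dict[str, str]:
    attrs: Dict[str, str] = {}
    for chunk in attr_field.strip().split(";"):
        if "=" in chunk:
            key, _, value = chunk.partition("=")
            attrs[key.strip()] = value.strip()
    return attrs


def _load_gtf_like(path: Path, source: str, dialect: str) -> List[TranscriptAnnotation]:
    exons: Dict[str, List[Interval]] = defaultdict(list)
    cds: Dict[str, List[Interval]] = defaultdict(list)
    meta: Dict[str, Tuple[str, str, str, str]] = {}  # tid -> (gene, chrom, strand, biotype)
    parse_attrs = _parse_gtf_attributes if dialect == "gtf" else _parse_gff3_attributes

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise AnnotationParseError(
                    path, lineno, f"expected 9 tab-separated fields, got {len(fields)}"
                )
            chrom, _src, ftype, start_s, end_s, _score, strand, _frame, attr_field = fields
            if ftype not in ("exon", "CDS"):
                continue
            try:
                start = int(start_s) - 1  # 1-based closed -> 0-based half-open
                end = int(end_s)
            except ValueError:
                raise AnnotationParseError(path, lineno, "non-integer coordinates")
            if end <= start:
                raise AnnotationParseError(path, lineno, f"empty interval {start_s}-{end_s}")
            attrs = parse_attrs(attr_field)
            if dialect == "gtf":
                tid = attrs.get("transcript_id")
                gene = attrs.get("gene_id")
            else:
                tid = attrs.get("Parent") or attrs.get("transcript_id")
                gene = attrs.get("gene_id") or attrs.get("gene")
            if tid is None:
                raise AnnotationParseError(path, lineno, "missing transcript identifier")
            biotype = attrs.get("gene_biotype") or attrs.get("transcript_biotype") or \
                attrs.get("biotype") or "protein_coding"
            meta.setdefault(tid, (gene or tid, chrom, strand, _normalise_biotype(biotype)))
            if ftype == "exon":
                exons[tid].append((start, end))
            else:
                cds[tid].append((start, end))

    out = []
    for tid, (gene, chrom, strand, biotype) in meta.items():
        tx_exons = exons.get(tid) or cds.get(tid, [])
        out.append(
            TranscriptAnnotation(
                gene_id=gene,
                transcript_id=tid,
                chrom=chrom,
                strand=strand,
                exons=tx_exons,
                cds=sorted(cds[tid]) if tid in cds else None,
                source=source,
                biotype=biotype,
            )
        )
    return out


def _load_bed12(path: Path, source: str) -> List[TranscriptAnnotation]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise AnnotationParseError(
                    path, lineno, f"expected 12 BED12 fields, got {len(fields)}"
                )
            try:
                chrom = fields[0]
                chrom_start = int(fields[1])
                name = fields[3]
                strand = fields[5]
                thick_start = int(fields[6])
                thick_end = int(fields[7])
                block_count = int(fields[9])
                sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
                starts = [int(x) for x in fields[11].rstrip(",").split(",")]
            except ValueError:
                raise AnnotationParseError(path, lineno, "malformed BED12 numeric field")
            if len(sizes) != block_count or len(starts) != block_count:
                raise AnnotationParseError(path, lineno, "block count mismatch")
            exons = [
                (chrom_start + bs, chrom_start + bs + sz)
                for bs, sz in zip(starts, sizes)
            ]
            # name dialect: "gene|transcript[|biotype]"; bare names serve as both
            parts = name.split("|")
            gene = parts[0]
            tid = parts[1] if len(parts) > 1 else name
            biotype = _normalise_biotype(parts[2]) if len(parts) > 2 else "protein_coding"
            cds = None
            if thick_end > thick_start:
                cds = [
                    (max(s, thick_start), min(e, thick_end))
                    for s, e in exons
                    if min(e, thick_end) > max(s, thick_start)
                ]
            out.append(
                TranscriptAnnotation(
                    gene_id=gene,
                    transcript_id=tid,
                    chrom=chrom,
                    strand=strand,
                    exons=exons,
                    cds=cds,
                    source=source,
                    biotype=biotype,
                )
            )
    return out


def load_annotations(
    path: str | Path, format: str, source: str
) -> List[TranscriptAnnotation]:
    """Load transcripts from GTF, GFF3 or BED12.

    Exon coordinates are returned 0-based half-open regardless of the
    input dialect.  ``source`` labels the provenance (``refseq`` or
    ``ensembl``) and drives the merge policy downstream.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format in ("gtf", "gff3"):
        return _load_gtf_like(path, source, format)
    if format == "bed12":
        return _load_bed12(path, source)
    raise ValueError(f"unknown annotation format {format!r}")


# ---------------------------------------------------------------------------
# Merging


@dataclass
class MergePolicy:
    """How the two annotation sources are combined.

    ``drop_nc_overlapping_refseq``: drop ensembl lncRNA/miRNA exons that
    overlap (>= 1 bp, either strand) any refseq exon.  ``per_transcript``
    evaluates that overlap per transcript rather than per exon.
    """

    drop_nc_overlapping_refseq: bool = True
    nc_biotypes: frozenset = frozenset({"lncRNA", "miRNA"})
    per_transcript: bool = False


@dataclass
class LabeledExon:
    """An exon interval with its gene/source labels and CDS sub-pieces."""

    chrom: str
    start: int
    end: int
    gene_ids: Set[str] = field(default_factory=set)
    sources: Set[str] = field(default_factory=set)
    cds: List[Interval] = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.end - self.start


def _transcript_exon_records(tx: TranscriptAnnotation) -> Iterable[LabeledExon]:
    for start, end in tx.exons:
        pieces = []
        if tx.cds:
            pieces = [
                (max(s, start), min(e, end))
                for s, e in tx.cds
                if min(e, end) > max(s, start)
            ]
        yield LabeledExon(tx.chrom, start, end, {tx.gene_id}, {tx.source}, pieces)


def merge_annotations(
    refseq: Sequence[TranscriptAnnotation],
    ensembl: Sequence[TranscriptAnnotation],
    policy: MergePolicy | None = None,
) -> List[LabeledExon]:
    """Union both sources' exons under the merge policy.

    Returns one :class:`LabeledExon` per distinct (chrom, start, end),
    carrying the union of gene labels, sources and CDS pieces.
    """
    policy = policy or MergePolicy()

    refseq_trees: Dict[str, IntervalTree] = defaultdict(IntervalTree)
    for tx in refseq:
        for start, end in tx.exons:
            refseq_trees[tx.chrom][start:end] = True

    def overlaps_refseq(chrom: str, start: int, end: int) -> bool:
        return bool(refseq_trees[chrom].overlap(start, end))

    records: List[LabeledExon] = []
    for tx in refseq:
        records.extend(_transcript_exon_records(tx))
    for tx in ensembl:
        is_nc = tx.biotype in policy.nc_biotypes
        if is_nc and policy.drop_nc_overlapping_refseq:
            if policy.per_transcript:
                if any(overlaps_refseq(tx.chrom, s, e) for s, e in tx.exons):
                    continue
                records.extend(_transcript_exon_records(tx))
            else:
                for rec in _transcript_exon_records(tx):
                    if not overlaps_refseq(rec.chrom, rec.start, rec.end):
                        records.append(rec)
        else:
            records.extend(_transcript_exon_records(tx))

    return collapse_duplicate_exons(records)


def collapse_duplicate_exons(records: Iterable[LabeledExon]) -> List[LabeledExon]:
    """Collapse records sharing (chrom, start, end), merging labels."""
    merged: Dict[Tuple[str, int, int], LabeledExon] = {}
    for rec in records:
        key = (rec.chrom, rec.start, rec.end)
        if key in merged:
            kept = merged[key]
            kept.gene_ids |= rec.gene_ids
            kept.sources |= rec.sources
            kept.cds = _union_intervals(kept.cds + rec.cds)
        else:
            merged[key] = LabeledExon(
                rec.chrom, rec.start, rec.end,
                set(rec.gene_ids), set(rec.sources), _union_intervals(rec.cds),
            )
    return sorted(merged.values(), key=lambda r: (r.chrom, r.start, r.end))


def _union_intervals(intervals: List[Interval]) -> List[Interval]:
    if not intervals:
        return []
    intervals = sorted(intervals)
    out = [list(intervals[0])]
    for s, e in intervals[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def remove_contained_exons(exons: Iterable[LabeledExon]) -> List[LabeledExon]:
    """Drop exons completely contained in a strictly longer exon.

    Labels (gene ids, sources, CDS pieces) of a removed exon are
    transferred to its container, so the covered base set and the gene
    roster are both preserved.  Idempotent by construction: a single
    left-to-right sweep per chromosome removes every contained interval.
    """
    exons = collapse_duplicate_exons(exons)
    by_chrom: Dict[str, List[LabeledExon]] = defaultdict(list)
    for rec in exons:
        by_chrom[rec.chrom].append(rec)

    kept: List[LabeledExon] = []
    for chrom in sorted(by_chrom):
        recs = sorted(by_chrom[chrom], key=lambda r: (r.start, -r.end))
        max_end = -1
        container: Optional[LabeledExon] = None
        for rec in recs:
            if rec.end <= max_end and container is not None:
                # contained in `container` (earlier start, larger end)
                container.gene_ids |= rec.gene_ids
                container.sources |= rec.sources
                container.cds = _union_intervals(container.cds + rec.cds)
            else:
                kept.append(rec)
                if rec.end > max_end:
                    max_end = rec.end
                    container = rec
    return sorted(kept, key=lambda r: (r.chrom, r.start, r.end))


# ---------------------------------------------------------------------------
# Target set


@dataclass
class TargetInterval:
    chrom: str
    start: int
    end: int
    gene_ids: Set[str] = field(default_factory=set)
    sources: Set[str] = field(default_factory=set)

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class TargetSetStats:
    unique_exon_count: int
    unique_gene_count: int
    total_target_bp: int


class TargetSet:
    """A non-redundant set of capture target intervals grouped by gene."""

    def __init__(self, targets: Sequence[TargetInterval]):
        self.targets: List[TargetInterval] = sorted(
            targets, key=lambda t: (t.chrom, t.start, t.end)
        )
        self.genes: Dict[str, List[TargetInterval]] = defaultdict(list)
        self._trees: Dict[str, IntervalTree] = defaultdict(IntervalTree)
        for idx, t in enumerate(self.targets):
            for g in t.gene_ids:
                self.genes[g].append(t)
            self._trees[t.chrom][t.start:t.end] = idx
        self.genes = dict(self.genes)

    @property
    def stats(self) -> TargetSetStats:
        return TargetSetStats(
            unique_exon_count=len(self.targets),
            unique_gene_count=len(self.genes),
            total_target_bp=sum(t.length for t in self.targets),
        )

    @property
    def total_target_bp(self) -> int:
        return sum(t.length for t in self.targets)

    def overlapping(self, chrom: str, start: int, end: int) -> List[TargetInterval]:
        if chrom not in self._trees:
            return []
        return [self.targets[iv.data] for iv in self._trees[chrom].overlap(start, end)]

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        return chrom in self._trees and bool(self._trees[chrom].overlap(start, end))

    def covered_bases(self, chrom: str) -> Set[int]:
        """Exact set of covered positions; intended for small fixtures."""
        out: Set[int] = set()
        for t in self.targets:
            if t.chrom == chrom:
                out.update(range(t.start, t.end))
        return out

    # -- I/O ---------------------------------------------------------------

    def write_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for t in self.targets:
                name = ",".join(sorted(t.gene_ids)) or "."
                fh.write(f"{t.chrom}\t{t.start}\t{t.end}\t{name}\t0\t.\n")

    @classmethod
    def read_bed(cls, path: str | Path) -> "TargetSet":
        targets = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split("\t")
                if len(fields) < 3:
                    raise AnnotationParseError(path, lineno, "expected >= 3 BED fields")
                genes = set()
                if len(fields) >= 4 and fields[3] != ".":
                    genes = set(fields[3].split(","))
                targets.append(
                    TargetInterval(fields[0], int(fields[1]), int(fields[2]), genes)
                )
        return cls(targets)

    def write_stats_tsv(self, path: str | Path) -> None:
        s = self.stats
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t")
            w.writerow(["metric", "value"])
            w.writerow(["unique_exon_count", s.unique_exon_count])
            w.writerow(["unique_gene_count", s.unique_gene_count])
            w.writerow(["total_target_bp", s.total_target_bp])


def build_target_set(
    exons: Sequence[LabeledExon],
    include_utr: bool = True,
    genome: Optional[GenomeAssembly] = None,
) -> TargetSet:
    """Assemble the final :class:`TargetSet` from merged, de-contained exons.

    With ``include_utr=False``, exons carrying CDS information are
    intersected with their CDS pieces (exons without CDS — e.g. retained
    non-coding RNAs — are kept whole).  With a genome supplied, intervals
    out of chromosome bounds raise a validation error.
    """
    targets: List[TargetInterval] = []
    for rec in exons:
        if genome is not None:
            if rec.chrom not in genome:
                raise ValueError(f"target on unknown chromosome: {rec.chrom}")
            if rec.start < 0 or rec.end > genome.length(rec.chrom):
                raise ValueError(
                    f"target {rec.chrom}:{rec.start}-{rec.end} out of chromosome bounds"
                )
        if not include_utr and rec.cds:
            for s, e in rec.cds:
                targets.append(TargetInterval(rec.chrom, s, e, set(rec.gene_ids), set(rec.sources)))
        else:
            targets.append(
                TargetInterval(rec.chrom, rec.start, rec.end, set(rec.gene_ids), set(rec.sources))
            )
    return TargetSet(targets)
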