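"""Stringent variant filtration, normal subtraction and catalog matching.

The filtration chain reflects a tumor/normal exome workflow:

1. depth filter — keep calls with total depth >= 50 and alternate
   allele depth >= 20 (defaults chosen for discriminating stringency),
2. exonic restriction against a capture target set,
3. split into catalog-annotated vs novel against a dbSNP-like catalog,
4. subtraction of variants seen in any normal sample,
5. codon/amino-acid annotation on explicit gene models, and
6. matching against a COSMIC-like catalog of validated somatic
   mutations by amino-acid substitution and/or codon location.

Variant keys are (chrom, pos, ref, alt); multi-allelic records are
split and indels left-normalized before any set operation.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, replace
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

from Bio.Seq import Seq

from .genome import GenomeAssembly, reverse_complement
from .qc import DepthProfile
from .targets import TargetSet, TranscriptAnnotation

VariantKey = Tuple[str, int, str, str]


@dataclass
class VariantRecord:
    chrom: str
    pos: int  # 1-based, VCF convention
    ref: str
    alt: str
    total_depth: int
    alt_depth: int
    sample_id: str = "sample"
    variant_id: Optional[str] = None
    gene_id: Optional[str] = None
    codon_change: Optional[str] = None
    aa_change: Optional[Tuple[str, int, str]] = None
    zygosity: str = "unknown"

    def __post_init__(self) -> None:
        if not (0 <= self.alt_depth <= self.total_depth):
            raise ValueError(
                f"{self.chrom}:{self.pos} AD={self.alt_depth} outside [0, DP={self.total_depth}]"
            )
        for allele in (self.ref, self.alt):
            if not allele or set(allele) - set("ACGT"):
                raise ValueError(f"invalid allele {allele!r} at {self.chrom}:{self.pos}")

    @property
    def kind(self) -> str:
        return "SNV" if len(self.ref) == 1 and len(self.alt) == 1 else "INDEL"

    @property
    def key(self) -> VariantKey:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def aa_change_str(self) -> Optional[str]:
        if self.aa_change is None:
            return None
        ref_aa, codon, alt_aa = self.aa_change
        return f"{ref_aa}{codon}{alt_aa}"


@dataclass(frozen=True)
class CatalogEntry:
    """dbSNP-like known-polymorphism entry keyed by position+alleles."""

    chrom: str
    pos: int
    ref: str
    alt: str
    id: str

    @property
    def key(self) -> VariantKey:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class CosmicEntry:
    """COSMIC-like validated somatic mutation: gene + amino-acid change."""

    gene_id: str
    aa_ref: str
    codon_number: int
    aa_alt: str
    chrom: str = ""
    pos: int = 0


MATCH_SUBSTITUTION_AND_LOCATION = "substitution_and_location"
MATCH_SUBSTITUTION_ONLY = "substitution_only"
MATCH_LOCATION_ONLY = "location_only"
MATCH_NONE = "none"


@dataclass
class MatchResult:
    category: str
    matched_entry: Optional[CosmicEntry] = None


# ---------------------------------------------------------------------------
# VCF I/O


def read_vcf(path: str | Path, sample_id: Optional[str] = None) -> List[VariantRecord]:
    """Read a VCF 4.x with per-sample DP and AD.

    Multi-allelic sites are split into one record per alternate allele,
    with AD taken from the matching allele.  Records missing DP or AD
    are skipped with a warning.
    """
    import pysam

    records: List[VariantRecord] = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        if not samples:
            raise ValueError(f"{path}: VCF has no sample columns")
        sample = samples[0]
        label = sample_id or sample
        for rec in vcf:
            fmt = rec.samples[sample]
            dp = fmt.get("DP")
            ad = fmt.get("AD")
            if dp is None or ad is None:
                warnings.warn(
                    f"{path}:{rec.chrom}:{rec.pos} missing DP/AD; record skipped"
                )
                continue
            for i, alt in enumerate(rec.alts or ()):
                if alt is None or set(alt) - set("ACGT"):
                    continue  # symbolic alleles are out of scope
                records.append(
                    VariantRecord(
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref=rec.ref,
                        alt=alt,
                        total_depth=int(dp),
                        alt_depth=int(ad[i + 1]),
                        sample_id=label,
                        variant_id=rec.id,
                    )
                )
    return records


def write_vcf(
    records: Sequence[VariantRecord],
    path: str | Path,
    sample_id: Optional[str] = None,
    contigs: Optional[Dict[str, int]] = None,
) -> None:
    """Write records as a minimal single-sample VCF 4.2."""
    sample = sample_id or (records[0].sample_id if records else "sample")
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=exocapkit\n")
        if contigs:
            for name, length in contigs.items():
                fh.write(f"##contig=<ID={name},length={length}>\n")
        else:
            for name in sorted({r.chrom for r in records}):
                fh.write(f"##contig=<ID={name}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write(
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n'
        )
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}\n")
        for r in sorted(records, key=lambda r: (r.chrom, r.pos, r.ref, r.alt)):
            ref_depth = r.total_depth - r.alt_depth
            gt = "1/1" if r.zygosity == "hom" else "0/1"
            fh.write(
                f"{r.chrom}\t{r.pos}\t{r.variant_id or '.'}\t{r.ref}\t{r.alt}\t.\tPASS\t.\t"
                f"GT:DP:AD\t{gt}:{r.total_depth}:{ref_depth},{r.alt_depth}\n"
            )


# ---------------------------------------------------------------------------
# Catalog I/O


def read_dbsnp_tsv(path: str | Path) -> List[CatalogEntry]:
    """TSV columns: chrom, pos, ref, alt, id (header optional)."""
    out = []
    with open(path) as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#") or row[0] == "chrom":
                continue
            out.append(CatalogEntry(row[0], int(row[1]), row[2], row[3], row[4]))
    return out


def write_dbsnp_tsv(entries: Iterable[CatalogEntry], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["chrom", "pos", "ref", "alt", "id"])
        for e in entries:
            w.writerow([e.chrom, e.pos, e.ref, e.alt, e.id])


def read_cosmic_tsv(path: str | Path) -> List[CosmicEntry]:
    """TSV columns: gene_id, aa_ref, codon_number, aa_alt, chrom, pos."""
    out = []
    with open(path) as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#") or row[0] == "gene_id":
                continue
            out.append(
                CosmicEntry(
                    gene_id=row[0],
                    aa_ref=row[1],
                    codon_number=int(row[2]),
                    aa_alt=row[3],
                    chrom=row[4] if len(row) > 4 else "",
                    pos=int(row[5]) if len(row) > 5 else 0,
                )
            )
    return out


def write_cosmic_tsv(entries: Iterable[CosmicEntry], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["gene_id", "aa_ref", "codon_number", "aa_alt", "chrom", "pos"])
        for e in entries:
            w.writerow([e.gene_id, e.aa_ref, e.codon_number, e.aa_alt, e.chrom, e.pos])


# ---------------------------------------------------------------------------
# Normalization and filters


def left_normalize(record: VariantRecord, genome: GenomeAssembly) -> VariantRecord:
    """Shift an indel to its smallest equivalent coordinate.

    Trailing shared bases are trimmed (extending left with reference
    sequence when an allele would empty), then leading shared bases are
    trimmed.  SNVs are returned unchanged.
    """
    ref, alt, pos = record.ref, record.alt, record.pos
    if len(ref) == 1 and len(alt) == 1:
        return record
    changed = True
    while changed:
        changed = False
        # trim identical trailing base
        while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
            ref, alt = ref[:-1], alt[:-1]
            changed = True
        # extend left when a trailing base still matches but one allele is length 1
        if ref[-1] == alt[-1] and (len(ref) > 1 or len(alt) > 1) and pos > 1:
            base = genome.fetch(record.chrom, pos - 2, pos - 1)
            ref, alt = base + ref[:-1], base + alt[:-1]
            pos -= 1
            changed = True
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return replace(record, chrom=record.chrom, pos=pos, ref=ref, alt=alt)


def filter_by_depth(
    records: Sequence[VariantRecord], min_total: int = 50, min_alt: int = 20
) -> List[VariantRecord]:
    """Keep records with DP >= min_total and AD >= min_alt."""
    return [r for r in records if r.total_depth >= min_total and r.alt_depth >= min_alt]


def restrict_to_targets(
    records: Sequence[VariantRecord], target_set: TargetSet
) -> List[VariantRecord]:
    """Exonic restriction: keep variants whose position falls in a target."""
    return [
        r for r in records if target_set.overlaps(r.chrom, r.pos - 1, r.pos)
    ]


def allele_fraction(record: VariantRecord) -> float:
    """AD/DP rounded half-up to 3 decimals."""
    if record.total_depth <= 0:
        raise ValueError("allele fraction undefined at zero total depth")
    frac = Decimal(record.alt_depth) / Decimal(record.total_depth)
    return float(frac.quantize(Decimal("0.001"), rounding=ROUND_HALF_UP))


def call_zygosity(record: VariantRecord, hom_threshold: float = 0.9) -> str:
    """hom iff the (unrounded) allele fraction reaches the threshold."""
    if record.total_depth <= 0:
        raise ValueError("zygosity undefined at zero total depth")
    return "hom" if record.alt_depth / record.total_depth >= hom_threshold else "het"


def round_pct_half_up(numerator: int, denominator: int) -> float:
    """Percentage n/d*100 rounded half-up to one decimal."""
    if denominator == 0:
        return 0.0
    pct = Decimal(numerator) * 100 / Decimal(denominator)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def split_by_catalog(
    records: Sequence[VariantRecord], catalog: Sequence[CatalogEntry]
) -> Tuple[List[VariantRecord], List[VariantRecord], Dict[str, float]]:
    """Split records into catalog-annotated vs novel.

    Membership is by (chrom, pos, ref, alt).  Percentages are over the
    input count, rounded half-up to one decimal.
    """
    keys: Set[VariantKey] = {e.key for e in catalog}
    annotated = [r for r in records if r.key in keys]
    novel = [r for r in records if r.key not in keys]
    pct = {
        "annotated_pct": round_pct_half_up(len(annotated), len(records)),
        "non_annotated_pct": round_pct_half_up(len(novel), len(records)),
    }
    return annotated, novel, pct


def subtract_normals(
    tumor_records: Sequence[VariantRecord],
    normal_record_sets: Sequence[Sequence[VariantRecord]],
) -> List[VariantRecord]:
    """Remove tumor variants whose key occurs in ANY normal sample.

    Removal is genotype-agnostic: presence of the key in one normal is
    enough, leaving cell-line-specific (putatively somatic) variants.
    """
    normal_keys: Set[VariantKey] = set()
    for ns in normal_record_sets:
        normal_keys.update(r.key for r in ns)
    return [r for r in tumor_records if r.key not in normal_keys]


# ---------------------------------------------------------------------------
# Codon annotation


def _cds_sequence(gene_model: TranscriptAnnotation, genome: GenomeAssembly) -> str:
    if not gene_model.cds:
        raise ValueError(f"{gene_model.transcript_id} has no CDS")
    seq = "".join(genome.fetch(gene_model.chrom, s, e) for s, e in gene_model.cds)
    if gene_model.strand == "-":
        seq = reverse_complement(seq)
    return seq


def _genomic_to_cds_offset(
    gene_model: TranscriptAnnotation, genomic_pos0: int
) -> Optional[int]:
    """0-based genomic position -> 0-based offset in the coding sequence."""
    forward = 0
    total = gene_model.cds_length
    for s, e in gene_model.cds:
        if s <= genomic_pos0 < e:
            offset = forward + (genomic_pos0 - s)
            return (total - 1 - offset) if gene_model.strand == "-" else offset
        forward += e - s
    return None


def annotate_codon_change(
    record: VariantRecord,
    gene_model: TranscriptAnnotation,
    genome: GenomeAssembly,
) -> VariantRecord:
    """Annotate an SNV inside a CDS with its codon and amino-acid change.

    The codon string is rendered lower-case with the mutated position
    upper-case in both alleles (e.g. ``cGt/cAt``); the amino-acid change
    uses one-letter code with '*' for stop (e.g. ``R271H``).  On
    reverse-strand genes the codon is read on the coding strand and the
    variant base complemented.  Non-SNVs and variants outside the CDS
    are returned unannotated (gene id recorded for CDS-resident indels).
    """
    if record.kind != "SNV":
        offset = _genomic_to_cds_offset(gene_model, record.pos - 1)
        if offset is not None:
            return replace(record, gene_id=gene_model.gene_id)
        return record
    offset = _genomic_to_cds_offset(gene_model, record.pos - 1)
    if offset is None:
        return record
    if gene_model.cds_length % 3 != 0:
        raise ValueError(
            f"{gene_model.transcript_id}: CDS length {gene_model.cds_length} not divisible by 3"
        )
    cds = _cds_sequence(gene_model, genome)
    ref_base, alt_base = record.ref, record.alt
    if gene_model.strand == "-":
        ref_base = reverse_complement(ref_base)
        alt_base = reverse_complement(alt_base)
    if cds[offset] != ref_base:
        raise ValueError(
            f"reference mismatch at {record.chrom}:{record.pos}: "
            f"CDS has {cds[offset]}, record ref (coding strand) is {ref_base}"
        )
    codon_index = offset // 3
    within = offset % 3
    ref_codon = cds[codon_index * 3 : codon_index * 3 + 3]
    alt_codon = ref_codon[:within] + alt_base + ref_codon[within + 1 :]

    def render(codon: str) -> str:
        return "".join(
            b.upper() if i == within else b.lower() for i, b in enumerate(codon)
        )

    ref_aa = str(Seq(ref_codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    return replace(
        record,
        gene_id=gene_model.gene_id,
        codon_change=f"{render(ref_codon)}/{render(alt_codon)}",
        aa_change=(ref_aa, codon_index + 1, alt_aa),
    )


# ---------------------------------------------------------------------------
# COSMIC matching


def match_cosmic(
    record: VariantRecord, catalog: Sequence[CosmicEntry]
) -> MatchResult:
    """Match an annotated variant against a somatic-mutation catalog.

    Within the same gene, in decreasing strength: identical
    (aa_ref, codon, aa_alt) triple; same substitution at a different
    codon; same codon with a different alternate amino acid; none.
    """
    if record.aa_change is None or record.gene_id is None:
        raise ValueError("record must carry gene_id and aa_change to match")
    ref_aa, codon, alt_aa = record.aa_change
    gene_entries = [e for e in catalog if e.gene_id == record.gene_id]
    for e in gene_entries:
        if (e.aa_ref, e.codon_number, e.aa_alt) == (ref_aa, codon, alt_aa):
            return MatchResult(MATCH_SUBSTITUTION_AND_LOCATION, e)
    for e in gene_entries:
        if (e.aa_ref, e.aa_alt) == (ref_aa, alt_aa) and e.codon_number != codon:
            return MatchResult(MATCH_SUBSTITUTION_ONLY, e)
    for e in gene_entries:
        if (e.aa_ref, e.codon_number) == (ref_aa, codon) and e.aa_alt != alt_aa:
            return MatchResult(MATCH_LOCATION_ONLY, e)
    return MatchResult(MATCH_NONE, None)


# ---------------------------------------------------------------------------
# Coverage-based deletion calling


def call_gene_deletion(
    gene_id: str,
    profile: DepthProfile,
    sample_median_depth: float,
    fraction_threshold: float = 0.05,
) -> str:
    """Flag a homozygous gene deletion from capture coverage.

    A gene is called deleted when its mean depth over all target bases
    falls below ``fraction_threshold`` times the sample median depth.
    """
    if sample_median_depth <= 0:
        raise ValueError("sample_median_depth must be positive")
    mean = profile.gene_mean_depth(gene_id)
    return "deleted" if mean < fraction_threshold * sample_median_depth else "not_deleted"


# ---------------------------------------------------------------------------
# Reporting


def write_match_report_tsv(
    rows: Sequence[Tuple[VariantRecord, MatchResult]], path: str | Path
) -> None:
    """Validation-table-shaped report: position, gene, codon change,
    coverage, allele depth, AF, zygosity, match category."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow([
            "chrom", "pos", "gene", "aa_change", "codon_change",
            "sample", "total_depth", "alt_depth", "af", "zygosity", "cosmic_match",
        ])
        for rec, match in rows:
            w.writerow([
                rec.chrom, rec.pos, rec.gene_id or ".",
                rec.aa_change_str or ".", rec.codon_change or ".",
                rec.sample_id, rec.total_depth, rec.alt_depth,
                f"{allele_fraction(rec):.3f}",
                call_zygosity(rec),
                match.category,
            ])
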