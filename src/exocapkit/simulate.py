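"""Seeded synthetic fixtures with planted ground truth.

Every other module of the toolkit is exercisable without external data:
this module generates a genome, two annotation sources, read-pair
alignments, tumor/normal variant call sets, polymorphism and somatic
catalogs, and signature-mixture SNV sets — all deterministic under a
fixed seed, with a :class:`GroundTruth` ledger sufficient to predict
every downstream result.

Defaults emulate the study conditions of a rat whole-exome capture
experiment: 101 nt paired-end reads, ~80% of reads on target, ~23%
duplicate reads for fresh-frozen-like libraries (roughly doubled to
~45% with shorter fragments in FFPE mode), and stringent variant
calling at 50X total / 20X alternate depth.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from .genome import GenomeAssembly, reverse_complement
from .qc import ReadPairAlignment, write_pairs_tsv
from .spectrum import (
    CONTEXT_LABELS,
    MutationSpectrum,
    SignatureCatalog,
)
from .targets import (
    LabeledExon,
    TargetSet,
    TranscriptAnnotation,
    build_target_set,
    merge_annotations,
    remove_contained_exons,
)
from .variants import (
    CatalogEntry,
    CosmicEntry,
    VariantRecord,
    annotate_codon_change,
    write_cosmic_tsv,
    write_dbsnp_tsv,
    write_vcf,
)

_STOP_CODONS = {"TAA", "TAG", "TGA"}
_NON_STOP_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOP_CODONS and a + b + c != "ATG"
]


@dataclass
class SimConfig:
    """Generator parameters; defaults are the emulated study conditions."""

    seed: int = 0
    # genome
    chrom_sizes: Dict[str, int] = field(
        default_factory=lambda: {"chr1": 120_000, "chr2": 80_000}
    )
    gc_content: float = 0.42
    duplication_count: int = 2
    duplication_length: int = 500
    # annotation
    gene_count: int = 30
    exons_per_gene: Tuple[int, int] = (2, 5)
    exon_length: Tuple[int, int] = (90, 360)
    intron_length: Tuple[int, int] = (150, 600)
    lnc_overlapping: int = 2   # ensembl lncRNAs planted on refseq exons (dropped at merge)
    lnc_intergenic: int = 2    # ensembl lncRNAs planted in gene deserts (retained)
    contained_exon_genes: int = 3  # genes given an extra exon nested in exon 1
    # reads
    n_pairs: int = 20_000
    read_length: int = 101
    fragment_mean: int = 180
    fragment_sd: int = 25
    on_target_fraction: float = 0.80
    duplicate_rate: float = 0.23
    ffpe_mode: bool = False
    ffpe_duplicate_rate: float = 0.45
    ffpe_on_target_fraction: float = 0.70
    ffpe_fragment_mean: int = 130
    # variants
    n_somatic: int = 12
    n_germline: int = 30
    n_normals: int = 8
    dbsnp_fraction: float = 0.5
    n_deleted_genes: int = 2

    def effective(self) -> "SimConfig":
        """FFPE mode: shorter fragments, roughly doubled duplication,
        lower on-target fraction."""
        if not self.ffpe_mode:
            return self
        return dataclasses.replace(
            self,
            fragment_mean=self.ffpe_fragment_mean,
            on_target_fraction=self.ffpe_on_target_fraction,
            duplicate_rate=self.ffpe_duplicate_rate,
        )


@dataclass
class GroundTruth:
    """Planted values; everything downstream modules should recover."""

    seed: int = 0
    duplications: List[dict] = field(default_factory=list)
    contained_exon_count: int = 0
    dropped_lnc_genes: List[str] = field(default_factory=list)
    retained_lnc_genes: List[str] = field(default_factory=list)
    duplicate_rate: float = 0.0
    on_target_fraction: float = 0.0
    mean_target_depth: float = 0.0
    nominal_pairs: int = 0
    somatic_keys: List[list] = field(default_factory=list)
    somatic_fail_keys: List[list] = field(default_factory=list)
    germline_keys: List[list] = field(default_factory=list)
    dbsnp_member_keys: List[list] = field(default_factory=list)
    cosmic_cases: Dict[str, list] = field(default_factory=dict)
    deleted_genes: List[str] = field(default_factory=list)
    signature_weights: Dict[str, float] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


# ---------------------------------------------------------------------------
# Genome


def make_genome(
    config: SimConfig, rng: Optional[np.random.Generator] = None
) -> Tuple[GenomeAssembly, GroundTruth]:
    """Random genome with i.i.d. bases at the configured GC content.

    ``duplication_count`` segments are copied verbatim to a second locus
    so probes tiled inside them multi-map; copies are recorded in the
    ground truth.
    """
    rng = rng or np.random.default_rng(config.seed)
    gc = config.gc_content
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    bases = np.array(list("ACGT"))
    chroms: Dict[str, str] = {}
    for name, size in config.chrom_sizes.items():
        if size <= 0:
            raise ValueError(f"chromosome size for {name} must be positive")
        chroms[name] = "".join(rng.choice(bases, size=size, p=probs))

    truth = GroundTruth(seed=config.seed)
    names = list(chroms)
    for _ in range(config.duplication_count):
        L = config.duplication_length
        src_chrom = names[int(rng.integers(len(names)))]
        dst_chrom = names[int(rng.integers(len(names)))]
        src_size, dst_size = len(chroms[src_chrom]), len(chroms[dst_chrom])
        if src_size < 2 * L + 2 or dst_size < 2 * L + 2:
            continue
        src_start = int(rng.integers(0, src_size - L))
        # destination in the far half of the chromosome, clear of the source
        for _ in range(50):
            dst_start = int(rng.integers(0, dst_size - L))
            if dst_chrom != src_chrom or abs(dst_start - src_start) >= L:
                break
        segment = chroms[src_chrom][src_start : src_start + L]
        s = chroms[dst_chrom]
        chroms[dst_chrom] = s[:dst_start] + segment + s[dst_start + L :]
        truth.duplications.append(
            {
                "src_chrom": src_chrom, "src_start": src_start,
                "dst_chrom": dst_chrom, "dst_start": dst_start, "length": L,
            }
        )
    return GenomeAssembly(name=f"sim{config.seed}", chromosomes=chroms), truth


# ---------------------------------------------------------------------------
# Annotation


def _write_coding_sequence(
    chrom_seq: List[str],
    cds_pieces: Sequence[Tuple[int, int]],
    strand: str,
    rng: np.random.Generator,
) -> None:
    """Patch the genome so the CDS is ATG + non-stop codons + TAA."""
    total = sum(e - s for s, e in cds_pieces)
    n_codons = total // 3
    body = [
        _NON_STOP_CODONS[int(rng.integers(len(_NON_STOP_CODONS)))]
        for _ in range(max(n_codons - 2, 0))
    ]
    coding = "ATG" + "".join(body) + "TAA"
    genomic = coding if strand == "+" else reverse_complement(coding)
    i = 0
    for s, e in cds_pieces:
        chrom_seq[s:e] = list(genomic[i : i + (e - s)])
        i += e - s


def make_annotation(
    config: SimConfig,
    genome: GenomeAssembly,
    rng: Optional[np.random.Generator] = None,
    truth: Optional[GroundTruth] = None,
) -> Tuple[List[TranscriptAnnotation], List[TranscriptAnnotation], GenomeAssembly]:
    """Lay out genes and return (refseq-like, ensembl-like, patched genome).

    Planted cases: cross-source exact-duplicate transcripts, an extra
    refseq exon nested inside a longer exon (containment removal),
    ensembl-only lncRNAs overlapping refseq exons (dropped at merge) and
    in gene deserts (retained).  Every CDS is divisible by 3, starts
    with ATG, ends with a stop and has no internal stop codon.
    """
    rng = rng or np.random.default_rng(config.seed + 1)
    truth = truth or GroundTruth(seed=config.seed)
    chrom_seqs = {c: list(s) for c, s in genome.chromosomes.items()}
    chrom_names = list(genome.chromosomes)
    cursors = {c: 2_000 for c in chrom_names}

    refseq: List[TranscriptAnnotation] = []
    ensembl: List[TranscriptAnnotation] = []

    for gi in range(config.gene_count):
        gene = f"g{gi + 1:03d}"
        chrom = chrom_names[gi % len(chrom_names)]
        strand = "+" if rng.random() < 0.5 else "-"
        n_exons = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
        pos = cursors[chrom]
        exons: List[Tuple[int, int]] = []
        for _ in range(n_exons):
            length = int(rng.integers(config.exon_length[0], config.exon_length[1] + 1))
            length -= length % 3  # keep per-exon CDS pieces frame-aligned
            exons.append((pos, pos + length))
            pos += length + int(rng.integers(config.intron_length[0], config.intron_length[1] + 1))
        if pos + 2_000 > genome.length(chrom):
            break  # chromosome full; stop placing genes
        cursors[chrom] = pos + 1_000

        cds = list(exons)  # whole-exon CDS; UTR handling is exercised elsewhere
        _write_coding_sequence(chrom_seqs[chrom], cds, strand, rng)

        tx = TranscriptAnnotation(
            gene_id=gene, transcript_id=f"{gene}.r1", chrom=chrom, strand=strand,
            exons=exons, cds=cds, source="refseq", biotype="protein_coding",
        )
        refseq.append(tx)

        # planted containment: a shorter transcript exon nested in exon 1
        if gi < config.contained_exon_genes and exons[0][1] - exons[0][0] >= 120:
            s0, e0 = exons[0]
            inner = (s0 + 30, e0 - 30)
            refseq.append(
                TranscriptAnnotation(
                    gene_id=gene, transcript_id=f"{gene}.r2", chrom=chrom,
                    strand=strand, exons=[inner], cds=None,
                    source="refseq", biotype="protein_coding",
                )
            )
            truth.contained_exon_count += 1

        # cross-source duplicate: ensembl transcript with identical exons
        if gi % 2 == 0:
            ensembl.append(
                TranscriptAnnotation(
                    gene_id=gene, transcript_id=f"{gene}.e1", chrom=chrom,
                    strand=strand, exons=list(exons), cds=list(cds),
                    source="ensembl", biotype="protein_coding",
                )
            )

    # ensembl lncRNAs overlapping refseq exons: dropped under default policy
    for i in range(config.lnc_overlapping):
        host = refseq[i * 2 % len(refseq)]
        s, e = host.exons[0]
        gene = f"lncO{i + 1}"
        ensembl.append(
            TranscriptAnnotation(
                gene_id=gene, transcript_id=f"{gene}.e1", chrom=host.chrom,
                strand="+", exons=[(s + 10, min(s + 210, e + 100))], cds=None,
                source="ensembl", biotype="lncRNA",
            )
        )
        truth.dropped_lnc_genes.append(gene)

    # intergenic lncRNAs: retained
    for i in range(config.lnc_intergenic):
        chrom = chrom_names[i % len(chrom_names)]
        start = genome.length(chrom) - 1_500 - i * 400
        gene = f"lncI{i + 1}"
        ensembl.append(
            TranscriptAnnotation(
                gene_id=gene, transcript_id=f"{gene}.e1", chrom=chrom,
                strand="+", exons=[(start, start + 200)], cds=None,
                source="ensembl", biotype="lncRNA",
            )
        )
        truth.retained_lnc_genes.append(gene)

    patched = GenomeAssembly(
        name=genome.name,
        chromosomes={c: "".join(s) for c, s in chrom_seqs.items()},
    )
    return refseq, ensembl, patched


def write_gtf(transcripts: Sequence[TranscriptAnnotation], path: str | Path) -> None:
    """GTF 2.2 output (1-based closed coordinates)."""
    with open(path, "w") as fh:
        for tx in transcripts:
            attrs = (
                f'gene_id "{tx.gene_id}"; transcript_id "{tx.transcript_id}"; '
                f'gene_biotype "{tx.biotype}";'
            )
            for s, e in tx.exons:
                fh.write(
                    f"{tx.chrom}\t{tx.source}\texon\t{s + 1}\t{e}\t.\t{tx.strand}\t.\t{attrs}\n"
                )
            for s, e in tx.cds or []:
                fh.write(
                    f"{tx.chrom}\t{tx.source}\tCDS\t{s + 1}\t{e}\t.\t{tx.strand}\t0\t{attrs}\n"
                )


def write_bed12(transcripts: Sequence[TranscriptAnnotation], path: str | Path) -> None:
    """BED12 output; name column is ``gene|transcript|biotype``."""
    with open(path, "w") as fh:
        for tx in transcripts:
            start = tx.exons[0][0]
            end = tx.exons[-1][1]
            if tx.cds:
                thick_start, thick_end = tx.cds[0][0], tx.cds[-1][1]
            else:
                thick_start = thick_end = start
            sizes = ",".join(str(e - s) for s, e in tx.exons)
            starts = ",".join(str(s - start) for s, e in tx.exons)
            name = f"{tx.gene_id}|{tx.transcript_id}|{tx.biotype}"
            fh.write(
                f"{tx.chrom}\t{start}\t{end}\t{name}\t0\t{tx.strand}\t"
                f"{thick_start}\t{thick_end}\t0\t{len(tx.exons)}\t{sizes}\t{starts}\n"
            )


# ---------------------------------------------------------------------------
# Read pairs


def make_readpairs(
    config: SimConfig,
    target_set: TargetSet,
    genome: GenomeAssembly,
    rng: Optional[np.random.Generator] = None,
    truth: Optional[GroundTruth] = None,
    deleted_genes: Sequence[str] = (),
) -> Tuple[List[ReadPairAlignment], GroundTruth]:
    """Simulate aligned FR read pairs with planted QC rates.

    On-target pairs are placed uniformly over target bases (excluding
    deleted genes, which get zero coverage); off-target pairs are placed
    uniformly in non-target space by rejection.  Duplicates re-emit
    existing pairs until the planted duplicate rate is reached.  The
    ground truth records the realised mean target depth exactly.
    """
    cfg = config.effective()
    rng = rng or np.random.default_rng(cfg.seed + 2)
    truth = truth or GroundTruth(seed=cfg.seed)

    deleted = set(deleted_genes)
    live_targets = [
        t for t in target_set.targets if not (t.gene_ids and t.gene_ids <= deleted)
    ]
    if not live_targets:
        raise ValueError("no targets available for read placement")
    weights = np.array([t.length for t in live_targets], dtype=float)
    weights /= weights.sum()
    chrom_names = list(genome.chromosomes)
    chrom_lens = np.array([genome.length(c) for c in chrom_names], dtype=float)
    chrom_probs = chrom_lens / chrom_lens.sum()

    n_total = cfg.n_pairs
    n_unique = int(round(n_total * (1 - cfg.duplicate_rate)))
    n_dup = n_total - n_unique

    def draw_fragment_length() -> int:
        return max(cfg.read_length, int(round(rng.normal(cfg.fragment_mean, cfg.fragment_sd))))

    uniques: List[ReadPairAlignment] = []
    serial = 0
    while len(uniques) < n_unique:
        serial += 1
        frag = draw_fragment_length()
        if rng.random() < cfg.on_target_fraction:
            # both mates must overlap the target so the planted per-read
            # on-target fraction is exact
            t = live_targets[int(rng.choice(len(live_targets), p=weights))]
            chrom = t.chrom
            chrom_len = genome.length(chrom)
            for _ in range(200):
                start = int(rng.integers(t.start - frag + 1, t.end))
                start = max(0, min(start, chrom_len - frag))
                r1 = (start, start + cfg.read_length)
                r2 = (max(start, start + frag - cfg.read_length), start + frag)
                if (
                    r1[1] > t.start and r1[0] < t.end
                    and r2[1] > t.start and r2[0] < t.end
                ):
                    break
            else:
                continue
        else:
            # rejection-sample a fragment clear of every target
            for _ in range(200):
                ci = int(rng.choice(len(chrom_names), p=chrom_probs))
                chrom = chrom_names[ci]
                if genome.length(chrom) <= frag:
                    continue
                start = int(rng.integers(0, genome.length(chrom) - frag))
                if not target_set.overlaps(chrom, start, start + frag):
                    break
            else:
                continue
        pos2 = max(start, start + frag - cfg.read_length)
        uniques.append(
            ReadPairAlignment(
                pair_id=f"u{serial:07d}",
                chrom1=chrom, pos1=start,
                chrom2=chrom, pos2=pos2,
                read_length=cfg.read_length,
                orientation="FR",
            )
        )

    pairs = list(uniques)
    for d in range(n_dup):
        src = uniques[int(rng.integers(len(uniques)))]
        pairs.append(
            dataclasses.replace(src, pair_id=f"z{d:07d}", duplicate=False)
        )
    order = rng.permutation(len(pairs))
    pairs = [pairs[i] for i in order]

    # exact realised depth over target bases from the unique pairs
    overlap_bases = 0
    for p in uniques:
        for chrom, s, e in p.reads():
            for t in target_set.overlapping(chrom, s, e):
                overlap_bases += min(e, t.end) - max(s, t.start)
    total_bp = target_set.total_target_bp

    truth.nominal_pairs = n_total
    truth.duplicate_rate = 100.0 * n_dup / n_total if n_total else 0.0
    truth.on_target_fraction = 100.0 * cfg.on_target_fraction
    truth.mean_target_depth = overlap_bases / total_bp if total_bp else 0.0
    truth.deleted_genes = sorted(deleted)
    return pairs, truth


# ---------------------------------------------------------------------------
# Variants


def _random_cds_snv(
    tx: TranscriptAnnotation,
    genome: GenomeAssembly,
    rng: np.random.Generator,
    used: Set[Tuple[str, int]],
) -> Optional[Tuple[str, int, str, str]]:
    """A random SNV inside the CDS of ``tx`` (past the start codon)."""
    pieces = tx.cds or []
    positions = [p for s, e in pieces for p in range(s, e)]
    if len(positions) < 10:
        return None
    for _ in range(50):
        pos0 = positions[int(rng.integers(3, len(positions) - 3))]
        if (tx.chrom, pos0) in used:
            continue
        ref = genome.fetch(tx.chrom, pos0, pos0 + 1)
        alts = [b for b in "ACGT" if b != ref]
        alt = alts[int(rng.integers(3))]
        used.add((tx.chrom, pos0))
        return tx.chrom, pos0 + 1, ref, alt
    return None


@dataclass
class VariantFixture:
    """Tumor/normal call sets plus catalogs, with annotations applied."""

    tumor: List[VariantRecord]
    normals: List[List[VariantRecord]]
    dbsnp: List[CatalogEntry]
    cosmic: List[CosmicEntry]
    truth: GroundTruth


def make_variants(
    config: SimConfig,
    refseq: Sequence[TranscriptAnnotation],
    genome: GenomeAssembly,
    rng: Optional[np.random.Generator] = None,
    truth: Optional[GroundTruth] = None,
) -> VariantFixture:
    """Plant germline and somatic variants with depth/catalog structure.

    Germline variants are shared by the tumor and every normal; somatic
    variants appear only in the tumor.  Somatic depths are drawn to pass
    the 50X/20X filter, except dedicated boundary cases planted just
    below each threshold.  The somatic-mutation catalog realises each
    match category (identical substitution+codon, substitution at a
    different codon, codon with a different substitution, no entry) on
    one planted missense variant each.
    """
    rng = rng or np.random.default_rng(config.seed + 3)
    truth = truth or GroundTruth(seed=config.seed)

    coding = [tx for tx in refseq if tx.cds and tx.transcript_id.endswith(".r1")]
    deleted = [tx.gene_id for tx in coding[-config.n_deleted_genes:]] if config.n_deleted_genes else []
    candidates = [tx for tx in coding if tx.gene_id not in deleted]
    used: Set[Tuple[str, int]] = set()

    def draw_depths(passing: bool = True) -> Tuple[int, int]:
        dp = int(rng.integers(60, 220))
        if rng.random() < 0.15:
            return dp, dp  # homozygous
        ad = int(np.clip(rng.binomial(dp, 0.5), 20, dp))
        return dp, ad

    germline: List[VariantRecord] = []
    for i in range(config.n_germline):
        tx = candidates[int(rng.integers(len(candidates)))]
        snv = _random_cds_snv(tx, genome, rng, used)
        if snv is None:
            continue
        chrom, pos, ref, alt = snv
        dp, ad = draw_depths()
        germline.append(VariantRecord(chrom, pos, ref, alt, dp, ad, sample_id="tumor"))

    # four dedicated COSMIC-category cases on distinct genes
    cosmic_entries: List[CosmicEntry] = []
    cosmic_cases: Dict[str, list] = {}
    somatic: List[VariantRecord] = []
    categories = ("substitution_and_location", "substitution_only", "location_only", "none")
    case_genes = candidates[: len(categories)]
    for cat, tx in zip(categories, case_genes):
        for _ in range(80):
            snv = _random_cds_snv(tx, genome, rng, used)
            if snv is None:
                break
            chrom, pos, ref, alt = snv
            dp, ad = draw_depths()
            rec = VariantRecord(chrom, pos, ref, alt, dp, ad, sample_id="tumor")
            ann = annotate_codon_change(rec, tx, genome)
            if ann.aa_change is None:
                continue
            ref_aa, codon, alt_aa = ann.aa_change
            if ref_aa == alt_aa or "*" in (ref_aa, alt_aa):
                used.discard((chrom, pos - 1))
                continue
            if cat == "substitution_and_location":
                cosmic_entries.append(CosmicEntry(tx.gene_id, ref_aa, codon, alt_aa, chrom, pos))
            elif cat == "substitution_only":
                cosmic_entries.append(
                    CosmicEntry(tx.gene_id, ref_aa, codon + 3, alt_aa, chrom, 0)
                )
            elif cat == "location_only":
                other = next(a for a in "ACDEFGHIKLMNPQRSTVWY" if a not in (ref_aa, alt_aa))
                cosmic_entries.append(
                    CosmicEntry(tx.gene_id, ref_aa, codon, other, chrom, pos)
                )
            somatic.append(ann)
            cosmic_cases[cat] = list(ann.key)
            break

    # remaining somatic passing variants
    while len(somatic) < config.n_somatic:
        tx = candidates[int(rng.integers(len(candidates)))]
        snv = _random_cds_snv(tx, genome, rng, used)
        if snv is None:
            continue
        chrom, pos, ref, alt = snv
        dp, ad = draw_depths()
        somatic.append(
            annotate_codon_change(
                VariantRecord(chrom, pos, ref, alt, dp, ad, sample_id="tumor"), tx, genome
            )
        )

    # boundary cases that must FAIL the 50X/20X filter
    somatic_fail: List[VariantRecord] = []
    for dp, ad in ((49, 30), (60, 19)):
        tx = candidates[int(rng.integers(len(candidates)))]
        snv = _random_cds_snv(tx, genome, rng, used)
        if snv is None:
            continue
        chrom, pos, ref, alt = snv
        somatic_fail.append(VariantRecord(chrom, pos, ref, alt, dp, ad, sample_id="tumor"))

    tumor = germline + somatic + somatic_fail

    normals: List[List[VariantRecord]] = []
    for ni in range(config.n_normals):
        label = f"normal{ni + 1}"
        recs = []
        for g in germline:
            dp, ad = draw_depths()
            recs.append(dataclasses.replace(g, total_depth=dp, alt_depth=ad, sample_id=label))
        normals.append(recs)

    # dbSNP-like catalog: a seeded fraction of germline and somatic keys
    dbsnp: List[CatalogEntry] = []
    member_keys = []
    rs = 1
    for rec in germline + somatic:
        if rng.random() < config.dbsnp_fraction:
            dbsnp.append(CatalogEntry(rec.chrom, rec.pos, rec.ref, rec.alt, f"rs{rs:06d}"))
            member_keys.append(list(rec.key))
            rs += 1

    truth.somatic_keys = sorted(list(r.key) for r in somatic)
    truth.somatic_fail_keys = sorted(list(r.key) for r in somatic_fail)
    truth.germline_keys = sorted(list(r.key) for r in germline)
    truth.dbsnp_member_keys = sorted(member_keys)
    truth.cosmic_cases = cosmic_cases
    truth.deleted_genes = sorted(deleted)
    return VariantFixture(tumor, normals, dbsnp, cosmic_entries, truth)


# ---------------------------------------------------------------------------
# Signature mixtures


def make_signature_catalog(
    n_signatures: int = 5,
    rng: Optional[np.random.Generator] = None,
    concentration: float = 0.3,
) -> SignatureCatalog:
    """A synthetic catalog of well-separated 96-context signatures.

    Each signature is a Dirichlet draw (sparse at low concentration, so
    signatures are nearly orthogonal and mixtures are identifiable).
    Names are Sig01, Sig02, ...
    """
    rng = rng or np.random.default_rng(0)
    sigs = {}
    for i in range(n_signatures):
        vec = rng.dirichlet(np.full(96, concentration))
        sigs[f"Sig{i + 1:02d}"] = vec / vec.sum()
    return SignatureCatalog(sigs)


def make_signature_mixture(
    weights: Dict[str, float],
    n: int,
    catalog: SignatureCatalog,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[List[VariantRecord], GenomeAssembly, GroundTruth]:
    """Draw n SNVs from a mixture of catalog signatures.

    Builds a dedicated single-chromosome genome hosting one planted
    trinucleotide context per SNV (contexts at stride 4, so neighbours
    never interfere), which lets the spectrum builder run end-to-end.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    total_w = sum(weights.values())
    if abs(total_w - 1.0) > 1e-9:
        raise ValueError("mixture weights must sum to 1")
    for name in weights:
        if name not in catalog.signatures:
            raise KeyError(f"unknown signature {name!r}")
    rng = rng or np.random.default_rng(0)

    mixture = np.zeros(96)
    for name, w in weights.items():
        mixture += w * catalog.signatures[name]
    mixture /= mixture.sum()
    counts = rng.multinomial(n, mixture)

    blocks: List[str] = []
    snv_plan: List[Tuple[int, str, str]] = []  # (block index, ref, alt)
    bi = 0
    for label, c in zip(CONTEXT_LABELS, counts):
        five, rest = label[0], label[2:]
        cls, three = rest[:3], label[-1]
        ref, alt = cls[0], cls[2]
        for _ in range(int(c)):
            blocks.append(five + ref + three + "A")
            snv_plan.append((bi, ref, alt))
            bi += 1
    chrom = "sim_spectrum"
    genome = GenomeAssembly(name="sigmix", chromosomes={chrom: "".join(blocks)})
    snvs = [
        VariantRecord(chrom, 4 * b + 2, ref, alt, 100, 50, sample_id="mixture")
        for b, ref, alt in snv_plan
    ]
    truth = GroundTruth(signature_weights=dict(weights))
    return snvs, genome, truth


def spectrum_from_mixture_counts(counts: np.ndarray, sample_id: str) -> MutationSpectrum:
    return MutationSpectrum(sample_id=sample_id, counts=np.asarray(counts, dtype=np.int64))


# ---------------------------------------------------------------------------
# End-to-end fixture emission


def simulate_fixture_set(config: SimConfig, out_dir: str | Path) -> GroundTruth:
    """Generate and write the full fixture family to ``out_dir``.

    Emits genome FASTA, refseq/ensembl GTF + BED12, target BED,
    alignment TSV, tumor and normal VCFs, dbSNP-like and COSMIC-like
    TSVs and the ground-truth ledger JSON.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    genome, truth = make_genome(config)
    rng_ann = np.random.default_rng(config.seed + 1)
    refseq, ensembl, genome = make_annotation(config, genome, rng_ann, truth)
    genome.to_fasta(out / "genome.fa")
    write_gtf(refseq, out / "refseq.gtf")
    write_gtf(ensembl, out / "ensembl.gtf")
    write_bed12(refseq, out / "refseq.bed12")
    write_bed12(ensembl, out / "ensembl.bed12")

    merged = merge_annotations(refseq, ensembl)
    exons = remove_contained_exons(merged)
    target_set = build_target_set(exons, genome=genome)
    target_set.write_bed(out / "targets.bed")

    fixture = make_variants(
        config, refseq, genome, np.random.default_rng(config.seed + 3), truth
    )
    pairs, truth = make_readpairs(
        config, target_set, genome, np.random.default_rng(config.seed + 2),
        truth, deleted_genes=fixture.truth.deleted_genes,
    )
    write_pairs_tsv(pairs, out / "pairs.tsv")
    contigs = {c: genome.length(c) for c in genome}
    write_vcf(fixture.tumor, out / "tumor.vcf", sample_id="tumor", contigs=contigs)
    for i, recs in enumerate(fixture.normals, start=1):
        write_vcf(recs, out / f"normal{i}.vcf", sample_id=f"normal{i}", contigs=contigs)
    write_dbsnp_tsv(fixture.dbsnp, out / "dbsnp.tsv")
    write_cosmic_tsv(fixture.cosmic, out / "cosmic.tsv")
    truth.to_json(out / "ground_truth.json")
    return truth
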