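"""Capture probe tiling, uniqueness and complexity filtering.

Probes are fixed-length (default 120 nt) genomic windows tiled
end-to-end across each target on the sense strand; the final probe of a
target is end-anchored so the target is always covered exactly.  A probe
is retained only if its sequence occurs exactly once in the genome
(both strands searched, zero mismatches), passes a DUST-style
low-complexity screen and contains no ambiguous base.
"""

from __future__ import annotations

import csv
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from intervaltree import IntervalTree

from .genome import GenomeAssembly, reverse_complement
from .targets import TargetInterval, TargetSet

DEFAULT_PROBE_LENGTH = 120
DEFAULT_COMPLEXITY_THRESHOLD = 7.0

STATUS_RETAINED = "retained"
STATUS_MULTI_MAP = "rejected_multi_map"
STATUS_LOW_COMPLEXITY = "rejected_low_complexity"
STATUS_AMBIGUOUS = "rejected_ambiguous_base"


@dataclass
class Probe:
    probe_id: str
    chrom: str
    start: int
    end: int
    sequence: str
    occurrence_count: int = 0
    complexity_score: float = 0.0
    status: str = STATUS_RETAINED

    @property
    def length(self) -> int:
        return self.end - self.start


def tile_target(
    target: TargetInterval,
    genome: GenomeAssembly,
    probe_length: int = DEFAULT_PROBE_LENGTH,
    tile_overlap: int = 0,
) -> List[Probe]:
    """Tile probes across one target interval.

    For a target of length ``L >= probe_length`` the step between probe
    starts is ``probe_length - tile_overlap`` (end-to-end by default; a
    1 nt overlap dialect is available via ``tile_overlap=1``) and the
    last probe is anchored at the target end.  A target shorter than the
    probe is covered by a single probe centred on it, shifted into
    chromosome bounds if necessary.
    """
    if probe_length < 1:
        raise ValueError("probe_length must be >= 1")
    if target.chrom not in genome:
        raise ValueError(f"target on unknown chromosome: {target.chrom}")
    chrom_len = genome.length(target.chrom)
    L = target.length
    step = probe_length - tile_overlap
    if step < 1:
        raise ValueError("tile_overlap must be smaller than probe_length")

    windows: List[Tuple[int, int]] = []
    if L >= probe_length:
        start = target.start
        while start + probe_length < target.end:
            windows.append((start, start + probe_length))
            start += step
        windows.append((target.end - probe_length, target.end))  # end-anchored
    else:
        center = (target.start + target.end) // 2
        start = center - probe_length // 2
        start = max(0, min(start, chrom_len - probe_length))
        start = max(0, start)
        end = min(start + probe_length, chrom_len)
        windows.append((start, end))

    probes = []
    for s, e in windows:
        seq = genome.fetch(target.chrom, s, e)
        probes.append(Probe(f"{target.chrom}:{s}-{e}", target.chrom, s, e, seq))
    return probes


def tile_target_set(
    target_set: TargetSet,
    genome: GenomeAssembly,
    probe_length: int = DEFAULT_PROBE_LENGTH,
    tile_overlap: int = 0,
) -> List[Probe]:
    probes: List[Probe] = []
    for t in target_set.targets:
        probes.extend(tile_target(t, genome, probe_length, tile_overlap))
    return probes


# ---------------------------------------------------------------------------
# Uniqueness


class OccurrenceIndex:
    """Seed-and-verify exact-match counter over both genome strands.

    A dictionary of fixed-length seed prefixes (forward strand only) maps
    to candidate start positions; a query verifies full-length matches of
    the query and of its reverse complement.  Self-overlapping
    occurrences count once per start position.
    """

    def __init__(self, genome: GenomeAssembly, seed_length: int = 12):
        self.genome = genome
        self.seed_length = seed_length
        self._index: Dict[str, List[Tuple[str, int]]] = defaultdict(list)
        for chrom, seq in genome.chromosomes.items():
            for i in range(len(seq) - seed_length + 1):
                seed = seq[i : i + seed_length]
                if "N" not in seed:
                    self._index[seed].append((chrom, i))

    def _count_forward(self, sequence: str) -> int:
        k = len(sequence)
        seed = sequence[: self.seed_length]
        count = 0
        for chrom, pos in self._index.get(seed, ()):
            if self.genome.chromosomes[chrom][pos : pos + k] == sequence:
                count += 1
        return count

    def count(self, sequence: str) -> int:
        if not sequence:
            raise ValueError("empty sequence")
        if "N" in sequence:
            raise ValueError("sequence contains ambiguous base N")
        if len(sequence) < self.seed_length:
            raise ValueError(
                f"sequence shorter than seed length {self.seed_length}"
            )
        return self._count_forward(sequence) + self._count_forward(
            reverse_complement(sequence)
        )


def count_genome_occurrences(
    sequence: str,
    genome: GenomeAssembly,
    index: Optional[OccurrenceIndex] = None,
) -> int:
    """Number of exact occurrences of ``sequence`` over both strands.

    With many queries against one genome, build an :class:`OccurrenceIndex`
    once and pass it in; otherwise a throwaway index is built.
    """
    if index is None:
        index = OccurrenceIndex(genome)
    return index.count(sequence)


# ---------------------------------------------------------------------------
# Complexity


def complexity_score(sequence: str) -> float:
    """DUST-style triplet score; higher means lower complexity.

    score = sum_t c_t (c_t - 1) / 2 / (w - 3) over all overlapping
    3-mers, with w the sequence length.  A poly-A 120-mer scores 59.0;
    a sequence with all distinct 3-mers scores 0.
    """
    w = len(sequence)
    if w < 4:
        raise ValueError("sequence must be at least 4 nt for a triplet score")
    counts: Dict[str, int] = defaultdict(int)
    for i in range(w - 2):
        counts[sequence[i : i + 3]] += 1
    return sum(c * (c - 1) / 2 for c in counts.values()) / (w - 3)


# ---------------------------------------------------------------------------
# Filtering and reporting


def filter_probes(
    probes: Sequence[Probe],
    genome: GenomeAssembly,
    complexity_threshold: float = DEFAULT_COMPLEXITY_THRESHOLD,
    index: Optional[OccurrenceIndex] = None,
) -> List[Probe]:
    """Set occurrence/complexity/status on every probe, order preserved.

    Retained iff the sequence is N-free, occurs exactly once genome-wide
    and its complexity score is at or below the threshold.
    """
    if index is None:
        index = OccurrenceIndex(genome)
    out = []
    for p in probes:
        q = Probe(p.probe_id, p.chrom, p.start, p.end, p.sequence)
        if "N" in q.sequence:
            q.status = STATUS_AMBIGUOUS
            q.occurrence_count = 0
            q.complexity_score = 0.0
        else:
            q.occurrence_count = index.count(q.sequence)
            q.complexity_score = complexity_score(q.sequence)
            if q.occurrence_count != 1:
                q.status = STATUS_MULTI_MAP
            elif q.complexity_score > complexity_threshold:
                q.status = STATUS_LOW_COMPLEXITY
            else:
                q.status = STATUS_RETAINED
        out.append(q)
    return out


@dataclass
class DesignReport:
    probes_total: int
    probes_retained: int
    percent_unique: float
    genes_total: int
    genes_with_any_probe: int
    genes_with_any_probe_pct: float
    genes_fully_covered: int
    genes_fully_covered_pct: float
    per_gene_probe_counts: Dict[str, int]


def design_report(probes: Sequence[Probe], target_set: TargetSet) -> DesignReport:
    """Gene-level coverage summary of a filtered probe pool.

    A gene counts as covered if at least one retained probe overlaps at
    least one of its targets, and fully covered if every one of its
    targets is overlapped by a retained probe.
    """
    retained = [p for p in probes if p.status == STATUS_RETAINED]
    trees: Dict[str, IntervalTree] = defaultdict(IntervalTree)
    for p in retained:
        trees[p.chrom][p.start:p.end] = True

    def covered(t: TargetInterval) -> bool:
        return t.chrom in trees and bool(trees[t.chrom].overlap(t.start, t.end))

    per_gene_counts: Dict[str, int] = {}
    genes_any = genes_full = 0
    for gene, gene_targets in target_set.genes.items():
        flags = [covered(t) for t in gene_targets]
        n_probes = 0
        for t in gene_targets:
            if t.chrom in trees:
                n_probes += len(trees[t.chrom].overlap(t.start, t.end))
        per_gene_counts[gene] = n_probes
        if any(flags):
            genes_any += 1
        if flags and all(flags):
            genes_full += 1

    n_genes = len(target_set.genes)
    total = len(probes)
    return DesignReport(
        probes_total=total,
        probes_retained=len(retained),
        percent_unique=100.0 * len(retained) / total if total else 0.0,
        genes_total=n_genes,
        genes_with_any_probe=genes_any,
        genes_with_any_probe_pct=100.0 * genes_any / n_genes if n_genes else 0.0,
        genes_fully_covered=genes_full,
        genes_fully_covered_pct=100.0 * genes_full / n_genes if n_genes else 0.0,
        per_gene_probe_counts=per_gene_counts,
    )


# ---------------------------------------------------------------------------
# I/O


def write_probe_fasta(probes: Iterable[Probe], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in probes:
            fh.write(f">{p.probe_id}|{p.status}\n{p.sequence}\n")


def write_retained_bed(probes: Iterable[Probe], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in probes:
            if p.status == STATUS_RETAINED:
                fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{p.probe_id}\t0\t+\n")


def write_design_report_tsv(report: DesignReport, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["metric", "value"])
        w.writerow(["probes_total", report.probes_total])
        w.writerow(["probes_retained", report.probes_retained])
        w.writerow(["percent_unique", f"{report.percent_unique:.1f}"])
        w.writerow(["genes_total", report.genes_total])
        w.writerow(["genes_with_any_probe", report.genes_with_any_probe])
        w.writerow(["genes_with_any_probe_pct", f"{report.genes_with_any_probe_pct:.1f}"])
        w.writerow(["genes_fully_covered", report.genes_fully_covered])
        w.writerow(["genes_fully_covered_pct", f"{report.genes_fully_covered_pct:.1f}"])
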