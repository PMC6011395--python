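"""Capture performance metrics from read-pair alignments.

The pipeline mirrors standard hybrid-capture QC: discard pairs whose
two ends map to different chromosomes (ambiguous with respect to the
single-locus probe criterion), mark PCR/optical duplicates by 5'
coordinates and orientation, then compute on-target fraction, per-base
target depth, breadth of coverage at fixed thresholds and coverage
uniformity histograms.

Alignments are accepted either as coordinate-sorted SAM/BAM (via pysam)
or as a plain 7-column TSV dialect::

    pair_id  chrom1  pos1  chrom2  pos2  read_length  orientation

with 0-based leftmost positions, orientation in {FR, RF, FF, RR}, and
``*``/``-1`` for an unmapped end.
"""

from __future__ import annotations

import csv
from collections import Counter, defaultdict
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats as _scipy_stats

from .targets import TargetSet

DEFAULT_BREADTH_THRESHOLDS = (1, 10, 20, 30, 50)


@dataclass
class ReadPairAlignment:
    pair_id: str
    chrom1: str
    pos1: int
    chrom2: str
    pos2: int
    read_length: int
    orientation: str = "FR"
    mapped1: bool = True
    mapped2: bool = True
    duplicate: bool = False

    def reads(self) -> List[Tuple[str, int, int]]:
        """Both read intervals as (chrom, start, end), mapped ends only."""
        out = []
        if self.mapped1:
            out.append((self.chrom1, self.pos1, self.pos1 + self.read_length))
        if self.mapped2:
            out.append((self.chrom2, self.pos2, self.pos2 + self.read_length))
        return out


# ---------------------------------------------------------------------------
# I/O

_TSV_COLUMNS = ["pair_id", "chrom1", "pos1", "chrom2", "pos2", "read_length", "orientation"]


def write_pairs_tsv(pairs: Iterable[ReadPairAlignment], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(_TSV_COLUMNS)
        for p in pairs:
            w.writerow([
                p.pair_id,
                p.chrom1 if p.mapped1 else "*",
                p.pos1 if p.mapped1 else -1,
                p.chrom2 if p.mapped2 else "*",
                p.pos2 if p.mapped2 else -1,
                p.read_length,
                p.orientation,
            ])


def read_pairs_tsv(path: str | Path) -> List[ReadPairAlignment]:
    pairs = []
    with open(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None:
            return []
        if header[0] != "pair_id":  # headerless file: treat first row as data
            fh.seek(0)
            reader = csv.reader(fh, delimiter="\t")
        for row in reader:
            if not row:
                continue
            pid, c1, p1, c2, p2, rl, orient = row[:7]
            pairs.append(
                ReadPairAlignment(
                    pair_id=pid,
                    chrom1=c1, pos1=int(p1),
                    chrom2=c2, pos2=int(p2),
                    read_length=int(rl),
                    orientation=orient,
                    mapped1=c1 != "*",
                    mapped2=c2 != "*",
                )
            )
    return pairs


def read_pairs_sam(path: str | Path) -> List[ReadPairAlignment]:
    """Pair primary alignments of a SAM/BAM file by query name."""
    import pysam

    ends: Dict[str, List] = defaultdict(list)
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for rec in fh:
            if rec.is_secondary or rec.is_supplementary:
                continue
            ends[rec.query_name].append(rec)

    pairs = []
    for qname, recs in ends.items():
        r1 = next((r for r in recs if r.is_read1), recs[0])
        r2 = next((r for r in recs if r.is_read2), recs[-1] if len(recs) > 1 else None)
        rl = r1.query_length or (r2.query_length if r2 is not None else 0) or 0
        m1 = not r1.is_unmapped
        m2 = r2 is not None and not r2.is_unmapped
        strand1 = "R" if (m1 and r1.is_reverse) else "F"
        strand2 = "R" if (m2 and r2.is_reverse) else "F"
        pairs.append(
            ReadPairAlignment(
                pair_id=qname,
                chrom1=r1.reference_name if m1 else "*",
                pos1=r1.reference_start if m1 else -1,
                chrom2=(r2.reference_name if m2 else "*"),
                pos2=(r2.reference_start if m2 else -1),
                read_length=rl,
                orientation=strand1 + strand2,
                mapped1=m1,
                mapped2=m2,
            )
        )
    return pairs


def read_pairs(path: str | Path) -> List[ReadPairAlignment]:
    path = Path(path)
    if path.suffix.lower() in (".sam", ".bam", ".cram"):
        return read_pairs_sam(path)
    return read_pairs_tsv(path)


# ---------------------------------------------------------------------------
# Filtering


@dataclass
class PairFilterResult:
    kept: List[ReadPairAlignment]
    discarded_cross_chromosome: List[ReadPairAlignment]
    discarded_unmapped: List[ReadPairAlignment]

    @property
    def n_kept(self) -> int:
        return len(self.kept)


def discard_cross_chromosome_pairs(
    pairs: Sequence[ReadPairAlignment],
) -> PairFilterResult:
    """Keep pairs with both ends mapped to the same chromosome.

    Pairs whose ends map to different chromosomes are ambiguous under
    the single-locus probe criterion and are discarded; pairs with an
    unmapped end are discarded and counted separately.
    """
    kept, cross, unmapped = [], [], []
    for p in pairs:
        if not (p.mapped1 and p.mapped2):
            unmapped.append(p)
        elif p.chrom1 != p.chrom2:
            cross.append(p)
        else:
            kept.append(p)
    return PairFilterResult(kept, cross, unmapped)


def mark_duplicates(
    pairs: Sequence[ReadPairAlignment],
) -> Tuple[List[ReadPairAlignment], float]:
    """Flag duplicate pairs by (chrom1, pos1, chrom2, pos2, orientation).

    Within each group the representative with the smallest pair_id stays
    unflagged.  Returns the flagged copies and the duplicate rate in
    percent of reads (2 reads per pair).
    """
    groups: Dict[tuple, List[ReadPairAlignment]] = defaultdict(list)
    for p in pairs:
        groups[(p.chrom1, p.pos1, p.chrom2, p.pos2, p.orientation)].append(p)

    flagged: Dict[str, bool] = {}
    for members in groups.values():
        members = sorted(members, key=lambda p: p.pair_id)
        flagged[members[0].pair_id] = False
        for m in members[1:]:
            flagged[m.pair_id] = True

    out = [replace(p, duplicate=flagged[p.pair_id]) for p in pairs]
    n_dup = sum(1 for p in out if p.duplicate)
    rate = 100.0 * n_dup / len(out) if out else 0.0
    return out, rate


# ---------------------------------------------------------------------------
# On-target and depth


def on_target_fraction(
    pairs: Sequence[ReadPairAlignment], target_set: TargetSet
) -> float:
    """Percent of reads overlapping >= 1 target base."""
    total = on = 0
    for p in pairs:
        for chrom, start, end in p.reads():
            total += 1
            if target_set.overlaps(chrom, start, end):
                on += 1
    return 100.0 * on / total if total else 0.0


class DepthProfile:
    """Per-base read depth over every target interval."""

    def __init__(self, target_set: TargetSet):
        self.target_set = target_set
        self.depths: List[np.ndarray] = [
            np.zeros(t.length, dtype=np.int64) for t in target_set.targets
        ]
        self._index = {id(t): i for i, t in enumerate(target_set.targets)}

    def add_read(self, chrom: str, start: int, end: int) -> None:
        for t in self.target_set.overlapping(chrom, start, end):
            i = self._index[id(t)]
            lo = max(start, t.start) - t.start
            hi = min(end, t.end) - t.start
            self.depths[i][lo:hi] += 1

    def all_depths(self) -> np.ndarray:
        if not self.depths:
            return np.zeros(0, dtype=np.int64)
        return np.concatenate(self.depths)

    @property
    def total_target_bases(self) -> int:
        return int(sum(len(d) for d in self.depths))

    def breadth_at(self, threshold: int) -> float:
        d = self.all_depths()
        if d.size == 0:
            return 0.0
        return 100.0 * float(np.count_nonzero(d >= threshold)) / d.size

    def breadth_table(
        self, thresholds: Sequence[int] = DEFAULT_BREADTH_THRESHOLDS
    ) -> Dict[int, float]:
        return {t: self.breadth_at(t) for t in thresholds}

    def mean_depth(self) -> float:
        d = self.all_depths()
        return float(d.mean()) if d.size else 0.0

    def median_depth(self) -> float:
        d = self.all_depths()
        return float(np.median(d)) if d.size else 0.0

    def gene_mean_depth(self, gene_id: str) -> float:
        """Mean depth over all target bases of one gene."""
        if gene_id not in self.target_set.genes:
            raise KeyError(f"gene {gene_id!r} has no targets")
        total = bases = 0
        for t in self.target_set.genes[gene_id]:
            i = self._index[id(t)]
            total += int(self.depths[i].sum())
            bases += len(self.depths[i])
        return total / bases if bases else 0.0


def depth_profile(
    pairs: Sequence[ReadPairAlignment],
    target_set: TargetSet,
    count_duplicates: bool = False,
) -> DepthProfile:
    """Per-target-base depth from read intervals (duplicates excluded
    unless ``count_duplicates``).  Mates both covering a base contribute 2."""
    profile = DepthProfile(target_set)
    for p in pairs:
        if p.duplicate and not count_duplicates:
            continue
        for chrom, start, end in p.reads():
            profile.add_read(chrom, start, end)
    return profile


def uniformity_histogram(profile: DepthProfile, bin_width: int) -> Dict[int, int]:
    """Base counts per depth bin; bin b covers depths [b*w, (b+1)*w)."""
    if bin_width < 1:
        raise ValueError("bin_width must be >= 1")
    d = profile.all_depths()
    hist: Dict[int, int] = {}
    if d.size == 0:
        return hist
    bins = d // bin_width
    for b, c in zip(*np.unique(bins, return_counts=True)):
        hist[int(b)] = int(c)
    return hist


# ---------------------------------------------------------------------------
# Chromosome distribution


@dataclass
class ChromosomeDistributionReport:
    item_counts: Dict[str, int]
    gene_counts: Dict[str, int]
    pearson_r: Optional[float]
    residuals: Dict[str, float]
    outliers: List[str]
    degenerate: bool = False


def chromosome_distribution(
    item_chroms: Sequence[str],
    gene_chroms: Sequence[str],
    residual_bound: float = 3.0,
) -> ChromosomeDistributionReport:
    """Compare per-chromosome item counts to gene counts.

    Expected item counts are proportional to gene counts; standardized
    residuals ``(obs - exp) / sqrt(exp)`` beyond ``residual_bound`` flag
    over/under-represented chromosomes.  With fewer than 2 chromosomes
    or zero variance the correlation is undefined and the report is
    marked degenerate.
    """
    items = Counter(item_chroms)
    genes = Counter(gene_chroms)
    chroms = sorted(set(items) | set(genes))
    iv = np.array([items.get(c, 0) for c in chroms], dtype=float)
    gv = np.array([genes.get(c, 0) for c in chroms], dtype=float)

    pearson = None
    degenerate = len(chroms) < 2 or iv.std() == 0 or gv.std() == 0
    if not degenerate:
        pearson = float(_scipy_stats.pearsonr(iv, gv)[0])

    residuals: Dict[str, float] = {}
    outliers: List[str] = []
    if gv.sum() > 0 and iv.sum() > 0:
        expected = iv.sum() * gv / gv.sum()
        for c, obs, exp in zip(chroms, iv, expected):
            if exp > 0:
                r = (obs - exp) / np.sqrt(exp)
            else:
                r = np.inf if obs > 0 else 0.0
            residuals[c] = float(r)
            if abs(r) > residual_bound:
                outliers.append(c)
    if degenerate:
        outliers = list(chroms)

    return ChromosomeDistributionReport(
        item_counts=dict(items),
        gene_counts=dict(genes),
        pearson_r=pearson,
        residuals=residuals,
        outliers=outliers,
        degenerate=degenerate,
    )


# ---------------------------------------------------------------------------
# Summary


@dataclass
class QcSummary:
    sample_id: str
    total_pairs: int
    kept_pairs: int
    discarded_cross_chromosome: int
    discarded_unmapped: int
    duplicate_rate_pct: float
    on_target_pct: float
    breadth_pct: Dict[int, float] = field(default_factory=dict)
    mean_target_depth: float = 0.0
    median_target_depth: float = 0.0


def qc_summary(
    pairs: Sequence[ReadPairAlignment],
    target_set: TargetSet,
    sample_id: str = "sample",
    thresholds: Sequence[int] = DEFAULT_BREADTH_THRESHOLDS,
) -> QcSummary:
    """Run the full QC chain: pair filtering, duplicate marking,
    on-target fraction (non-duplicate reads), depth and breadth."""
    filt = discard_cross_chromosome_pairs(pairs)
    marked, dup_rate = mark_duplicates(filt.kept)
    non_dup = [p for p in marked if not p.duplicate]
    on_target = on_target_fraction(non_dup, target_set)
    profile = depth_profile(marked, target_set)
    return QcSummary(
        sample_id=sample_id,
        total_pairs=len(pairs),
        kept_pairs=len(filt.kept),
        discarded_cross_chromosome=len(filt.discarded_cross_chromosome),
        discarded_unmapped=len(filt.discarded_unmapped),
        duplicate_rate_pct=dup_rate,
        on_target_pct=on_target,
        breadth_pct=profile.breadth_table(thresholds),
        mean_target_depth=profile.mean_depth(),
        median_target_depth=profile.median_depth(),
    )


def write_qc_summary_tsv(summary: QcSummary, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["metric", "value"])
        w.writerow(["sample_id", summary.sample_id])
        w.writerow(["total_pairs", summary.total_pairs])
        w.writerow(["kept_pairs", summary.kept_pairs])
        w.writerow(["discarded_cross_chromosome", summary.discarded_cross_chromosome])
        w.writerow(["discarded_unmapped", summary.discarded_unmapped])
        w.writerow(["duplicate_rate_pct", f"{summary.duplicate_rate_pct:.2f}"])
        w.writerow(["on_target_pct", f"{summary.on_target_pct:.2f}"])
        for t, b in summary.breadth_pct.items():
            w.writerow([f"breadth_{t}x_pct", f"{b:.2f}"])
        w.writerow(["mean_target_depth", f"{summary.mean_target_depth:.2f}"])
        w.writerow(["median_target_depth", f"{summary.median_target_depth:.2f}"])
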