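"""Published reference counts from a rat whole-exome capture study.

These are the variant-count summaries reported for a rat WES platform
evaluated on four chemically induced tumor cell lines (C6 glioma, FAT7
nasal squamous cell carcinoma, DSL-6A/C1 pancreatic acinar carcinoma,
NBTII bladder carcinoma) and pooled fresh-frozen (FF) and
formalin-fixed paraffin-embedded (FFPE) normal liver, at the stringent
calling thresholds of 50X total / 20X alternate depth.  They serve as
fixed inputs for arithmetic cross-checks of the toolkit's percentage
and split computations, and as reference regimes for the synthetic
generator.
"""

from __future__ import annotations

from typing import Dict, NamedTuple

from .variants import round_pct_half_up


class VariantCounts(NamedTuple):
    total: int
    annotated: int  # registered in the dbSNP-like catalog
    non_annotated: int


#: All exonic SNVs per sample (total, dbSNP-annotated, novel).
EXONIC_VARIANT_COUNTS: Dict[str, VariantCounts] = {
    "C6": VariantCounts(30_529, 15_945, 14_584),
    "FAT7": VariantCounts(24_167, 13_818, 10_349),
    "DSL-6A/C1": VariantCounts(22_060, 12_719, 9_341),
    "NBTII": VariantCounts(37_984, 18_121, 19_863),
    "FF": VariantCounts(22_685, 14_240, 8_445),
    "FFPE": VariantCounts(15_944, 10_193, 5_751),
}

#: Cell-line-specific variants (SNVs + indels) after subtracting
#: FF/FFPE normal-tissue variants.
CELL_LINE_SPECIFIC_COUNTS: Dict[str, VariantCounts] = {
    "C6": VariantCounts(5_387, 1_523, 3_864),
    "FAT7": VariantCounts(3_551, 1_211, 2_340),
    "DSL-6A/C1": VariantCounts(3_277, 1_069, 2_208),
    "NBTII": VariantCounts(10_123, 2_430, 7_693),
}


class DepthPair(NamedTuple):
    total_depth: int
    alt_depth: int


#: Sequencing depths of orthogonally validated driver mutations
#: (sample, gene, amino-acid change) -> (total depth, alternate depth).
VALIDATED_CALL_DEPTHS: Dict[str, DepthPair] = {
    "NBTII:Tp53:R211W": DepthPair(197, 113),
    "NBTII:Tp53:I230T": DepthPair(174, 90),
    "FAT7:Tp53:R271H": DepthPair(71, 71),
    "C6:Ncor1:E544D": DepthPair(194, 85),
    "NBTII:Pik3ca:M811T": DepthPair(227, 111),
    "C6:Pik3ca:C90Y": DepthPair(129, 62),
}


def annotated_percentages(counts: Dict[str, VariantCounts]) -> Dict[str, float]:
    """Recompute the catalog-annotated percentage column from raw counts."""
    return {
        sample: round_pct_half_up(c.annotated, c.total) for sample, c in counts.items()
    }


def non_annotated_percentages(counts: Dict[str, VariantCounts]) -> Dict[str, float]:
    return {
        sample: round_pct_half_up(c.non_annotated, c.total)
        for sample, c in counts.items()
    }


def total_across_samples(counts: Dict[str, VariantCounts]) -> VariantCounts:
    """Column sums across samples."""
    return VariantCounts(
        total=sum(c.total for c in counts.values()),
        annotated=sum(c.annotated for c in counts.values()),
        non_annotated=sum(c.non_annotated for c in counts.values()),
    )
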