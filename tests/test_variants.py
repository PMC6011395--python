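"""Depth filtering, catalogs, normal subtraction, codon annotation,
somatic-catalog matching and deletion calling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from exocapkit.genome import GenomeAssembly, reverse_complement
from exocapkit.qc import ReadPairAlignment, depth_profile
from exocapkit.targets import TargetInterval, TargetSet, TranscriptAnnotation
from exocapkit.variants import (
    CatalogEntry,
    CosmicEntry,
    VariantRecord,
    allele_fraction,
    annotate_codon_change,
    call_gene_deletion,
    call_zygosity,
    filter_by_depth,
    left_normalize,
    match_cosmic,
    read_vcf,
    restrict_to_targets,
    round_pct_half_up,
    split_by_catalog,
    subtract_normals,
    write_vcf,
)


def rec(chrom="chr1", pos=100, ref="A", alt="G", dp=100, ad=50, **kw):
    return VariantRecord(chrom, pos, ref, alt, dp, ad, **kw)


class TestVcfIO:
    def test_round_trip_is_identity_on_modeled_fields(self, tmp_path):
        rng = np.random.default_rng(1)
        records = []
        for i in range(100):
            dp = int(rng.integers(30, 300))
            records.append(
                rec(
                    chrom=f"chr{1 + i % 3}",
                    pos=100 + i * 7,
                    ref="ACGT"[i % 4],
                    alt="GTAC"[i % 4],
                    dp=dp,
                    ad=int(rng.integers(0, dp + 1)),
                    sample_id="s1",
                )
            )
        p = tmp_path / "x.vcf"
        write_vcf(records, p, sample_id="s1")
        back = read_vcf(p)
        key = lambda r: (r.chrom, r.pos, r.ref, r.alt, r.total_depth, r.alt_depth)
        assert sorted(map(key, back)) == sorted(map(key, records))

    def test_multiallelic_split_takes_matching_ad(self, tmp_path):
        vcf = (
            "##fileformat=VCFv4.2\n"
            "##contig=<ID=chr1>\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="GT">\n'
            '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="DP">\n'
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="AD">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts\n"
            "chr1\t50\t.\tA\tC,T\t.\tPASS\t.\tGT:DP:AD\t1/2:60:10,20,30\n"
        )
        p = tmp_path / "m.vcf"
        p.write_text(vcf)
        back = read_vcf(p)
        assert [(r.alt, r.alt_depth) for r in back] == [("C", 20), ("T", 30)]
        assert all(r.total_depth == 60 for r in back)

    def test_published_depth_convention(self, tmp_path):
        # a heterozygous call at DP=197 with ref,alt depths 84,113
        p = tmp_path / "one.vcf"
        write_vcf([rec(pos=56195619, ref="C", alt="T", dp=197, ad=113)], p)
        (r,) = read_vcf(p)
        assert (r.total_depth, r.alt_depth) == (197, 113)


class TestDepthFilter:
    @pytest.mark.parametrize(
        "dp,ad,passes",
        [(197, 113, True), (49, 30, False), (60, 19, False), (50, 20, True)],
    )
    def test_thresholds(self, dp, ad, passes):
        out = filter_by_depth([rec(dp=dp, ad=ad)])
        assert bool(out) is passes

    def test_idempotent_and_order_preserving(self):
        records = [rec(pos=i, dp=40 + i, ad=25) for i in range(30)]
        once = filter_by_depth(records)
        assert filter_by_depth(once) == once
        positions = [r.pos for r in once]
        assert positions == sorted(positions)


class TestAlleleFractionAndZygosity:
    @pytest.mark.parametrize(
        "dp,ad,af",
        [(197, 113, 0.574), (194, 85, 0.438), (100, 100, 1.000), (174, 90, 0.517)],
    )
    def test_af_half_up_3_decimals(self, dp, ad, af):
        assert allele_fraction(rec(dp=dp, ad=ad)) == af

    def test_af_undefined_at_zero_depth(self):
        with pytest.raises(ValueError):
            allele_fraction(rec(dp=0, ad=0))

    @pytest.mark.parametrize(
        "dp,ad,zyg",
        [(100, 100, "hom"), (197, 113, "het"), (100, 90, "hom"), (100, 89, "het")],
    )
    def test_zygosity_threshold_boundary(self, dp, ad, zyg):
        assert call_zygosity(rec(dp=dp, ad=ad)) == zyg


class TestCatalogSplit:
    def test_three_of_four_annotated(self):
        records = [rec(pos=p) for p in (10, 20, 30, 40)]
        catalog = [CatalogEntry("chr1", p, "A", "G", f"rs{p}") for p in (10, 20, 30)]
        annotated, novel, pct = split_by_catalog(records, catalog)
        assert len(annotated) == 3 and len(novel) == 1
        assert pct == {"annotated_pct": 75.0, "non_annotated_pct": 25.0}

    def test_empty_catalog(self):
        _, novel, pct = split_by_catalog([rec()], [])
        assert pct["annotated_pct"] == 0.0 and len(novel) == 1

    def test_partition_is_exhaustive(self):
        records = [rec(pos=p) for p in range(1, 20)]
        catalog = [CatalogEntry("chr1", p, "A", "G", "x") for p in range(1, 20, 3)]
        a, n, _ = split_by_catalog(records, catalog)
        assert len(a) + len(n) == len(records)

    def test_rounding_half_up(self):
        assert round_pct_half_up(1, 8) == 12.5
        assert round_pct_half_up(15945, 30529) == 52.2
        assert round_pct_half_up(2430, 10123) == 24.0


class TestNormalSubtraction:
    def test_set_difference(self):
        t = [rec(pos=1), rec(pos=2), rec(pos=3)]
        out = subtract_normals(t, [[rec(pos=2, sample_id="n")]])
        assert [r.pos for r in out] == [1, 3]

    def test_empty_normals_identity(self):
        t = [rec(pos=1)]
        assert subtract_normals(t, []) == t

    def test_variant_in_all_normals_removed_once(self):
        t = [rec(pos=5)]
        normals = [[rec(pos=5, sample_id=f"n{i}")] for i in range(8)]
        assert subtract_normals(t, normals) == []

    def test_result_subset_and_disjoint(self):
        rng = np.random.default_rng(0)
        tumor = [rec(pos=int(p)) for p in rng.choice(1000, 50, replace=False)]
        normals = [[rec(pos=int(p)) for p in rng.choice(1000, 30, replace=False)]]
        out = subtract_normals(tumor, normals)
        out_keys = {r.key for r in out}
        assert out_keys <= {r.key for r in tumor}
        assert not out_keys & {r.key for n in normals for r in n}


class TestLeftNormalize:
    genome = GenomeAssembly("g", {"chr1": "GGGCACACACTT"})

    def test_snv_unchanged(self):
        r = rec(pos=5, ref="A", alt="T")
        assert left_normalize(r, self.genome).key == r.key

    def test_deletion_shifts_left_through_repeat(self):
        # deleting "AC" from the CACACAC run: right-most spelling
        r = rec(pos=8, ref="CAC", alt="C", dp=100, ad=50)
        n = left_normalize(r, self.genome)
        # left-most equivalent spelling anchors just before the AC run
        assert (n.pos, n.ref, n.alt) == (3, "GCA", "G")

    def test_identical_spellings_compare_equal_after_normalization(self):
        a = left_normalize(rec(pos=6, ref="CAC", alt="C"), self.genome)
        b = left_normalize(rec(pos=8, ref="CAC", alt="C"), self.genome)
        assert a.key == b.key


def make_gene(chrom="chr1", start=10, strand="+", cds_seq="ATGCGTTAA"):
    """A single-exon gene whose CDS is written into a small genome."""
    pre = "GGTTGG" + "A" * max(0, start - 6)
    genomic = cds_seq if strand == "+" else reverse_complement(cds_seq)
    seq = (pre[:start] + genomic + "GGTTGGCCAA").upper()
    genome = GenomeAssembly("g", {chrom: seq})
    tx = TranscriptAnnotation(
        gene_id="gX", transcript_id="gX.t1", chrom=chrom, strand=strand,
        exons=[(start, start + len(cds_seq))], cds=[(start, start + len(cds_seq))],
    )
    return genome, tx


class TestCodonAnnotation:
    def test_missense_on_forward_strand(self):
        genome, tx = make_gene()
        # CDS ATG CGT TAA; offset 4 is the G of CGT; G->A gives CAT = H
        r = rec(pos=10 + 4 + 1, ref="G", alt="A")
        ann = annotate_codon_change(r, tx, genome)
        assert ann.aa_change == ("R", 2, "H")
        assert ann.codon_change == "cGt/cAt"

    def test_synonymous_change(self):
        genome, tx = make_gene()
        # third codon position T->A: CGT->CGA, both arginine
        r = rec(pos=10 + 5 + 1, ref="T", alt="A")
        ann = annotate_codon_change(r, tx, genome)
        assert ann.aa_change == ("R", 2, "R")
        assert ann.codon_change == "cgT/cgA"

    def test_reverse_strand_complements_variant(self):
        genome, tx = make_gene(strand="-")
        # genomic layout is revcomp(ATGCGTTAA) = TTAACGCAT at [10,19)
        # coding offset 4 (the G of CGT) sits at genomic position start + (8-4)
        gpos0 = 10 + (9 - 1 - 4)
        ref = genome.fetch("chr1", gpos0, gpos0 + 1)
        alt = reverse_complement("A")  # coding G->A is genomic C->T
        ann = annotate_codon_change(
            rec(pos=gpos0 + 1, ref=ref, alt=alt), tx, genome
        )
        assert ann.aa_change == ("R", 2, "H")
        assert ann.codon_change == "cGt/cAt"

    def test_stop_gain_renders_star(self):
        genome, tx = make_gene(cds_seq="ATGTGGTAA")  # M W *
        # TGG -> TGA (W -> *): position 5 of CDS, G->A
        r = rec(pos=10 + 5 + 1, ref="G", alt="A")
        ann = annotate_codon_change(r, tx, genome)
        assert ann.aa_change == ("W", 2, "*")

    def test_variant_outside_cds_left_unannotated(self):
        genome, tx = make_gene()
        r = rec(pos=3, ref=genome.fetch("chr1", 2, 3), alt="T" if genome.fetch("chr1", 2, 3) != "T" else "C")
        ann = annotate_codon_change(r, tx, genome)
        assert ann.aa_change is None and ann.codon_change is None

    def test_indel_gets_gene_but_no_codon(self):
        genome, tx = make_gene(cds_seq="ATG" + "CGT" * 5 + "TAA")
        base = genome.fetch("chr1", 13, 14)
        r = rec(pos=14, ref=base + genome.fetch("chr1", 14, 15), alt=base)
        ann = annotate_codon_change(r, tx, genome)
        assert ann.gene_id == "gX" and ann.codon_change is None

    @given(st.data())
    @settings(max_examples=60, deadline=None)
    def test_alt_codon_retranslates_to_alt_aa(self, data):
        from Bio.Seq import Seq

        rng_codons = st.sampled_from(
            [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
             if a + b + c not in ("TAA", "TAG", "TGA")]
        )
        n = data.draw(st.integers(2, 8))
        body = "".join(data.draw(rng_codons) for _ in range(n))
        cds = "ATG" + body + "TAA"
        strand = data.draw(st.sampled_from("+-"))
        genome, tx = make_gene(strand=strand, cds_seq=cds)
        offset = data.draw(st.integers(0, len(cds) - 1))
        ref_coding = cds[offset]
        alt_coding = data.draw(st.sampled_from([b for b in "ACGT" if b != ref_coding]))
        if strand == "+":
            gpos0 = 10 + offset
            ref_g, alt_g = ref_coding, alt_coding
        else:
            gpos0 = 10 + (len(cds) - 1 - offset)
            ref_g, alt_g = reverse_complement(ref_coding), reverse_complement(alt_coding)
        ann = annotate_codon_change(
            rec(pos=gpos0 + 1, ref=ref_g, alt=alt_g), tx, genome
        )
        ref_aa, codon_no, alt_aa = ann.aa_change
        # apply the alt codon back to the CDS and re-translate
        i = (codon_no - 1) * 3
        alt_cds = cds[:i] + ann.codon_change.split("/")[1].upper() + cds[i + 3 :]
        assert str(Seq(alt_cds[i : i + 3]).translate()) == alt_aa
        assert str(Seq(cds[i : i + 3]).translate()) == ref_aa


class TestCosmicMatch:
    catalog = [
        CosmicEntry("Tp53", "R", 271, "H"),
        CosmicEntry("Pik3ca", "M", 100, "T"),
        CosmicEntry("Clp1", "M", 417, "V"),
    ]

    def _r(self, gene, aa):
        return rec(gene_id=gene, aa_change=aa)

    def test_substitution_and_location(self):
        m = match_cosmic(self._r("Tp53", ("R", 271, "H")), self.catalog)
        assert m.category == "substitution_and_location"

    def test_substitution_only(self):
        m = match_cosmic(self._r("Pik3ca", ("M", 811, "T")), self.catalog)
        assert m.category == "substitution_only"

    def test_location_only(self):
        m = match_cosmic(self._r("Clp1", ("M", 417, "I")), self.catalog)
        assert m.category == "location_only"

    def test_gene_scoping(self):
        m = match_cosmic(self._r("OtherGene", ("R", 271, "H")), self.catalog)
        assert m.category == "none" and m.matched_entry is None

    def test_empty_catalog_none(self):
        assert match_cosmic(self._r("Tp53", ("R", 271, "H")), []).category == "none"

    def test_adding_own_triple_upgrades_to_full_match(self):
        r = self._r("Nf1", ("Q", 962, "*"))
        weak = self.catalog + [CosmicEntry("Nf1", "Q", 5, "*")]
        assert match_cosmic(r, weak).category == "substitution_only"
        full = weak + [CosmicEntry("Nf1", "Q", 962, "*")]
        assert match_cosmic(r, full).category == "substitution_and_location"

    def test_missing_annotation_rejected(self):
        with pytest.raises(ValueError):
            match_cosmic(rec(), self.catalog)


class TestGeneDeletion:
    def _profile(self, gene_depth, other_depth=80):
        ts = TargetSet(
            [
                TargetInterval("chr1", 0, 100, {"gDel"}),
                TargetInterval("chr1", 1000, 1100, {"gOk"}),
            ]
        )
        pairs = []
        for i in range(other_depth // 2):
            pairs.append(ReadPairAlignment(f"o{i}", "chr1", 1000, "chr1", 1000, 100))
        for i in range(gene_depth // 2):
            pairs.append(ReadPairAlignment(f"d{i}", "chr1", 0, "chr1", 0, 100))
        return depth_profile(pairs, ts, count_duplicates=True)

    def test_zero_coverage_deleted(self):
        prof = self._profile(0)
        assert call_gene_deletion("gDel", prof, 80) == "deleted"

    def test_low_fraction_deleted(self):
        prof = self._profile(2)
        assert call_gene_deletion("gDel", prof, 80) == "deleted"  # 2 < 4

    def test_half_coverage_not_deleted(self):
        prof = self._profile(40)
        assert call_gene_deletion("gDel", prof, 80) == "not_deleted"

    def test_unknown_gene_rejected(self):
        with pytest.raises(KeyError):
            call_gene_deletion("nope", self._profile(0), 80)


class TestExonicRestriction:
    def test_positions_outside_targets_dropped(self):
        ts = TargetSet([TargetInterval("chr1", 99, 200, {"g"})])
        inside = rec(pos=100)   # 1-based 100 == 0-based 99, first target base
        outside = rec(pos=99)
        edge = rec(pos=200)     # 0-based 199, last target base
        out = restrict_to_targets([inside, outside, edge], ts)
        assert [r.pos for r in out] == [100, 200]
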