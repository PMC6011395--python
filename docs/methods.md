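# Methods

This note documents the models and procedures implemented in
`exocapkit`, their assumptions, the parameters that matter, and the
choices made where the design was genuinely open.

## Target-set construction

Transcript annotations from two providers are reduced to a
non-redundant set of genomic intervals ("targets") to be captured.

* **Coordinates.** Everything internal is 0-based half-open. GTF/GFF3
  input (1-based closed) and BED12 (already half-open) are converted at
  the parsing boundary; BED block arithmetic uses
  `chromStart + blockStarts[i]`.
* **Merge policy.** Exact-duplicate exons across sources collapse into
  one record carrying both source labels. Ensembl entries of lncRNA or
  miRNA biotype are dropped when they overlap (≥ 1 bp, either strand)
  any refseq exon; capture baits hybridize either strand, so the
  overlap test is strand-agnostic. The rule is evaluated **per exon**
  by default; a `per_transcript` switch in `MergePolicy` drops the
  whole transcript when any of its exons overlaps, since either reading
  of "no overlap" is defensible.
* **Containment removal.** An exon completely contained in a strictly
  longer exon on the same chromosome is removed and its gene labels are
  transferred to the container, so the covered base set and the gene
  roster are invariant under the operation. Equal intervals are
  collapsed (never mutually removed — that would lose coverage). The
  implementation is a per-chromosome sweep over intervals sorted by
  (start asc, end desc); the unit tests check it against an O(n²)
  brute-force containment scan and verify idempotence.
* **UTRs.** Exons from transcript annotations already include UTRs;
  `include_utr=False` intersects exons with their CDS pieces when CDS
  information is present, and keeps CDS-less exons (retained
  non-coding RNAs) whole.

## Probe design

* **Tiling.** Probes are fixed-length windows (default 120 nt, the
  standard RNA-bait length) laid end-to-end along the sense strand.
  For a target of length L ≥ P the probe count is ⌈L/P⌉, with the final
  probe end-anchored so that coverage of the target is exact; targets
  shorter than P receive one centred probe, shifted into chromosome
  bounds when necessary. A `tile_overlap` option supports the 1-bp
  overlap dialect (step P−1) used by some capture designs; end-to-end
  is the default because it is the plainer operational description.
* **Uniqueness.** A probe is rejected as multi-mapping unless its
  sequence occurs exactly once in the genome, counting exact
  (0-mismatch) matches over both strands, with self-overlapping
  occurrences counted at each start. The production path is a
  seed-and-verify index (12-mer prefix dictionary over the forward
  strand; queries verify the full probe and its reverse complement);
  tests compare it against an independent sliding-window scan.
  Near-exact (k > 0 mismatch) mappability is deliberately out of scope.
* **Complexity.** Low-complexity probes are rejected by a DUST-style
  triplet score, Σ c_t(c_t−1)/2 / (w−3), above a threshold of 7.0 by
  default. The threshold is a scale choice, not a fitted value: a
  poly-A 120-mer scores 59.0, a perfect dinucleotide repeat ≈ 29.3, and
  random 42%-GC sequence scores ≈ 1, so 7.0 cleanly separates simple
  repeats from typical exonic sequence. It is exposed as a parameter.
* **Reporting.** A gene counts as covered when ≥ 1 retained probe
  overlaps ≥ 1 of its targets, and fully covered when every target of
  the gene is overlapped — the two gene-level statistics a capture
  design is judged by.

## Capture QC

* **Pair filtering.** Pairs whose ends map to different chromosomes are
  ambiguous under the single-locus probe criterion and are discarded;
  pairs with an unmapped end are discarded and counted separately.
* **Duplicates.** Duplicate groups share (chrom1, pos1, chrom2, pos2,
  orientation) — standard 5'-coordinate MarkDuplicates semantics. The
  member with the smallest pair id stays unflagged, which makes the
  operation input-order invariant. The duplicate rate is reported in
  percent of reads (two reads per pair).
* **On-target.** A read is on-target iff it overlaps ≥ 1 target base
  (no padding by default; a pad option exists because some vendors
  count near-bait reads). Reported over non-duplicate reads.
* **Depth and breadth.** Per-base depth counts read intervals
  (mates both covering a base contribute 2, matching per-base pileup
  semantics). Breadth at threshold t is the percent of target bases at
  depth ≥ t, reported at 1X/10X/20X/30X/50X; the depth histogram
  partitions target bases by depth bin.
* **Chromosome distribution.** Item counts per chromosome are compared
  to gene counts per chromosome via Pearson correlation and
  standardized residuals (obs − exp)/√exp with expectation proportional
  to gene counts; chromosomes beyond a residual bound (default 3) are
  flagged. Degenerate inputs (one chromosome, zero variance) yield an
  undefined correlation and are flagged wholesale.

## Variant filtration and matching

* **Thresholds.** Defaults DP ≥ 50 and AD ≥ 20 — the stringent regime
  the platform this package reimplements settled on for discriminating
  sensitivity and accuracy. The depth filter runs **before** normal
  subtraction by default (both orders are trivially composable from the
  library functions; subtraction is key-based and order-independent in
  the planted fixtures).
* **Keys.** All set operations use (chrom, pos, ref, alt); rsIDs are
  annotation output only, since position+alleles is what sequencing
  observes. Multi-allelic records are split on read; indels are
  left-normalized (trailing/leading shared bases trimmed, extending
  left through reference context) so equivalent spellings compare
  equal.
* **Normal subtraction** removes a tumor variant present in *any*
  normal sample set, genotype-agnostically — the conservative union
  filter.
* **Zygosity.** hom iff AF ≥ 0.9 on the unrounded ratio; reported AFs
  are rounded half-up to 3 decimals, percentages half-up to 1 decimal.
* **Codon annotation.** A minimal annotator on explicit gene models
  replaces a full effect-prediction stack: SNVs inside a CDS (length
  divisible by 3) are translated with the standard code; on
  reverse-strand genes the codon is read on the coding strand with the
  variant base complemented. The codon string is rendered lower-case
  with the mutated position upper-case in both alleles (`cGt/cAt`).
  Indels are assigned to their gene but not codon-annotated.
* **Catalog matching.** Within the same gene, match categories in
  decreasing strength: identical (aa_ref, codon, aa_alt) triple; same
  (aa_ref, aa_alt) at a different codon; same (aa_ref, codon) with a
  different alternate; none. The strongest available category wins.
* **Deletion calling.** A gene is called homozygously deleted when its
  mean depth over all target bases is below 5% of the sample median
  depth — a deliberately simple rule for the extreme (near-zero
  coverage) events it is meant to flag, not a general CNV caller.

## Mutation spectra

* 96 contexts (6 pyrimidine-strand substitution classes × 4 × 4
  flanks), class-major ordering. Purine-reference SNVs are
  reverse-complemented together with their context; the suite verifies
  the involution property (flipping the reported strand of every input
  leaves the spectrum unchanged). A 6-class collapse is provided for
  summary plots.
* Divergences use a pseudocount (default 1e-6, added to every cell and
  renormalized) so sparse spectra have finite KL; the symmetrized form
  ½(KL(p‖q)+KL(q‖p)) is the default because neither sample is a
  privileged reference. Both the direction and the smoothing are
  exposed.
* Clustering is agglomerative (average linkage by default, complete
  available) on the symmetrized-KL matrix; samples are sorted
  lexicographically before linkage so tie-breaking is deterministic and
  input-order invariant. Signature ranking uses cosine similarity
  (descending) or symmetrized KL (ascending) against a catalog of
  96-dim probability vectors.
* Both 96-context and 6-class comparisons are supported; the
  96-context space is the default since signature catalogs are defined
  there.

## Synthetic data

The generator plants every quantity the downstream modules measure and
records it in a `GroundTruth` ledger:

* **Genome:** i.i.d. bases at 42% GC (typical mammalian exome
  neighborhood) over two chromosomes of 120 kb + 80 kb by default —
  large enough for ~30 multi-exon genes and small enough that the whole
  suite runs in seconds. Duplicated segments (2 × 500 bp) are copied
  verbatim to second loci so probes tiled there multi-map.
* **Annotation:** ~30 genes with 2–5 exons of 90–360 nt; every CDS
  starts with ATG, ends with a stop, has no internal stop and length
  divisible by 3 (the generator writes the coding sequence into the
  genome). Planted merge cases: cross-source duplicate transcripts,
  exons nested inside longer exons, ensembl-only lncRNAs both
  overlapping refseq exons (dropped) and intergenic (retained).
* **Reads:** 101-nt FR pairs (fragment 180 ± 25 nt), 80% on-target,
  23% duplicates — the fresh-frozen regime of the motivating platform;
  `ffpe_mode` switches to 130-nt fragments, 70% on-target and 45%
  duplicates, the formalin-fixed contrast. Duplicates are literal
  re-emissions of existing pairs; on-target pairs are placed so both
  mates overlap a target and off-target fragments are
  rejection-sampled clear of all targets, so the planted rates are
  exact expectations. The ledger records the *realised* mean target
  depth from per-read overlap accounting, which the depth profiler
  must reproduce.
* **Variants:** 30 germline variants shared by tumor and all 8 normals,
  12 tumor-only somatic variants with depths drawn to pass 50X/20X,
  plus dedicated boundary cases (DP=49/AD=30 and DP=60/AD=19) that must
  fail. The somatic catalog is constructed to realise each match
  category exactly once on a planted missense variant. Two genes are
  "deleted": no variants and zero read coverage.
* **Signature mixtures:** n SNVs drawn from a weighted mixture of
  catalog signatures, hosted on a purpose-built chromosome with one
  planted trinucleotide per SNV at stride 4 (neighbours cannot
  interfere), so the spectrum builder runs end-to-end on them.

**What the synthetic data does not emulate:** sequencing errors and
base qualities, GC-dependent capture bias, insert-size/selection
artifacts beyond the fragment-length shift, FFPE chemical damage
(C>T deamination is available only as an explicit spectrum flag, off by
default), alignment ambiguity, and multi-sample germline structure.
Passing tests therefore demonstrate the correctness of the
*computations* under clean planted conditions, not robustness to the
noise profile of real libraries.

## Numerical and formatting choices

* Percentages are rounded half-up to 1 decimal, allele fractions
  half-up to 3 decimals (`decimal.Decimal`, not banker's rounding), to
  match how such tables are conventionally printed.
* Spectrum frequency vectors are float64; signature catalogs validate
  Σ = 1 ± 1e-6; smoothed KL uses `scipy.special.rel_entr`.
* The occurrence index requires queries of at least the seed length
  (12); probe sequences with N are rejected before counting.
* Alignment fixtures use a 7-column TSV dialect (pair id, two
  chrom/pos pairs, read length, orientation) as the canonical test
  interface, with SAM/BAM accepted through pysam, so no binary files
  are needed anywhere in the test suite.

## Known limitations

* Uniqueness is exact-match only; a probe unique at 0 mismatches may
  still cross-hybridize at 1–2 mismatches.
* The codon annotator handles SNVs on single-transcript models; it does
  not annotate splice-region effects, multi-codon substitutions or
  frameshift consequences.
* The deletion caller is a threshold rule on mean gene depth; it has no
  segmentation and cannot detect partial-gene or heterozygous losses.
* `mark_duplicates` assumes unique pair ids within one input (true for
  all readers in this package).
* Scale: the toolkit holds genomes and indexes in memory. It is
  comfortable at the tens-of-megabases scale; a full mammalian
  genome-wide uniqueness scan would want an FM-index-backed
  implementation behind the same interface.
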