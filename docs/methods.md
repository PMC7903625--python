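# Methods

## Problem and model

`varbench` characterizes the analytical performance of a germline
small-variant calling assay by scoring a query VCF against a gold-standard
truth set (truth VCF plus high-confidence regions, e.g. GIAB) inside one or
more regions of interest (ROIs). Every comparison yields per-record
decisions — true positive (TP), false positive (FP), false negative (FN),
or unknown (UNK, outside the evaluation region) — and per-stratum metrics:

    precision       = TP / (TP + FP)                 (query-side TP)
    recall          = TP / (TP + FN)                 (truth-side TP)
    TN              = region bases − (TP + FP + FN)
    total negatives = TN + FP
    NPA             = TN / total negatives

NPA (negative percent agreement) is the specificity surrogate recommended
for clinical assay validation: with true negatives defined per reference
base rather than per assayable position, it is the only tractable
specificity notion for a sequencing assay. Strata are sample × region ×
variant type (SNP, MNP, InDel) × InDel size bin.

TP is tallied twice, on the query side (precision numerator) and the truth
side (recall numerator). The two coincide except when representation
differences match one truth record to several query records (an MNP vs.
its component SNPs), where a single "TP" column would be ambiguous.

## Haplotype-equivalence matching

The same variant can be spelled many ways in VCF. The match engine treats
two callsets as concordant over a locus when they imply the same local
haplotype sequences, in five steps:

1. **Decomposition.** Multi-allelic records are split into biallelic
   records per genotype-carried allele; genotypes are recoded onto {0, 1}.
   Hom-ref leftovers are dropped.
2. **Normalization.** Shared trailing then leading allele bases are
   trimmed (keeping one base per side for InDels) and length-changing
   variants are left-aligned by iterated left shift — the standard
   vt/`bcftools norm` algorithm. The result is parsimonious, left-most,
   and idempotent. REF alleles are checked against the reference sequence;
   a mismatch is a hard error naming the site.
3. **Clustering.** Truth and query records whose reference footprints lie
   within `cluster_window` (default 30 bp) of each other are grouped by
   transitive closure into paired clusters. 30 bp covers the assay's
   reportable InDel range (1–20 bp) with margin while keeping clusters
   small. Clusters whose per-side size exceeds `max_cluster_size`
   (default 8, bounding enumeration at 2^7 phasings per side) are split
   at the largest internal gap — left-most on ties, for determinism — and
   flagged.
4. **Haplotype enumeration.** For each side of a pair, every phase
   assignment consistent with the genotypes (unphased hets free, phased
   hets fixed, hom-alts on both haplotypes) is applied to the reference
   span, producing a set of unordered haplotype-sequence pairs.
   Assignments that stack overlapping alleles on one haplotype are
   skipped; a cluster with no consistent assignment falls back to exact
   matching with a warning.
5. **Decision.** If the truth and query spelling sets intersect, all
   members on both sides are TP. A truth-only cluster is FN; a query-only
   cluster is FP. Discordant two-sided clusters fall back to exact
   (chrom, pos, ref, alt) matching, where an allele match with a zygosity
   mismatch counts one FN *and* one FP — no partial credit.

This is a local re-implementation of the comparison contract that
haplotype-aware comparators such as hap.py and vcfeval provide; it does
not reproduce any particular tool's global haplotype-graph search, and for
clusters within the enumeration bound it is verified in the tests against
an independent exhaustive phasing enumeration.

### Evaluation region and UNK

The evaluation region is `high-confidence ∩ ROI` (or the ROI alone when no
confidence regions are given; an empty intersection is a configuration
error). A record counts only when its normalized footprint is *fully
contained* in the evaluation region; anything else is UNK — written to the
annotated output VCF but excluded from every tally. Full containment is
the conservative reading for boundary-straddling records and makes
eligibility independent of match outcomes.

Query records failing FILTER are excluded by default (`--all-records`
includes them); truth records are accepted regardless of FILTER, since
truth sets commonly carry half-calls and evaluation is already restricted
to their confidence regions. Records with missing genotypes are dropped
with a logged count. Contig naming is strict by default; an optional
harmonization flag strips the `chr` prefix on read, and disjoint contig
namespaces between inputs are a hard error rather than a silent zero.

## Region algebra

Regions are merged, sorted interval sets over 0-based half-open
coordinates with a derived total base count. Book-ended intervals merge
(`bedtools merge` semantics) — the stable convention for reproducible base
counts, and conservative for NPA. Padding (default 20 bp, the splice-site
flank) clamps at zero and at contig ends when lengths are known. The
clinically relevant ROI is built by selecting exon intervals that contain
at least one known pathogenic site (1-based sites converted to 0-based in
a single audited function — the classic off-by-one lives in exactly one
place), padding the selection, and unioning deep-intronic regions
unpadded. Inclusion–exclusion over randomized interval sets serves as the
algebra's oracle in the tests.

## Metrics, bins, rendering

InDel size is |len(alt) − len(ref)| after normalization; 0 marks SNP/MNP
records, which are excluded from size bins. Default bins: 1–10, 11–20,
21–50, >50 bp. Coarser report bins (e.g. 1–20) must be unions of base
bins; their metrics are recomputed from summed counts, never averaged
percentages. Undefined ratios (0/0 strata) render as `NA` — reporting 0
or 100 would bias small strata. Values are stored at full precision;
rendering rounds half-up to 2 decimals, and NPA renders as an integer by
default (matching how clinical-exome-scale NPA is conventionally printed;
at ~10⁷ negatives it is indistinguishable from 100 at two decimals).

## Truth-variant verification

Clinical assertions (sample, chrom, pos, ref, alt, optional genotype) are
verified with the same machinery: the normalized assertion is clustered
with nearby query records, query phasings are enumerated, and the verdict
is **Yes** when one query haplotype spells exactly the assertion-applied
reference over the shared span. Genotype is checked only when the
assertion specifies one (then the full unordered haplotype pair must
match). Adjacent assertions are verified independently — co-occurrence on
one haplotype is not required. A query call that bundles the asserted
change with additional changes in one record (e.g. an MNP superset) is
treated as a different variant and not credited; separate nearby records
are handled by the phasing enumeration.

## Synthetic fixtures

The generator emulates the benchmark's inputs at desk scale: a random
reference contig (default 24 kb), truth/query VCFs with planted structure,
confidence/ROI BEDs, and an assertions table. Planted TPs can be
re-represented in the query without changing the implied haplotypes:
shared-base allele padding, right-shifted deletions inside planted
homopolymer runs, and adjacent truth SNP pairs joined into one query MNP.
Query-only, truth-only and outside-ROI records plant FP, FN and UNK
labels. Variants sit on a jittered raster (default spacing 120 bp) so
distinct plants never share a cluster; genotypes are het with probability
0.6 by default. One `SeedSequence` per fixture spawns independent
sub-streams per concern, so identical configs are byte-identical and
adding one output kind does not reshuffle others.

What the fixtures do *not* emulate: alignment artifacts, systematic
context-dependent error modes (high-GC, STRs beyond simple homopolymers),
quality-score distributions, and real truth-set curation quirks. Passing
the fixture suite therefore demonstrates the *accounting* — matching,
stratification, arithmetic, reporting — is correct, not that any
particular assay performs well on real data.

The GeT-RM fixture plants the six validated pathogenic variants on short
toy contigs keeping chromosome names and the final digits of each GRCh37
position (offsets recorded in the manifest), so verification semantics can
be tested without genome-scale data.

## Orchestration and reproducibility

One YAML config drives the run: per sample × ROI, classify → annotated
VCFs (whole and split by variant type) → InDel spectrum (TSV + plot) →
metrics TSV; then one consolidated report with a provenance header (tool
version, config echo, MD5 checksum per input file) and the verification
table. The report carries no timestamps; identical inputs produce
byte-identical text outputs, which is asserted in the tests by running the
orchestrator twice. Stage failures are logged and flagged, and remaining
strata still run; the exit status reflects partial failure.

## Problem sizes and numerical choices

The test and acceptance workloads use 200 randomized fixtures of ~20–60
variants on 14 kb contigs, 25 perturbation-only fixtures, 250 randomized
matcher-oracle trials, and 200 interval-algebra trials — sizes chosen so
the whole suite completes in seconds while every planted case is checked
exactly (no tolerances anywhere in the synthetic path; published-table
arithmetic is checked at its printed 2-decimal precision). Degenerate
inputs are defined, not guessed: empty BED → empty region; empty stratum →
`NA` metrics; 0-length InDel bins rejected; negative derived TN rejected
as an input inconsistency.

## Known limitations

* Clusters larger than the enumeration bound fall back to exact matching
  after a deterministic split; dense multi-variant loci may therefore be
  scored more strictly than a global haplotype-graph comparison would.
* Structural variants, gVCF blocks, multi-sample cohort VCFs and CRAM/BAM
  are out of scope, as are quality-threshold ROC curves.
* Verification credits only haplotype spellings that equal the
  assertion-applied reference exactly over the local span (see above).
* Truth `truth_total` is derived as TP+FN; external comparators sometimes
  print truth totals that differ from their own TP+FN tallies, and no
  attempt is made to emulate that.
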