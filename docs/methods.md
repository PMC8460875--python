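# Methods

## Site model

A canonical binding site is defined strictly: a 7-nt stretch of 3′UTR that
is exactly reverse-complementary to the miRNA seed, nucleotides 2–8 of the
mature sequence (the 7mer-m8 class). Matching is exact Watson–Crick — no
G:U wobble, no mismatches, no 6mer/7mer-A1/8mer variants — because the
funnel this package implements is built on that stated rule. Scanning runs
in DNA space: UTRs are stored as DNA, and the seed is converted U→T when
the site pattern is built, so one alphabet serves the whole variant
pipeline. All overlapping occurrences are reported.

Consequences worth knowing: the model has no affinity scale (a site either
matches or it does not), so "disruption" is a discrete verdict, not a
repression magnitude; and pair hypotheses from external predictors may
legitimately have *zero* canonical sites in the annotated UTR (predictors
also use non-canonical evidence). Such pairs are retained and flagged
rather than dropped or guessed at.

## Coordinates and naming

Genomic coordinates are 1-based inclusive (VCF/GTF convention); 3′UTR
offsets are 0-based; `c.*` labels are 1-based from the first base after
the stop codon. The 3′UTR is all exonic sequence strictly 3′ of the stop
codon's last base, spliced across exons; one record is kept per transcript
(pair hypotheses are per-transcript), with the gene symbol carried for
aggregation. For minus-strand transcripts the UTR sequence is the reverse
complement of the concatenated genomic slices, and the offset map is a
bijection checked by round-trip tests. Transcript version suffixes are
stripped at load time by default (configurable), since pair lists and
annotations rarely agree on versions.

`TranscriptModel` carries an optional `cds_start_genomic` in addition to
the stop-codon anchor; it exists only to separate CDS from 5′UTR during
region classification. When absent, exonic positions 5′ of the stop are
classed CDS.

## Variant handling

VCF records are split per ALT allele. MAF precedence: an explicit `AF`
INFO annotation wins over a genotype-derived frequency (cases + controls
combined); the rare/common boundary is strict (`rare ⇔ MAF < 0.01`, so a
variant at exactly 1% is common). Region classification across transcripts
uses the precedence CDS > UTR3 > UTR5 > intron > upstream2kb > intergenic,
with every per-transcript hit retained so downstream counts are auditable.

Two normalization modes exist:

* `left_align` (default): minimal, left-aligned representation with one
  anchor base, verified against a brute-force enumerator of equivalent
  representations in the tests.
* `paper_1bp`: a compatibility mode for annotators that only accept 1-bp
  events. Multi-base indels are left-aligned once, then decomposed into
  consecutive 1-bp events anchored immediately after the variant position,
  conserving the inserted/deleted sequence. Events that are already 1-bp
  pass through unrepositioned — the mode is a formatting convention, not
  an aligner — which is what makes it idempotent.

## Disruption calling

A variant is translated into sense-strand UTR space (alleles complemented
and insertion points mirrored on minus-strand transcripts; edits spanning
splice junctions are rejected), applied to the UTR, and both alleles are
re-scanned from scratch. Overlap with a site is closed-interval
intersection of the edit footprint with the 7-base window; an insertion
counts only if its insertion point is strictly inside the window (an
insertion flush against either edge leaves the contiguous 7-mer intact).

Site correspondence across an indel uses offset identity adjusted by the
length shift: sites strictly 5′ of the edit keep their offsets, sites 3′
shift by `len(alt) − len(ref)`. A site that survives but shifts is
RETAINED — the biological site persists even though its coordinate moved
(e.g. a 1-bp deletion inside a homopolymer run holding overlapping sites).
LOST takes precedence over GAINED when one edit does both for the same
miRNA; both site lists are always reported.

GAINED calls are computed but excluded from the default funnel: stage 2
membership is defined by overlap with a *reference* site of a hypothesized
pair, which is how the emulated study counted. `include_gains` widens the
funnel to variants whose verdict is GAINED.

## Expression filtering

Input values are taken to be already log2-scale array signals, so the fold
change between populations is a difference, not a ratio — this reproduces
the packaged differential table's arithmetic exactly (7.908 − 6.294 =
1.614). "N.D." cells are stored as missing, never zero; a miRNA detected
in only one population has an undefined fold change but still belongs to
the differential set (POP1_ONLY / POP2_ONLY), and the reported
enriched/depleted totals include those one-sided calls, matching how such
tables are conventionally tallied. Detection is simply the presence of a
numeric value: array-level detection calls are upstream of this package
and are not modeled, which is also why the upstream detected-miRNA totals
(201/221) are not reproducible from the printed tables and are not
attempted.

## Pipeline

Stages run in order (3′UTR restriction → reference-site overlap →
expressed-miRNA filter → status/rarity filters), with each stage's variant
set tracked explicitly; monotonicity is asserted on the sets, not the
counts. Outputs are sorted by (gene, `c.*` label, miRNA), so input row
order cannot change any output byte. Joins between pair lists, miRNAs, and
transcripts tolerate a configurable fraction of unresolvable IDs (default
0: any join failure is an error). The final step of the emulated study —
an expert picking phenotype-consistent candidates from the filtered list —
has no algorithm to implement; the package applies only computable filters
and passes phenotype columns through for human review.

## Synthetic data

The generator emulates the study conditions end to end: a random genome
with plus- and minus-strand transcripts (spliced and unspliced UTRs, so
strand and splice logic is exercised by default), planted exact sites
written through the genomic coordinate map, a cohort of 412 cases and 213
controls with heterozygous carriers matching planted rarity (rare MAF ~
U(0.001, 0.009), common ~ U(0.05, 0.4)) and carriage (the disrupting
candidates are rare and case-only with 1–2 carriers, the pattern reported
for such candidates), and a two-population log2 expression table designed
to yield exactly 9 enriched-total and 7 depleted miRNAs at cutoff 1.0,
mirroring the reference table's totals.

Because matching is exact, planted truth is noiseless; difficulty is
injected through decoys instead of stochastic labels: near-miss 7-mers
(Hamming distance 1), siteless pair hypotheses, miRNAs not detected in the
target population, and variants outside UTRs. Every planted variant is
re-verified by naive substring scanning on the reference and mutated UTR
strings before it is accepted, and indel placements are checked to still
touch their site *after* left-alignment (a deletion in a repeat run can
slide out of a site; such placements are retried). A single integer seed
fully determines the bundle, byte for byte.

What passing tests on this generator do **not** show: behavior under
non-canonical sites, sequencing/genotyping error, population structure in
allele frequencies, or probe-level microarray noise — none of which the
deterministic site rule under test depends on.

## Numerical and scale choices

Default bundle sizes (8 transcripts, 300–600 nt UTRs, 24 miRNAs, 2 sites
per UTR, 15 variants) keep a full generate-plus-run cycle around 50 ms
while covering every code path (both strands, spliced UTRs, all three
variant types, all decoy classes); the acceptance script runs 10 bundles
plus 1,000 randomized scanner trials per invocation. Fold-change
comparisons against printed values use ±0.002 (printed columns are rounded
from unrounded signals). Expression deltas for planted enriched/depleted
miRNAs are drawn at least 0.3 above the cutoff so 3-decimal rounding can
never flip a class.

## Known limitations

* Only the strict 7mer-m8 rule is implemented; weaker site classes and
  context scoring are out of scope by design.
* No thermodynamic rescoring of mutant duplexes and no repression-magnitude
  prediction; wet-lab effect sizes are not computable here.
* Region classification of an indel uses its first affected base; an
  exotic deletion straddling a region boundary is classed by where the
  deletion starts.
* `c.*` labels for deletions spanning splice junctions are not emitted
  (the region class is still reported).
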