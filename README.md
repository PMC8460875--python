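# seedbreak

Find 3′UTR variants that break — or create — canonical microRNA binding
sites, and rank them against where the relevant miRNAs are actually
expressed.

## The problem

miRNAs repress genes mainly through Watson–Crick pairing between their
**seed** (nucleotides 2–8 of the mature sequence) and a complementary
7-mer in a transcript's 3′UTR (the 7mer-m8 site). A single-nucleotide
variant (SNV) or 1-bp indel inside such a site can abolish the pairing and
de-repress the gene; conversely, a variant can turn a near-miss 7-mer into
a new site. In cohort studies of congenital heart disease, candidate
variants of this kind are found by a staged funnel:

1. keep cohort variants that fall in annotated 3′UTRs;
2. keep those whose footprint intersects a canonical seed-match site of an
   externally predicted miRNA–transcript pair (prediction lists give pairs,
   not site coordinates, so sites are localized by scanning the UTR for the
   reverse complement of the seed);
3. keep pairs whose miRNA is detected in the cell population of interest
   (here: a cardiac neural-crest-cell expression profile vs its non-NCC
   control);
4. classify each surviving variant × miRNA as **LOST / GAINED / RETAINED /
   NONE** by re-scanning the mutated UTR, and report rare (MAF < 1%)
   candidates with their case/control carriage.

`seedbreak` implements this funnel as a tested, reusable library plus CLI:
strand-aware 3′UTR extraction and HGVS-style `c.*` naming, VCF ingestion
with left-aligned indel normalization (and a compatibility mode that
decomposes multi-base indels into 1-bp events), exact 7mer-m8 scanning,
disruption calling, log2 fold-change expression filtering, and a synthetic
truth-labeled data generator so every stage is testable without external
downloads. It also packages the profiled NCC/non-NCC miRNA tables used as
reference fixtures.

## Worked example

Generate a synthetic study (genome, transcripts, cohort VCF with 412 cases
and 213 controls, miRNAs, pair hypotheses, two-population expression table)
and run the funnel:

```bash
seedbreak simulate --out bundle --seed 1
cat > bundle/config.yaml <<EOF
genome: genome.fa
transcripts: transcripts.tsv
vcf: variants.vcf
mirnas: mirnas.tsv
pairs: pairs.tsv
expression: expression.tsv
groups: groups.tsv
expressed_population: pop1_ncc
EOF
seedbreak run --config bundle/config.yaml --out reports
```

which prints:

```
total_variants  15 variants
utr3_variants   11 variants
seed_site_overlap       7 variants      7 pairs
expressed_mirna 6 variants      6 pairs
candidates      6 variants      6 pairs
reports written to reports
```

The bundle plants 15 variants: 7 that destroy a seed site (one of them for
a miRNA not detected in the target population), 2 that create one, and 6
neutral decoys. The funnel narrows 15 → 11 (in a 3′UTR) → 7 (overlapping a
hypothesized pair's site) → 6 (miRNA expressed) → 6 candidates — exactly
the planted expressed LOST variants. `reports/candidates.tsv` begins:

```
gene    transcript  cstar_label  variant       mirna       status  rarity  n_case  n_control
GENE0   TX000       c.*44C>T     chr1:344C>T   syn-miR-08  LOST    rare    2       0
GENE2   TX002       c.*95A>G     chr1:1309A>G  syn-miR-07  LOST    rare    2       0
```

Each row is one variant × miRNA verdict: the `c.*` name locates the variant
within the UTR (1-based from the first base after the stop codon), `status`
is the site verdict, and `n_case`/`n_control` count carriers per cohort
group. Site-creating variants are computed but enter the funnel only with
`include_gains: true`.

In the library, the same run is three lines:

```python
from seedbreak.synthetic_data import FixtureSpec, generate_bundle, bundle_config
from seedbreak.pipeline import run

bundle = generate_bundle(FixtureSpec(), seed=1, outdir="bundle")
result = run(bundle_config("bundle"))
print(result.funnel.counts())   # {'total_variants': 15, ..., 'candidates': 6}
```

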