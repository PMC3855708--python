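# Methods

## The Seq-Walking model

Seq-Walking locates a transposon insertion that co-segregates with a
recessive mutant phenotype by comparing two DNA pools: homozygous mutant
plants and wild-type relatives from the same cross. Reads have the anatomy
`barcode + Mu TIR + genomic flank`; after decoding and TIR trimming, the
flank is what aligns to the reference.

The analysis rests on three assumptions:

- **Pool specificity.** An insertion present in both pools segregates
  independently of the phenotype and is discarded. Only mutant-specific
  sites can be causal.
- **Germinal vs. somatic read counts.** A heritable (germinal) insertion is
  carried by every cell of every pooled individual and accumulates a high
  flank read count; a somatic insertion exists in a sector of one plant and
  contributes on the order of one read. Ranking mutant-specific sites by
  read count therefore pushes somatic noise to the bottom.
- **Convergent evidence.** The causal site must fall in the genetic mapping
  interval (supplied externally, e.g. from bulked-segregant RNA-seq), and a
  loss-of-function insertion is expected to perturb its gene's expression,
  so sites in differentially expressed genes (DEGs) are promoted.

### Anchor coordinates and TSD pairing

Mu1 duplicates 9 bp of target sequence. The two flanks of one insertion
align on opposite sides of the TSD:

- a forward-strand flank ends at reference base `start − 1` and anchors the
  TSD's first base (`left` anchor = alignment end + 1);
- a reverse-orientation flank starts at `end + 1` and anchors the TSD's
  last base (`right` anchor = alignment start − 1).

Anchors collapse by exact position (an `anchor_slop` option, default 0,
relaxes this for noisy data), and a left/right pair satisfying
`right = left + tsd_span − 1` merges into one dual-anchor site whose
`[start, end]` covers the TSD and whose count is the sum of both flanks.
Unpaired anchors are kept as single-anchor sites (`start == end`); this is
the expected signature of count-1 somatic sites, where only one flank was
ever sequenced. Coordinates are 1-based inclusive throughout, matching
printed site tables. With slop 0 a left anchor can match at most one right
anchor; under slop > 0 ties go to the nearest candidate, then the lower
coordinate.

### Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `TirPattern.max_mismatches` | 0 | Hamming tolerance for the degenerate TIR match; the TIR is searched on the forward read orientation (library chemistry puts it at the read start), with an optional reverse-complement fallback |
| `min_length` | 91 bp | post-trim flank filter; "longer than 90 bp" is a strict inequality |
| `min_mapq` | 20 | "uniquely mapped" = primary alignment, MAPQ ≥ 20, and no secondary/supplementary alignment anywhere for that read (reads with any secondary hit are dropped entirely) |
| `tsd_span` | 9 bp | Mu1 target-site duplication; configurable for other elements |
| `anchor_slop` | 0 bp | anchor-collapse fuzz window |
| `min_count` | 2 | below this mutant read count a site is flagged probable-somatic and demoted, not removed — the count threshold separating germinal from somatic is a judgment call and the flag keeps the audit trail |
| DEG call | q ≤ 0.05 | a gene is differentially expressed at FDR 5%; `DegRecord.is_strong` additionally requires \|log2FC\| ≥ 4 |

Triage ordering is lexicographic: DEG-hitting sites first, then
non-somatic before somatic, then read count descending, then coordinate.
A candidate whose gene is not a DEG is reported but flagged low-confidence;
an empty DEG table degrades to count-only ranking with a warning.

The mapping-interval intersection uses any-overlap by default with a
`--strict` containment flag: published interval boundaries are typically
soft (printed site tables include marginal sites), so a hard boundary is
opt-in.

## EMS-allele triage

EMS alkylates guanine, producing almost exclusively G:C→A:T transitions.
On the reference strand this is `G→A` or `C→T` — the accepted 2 of the 12
possible substitution types; everything else (including all indels) fails
the EMS-typicality test but is still annotated, since spontaneous lesions
co-occur in allele collections.

Variants whose alternate allele is observed in any founder of a diversity
panel (≥ `min_support` reads, default 1) are standing variation and are
excluded; missing panel data never excludes, so exclusion is monotone in
the panel.

Effect annotation maps a position into the spliced CDS strand-aware,
re-translates the affected codon under the standard genetic code
(stops TAA/TAG/TGA), and reports:

- `PTC` (alt codon is a stop), `non_synonymous`, `synonymous` — with the
  1-based amino-acid position from the initiator methionine and the
  `(ref/alt)` change, printed in the field's `655AA(Q/PTC)` style;
- `UTR` / `intron` inside the gene span, `upstream` / `downstream` outside
  it (relative to transcription direction), with the genomic distance to
  the start codon (5′ side) or stop codon (3′ side);
- `frameshift` for indels landing in the CDS; indels are never EMS-flagged.

A spliced CDS whose length is not a multiple of 3 yields an annotation with
the `error` field set rather than a guess. A substitution in the natural
stop codon that destroys it is reported as `non_synonymous` with ref `*`
(stop-loss is not separated into its own category). Per allele, the "best"
lesion is chosen by severity `PTC > frameshift > non_synonymous >
exon_insertion > synonymous > non-coding`, and the summary counts alleles
whose best lesion is coding (PTC or non-synonymous) — the quantity a
cloning report quotes.

The packaged `gl13` allele table carries its printed lesion annotations;
`allele_report` consumes those directly when no reference genome is given,
and computes annotations from genome + gene models when it is. One printed
row gives an amino-acid position with no (ref/alt) pair; the report treats
a missing change as valid rather than inventing one.

## Expression arithmetic

- `rq`: RQ = 2^−ΔCt with ΔCt = Ct(target) − Ct(reference); strictly
  decreasing in ΔCt, and rq(ΔCt)·rq(−ΔCt) = 1.
- `rpkm`: count / (length/10³) / (library/10⁶); invariant under joint
  scaling of count and library size.
- `upper_quartile_factor`: the 0.75 quantile of a sample's per-gene count
  vector, with linear interpolation between order statistics (numpy's
  default); no convention is canonical, so the choice is fixed and
  documented here. An all-zero vector is an error, not a zero factor.
- `report_fraction`: 100·n/d rounded **half-up** (not banker's rounding),
  matching how percentages are printed in reports.

## The synthetic-data generator

`muwalk.simulate` emulates the statistical structure the method assumes,
with defaults set to the study's pool structure:

- **Reference**: 2 Mb random genome, 40 non-overlapping multi-exon genes
  (2–4 exons, 150–400 bp each) on both strands, every spliced CDS a valid
  `ATG…stop` with no internal stop by construction.
- **Insertions**: 471 mutant-pool and 251 wild-type-pool non-redundant
  sites with 82 shared (the published partition), sampled without
  replacement on a 25-bp spacing grid; each site carries a 9-bp TSD.
  `somatic_rate` (default 10 per pool) of the pool-specific sites are
  somatic with read count fixed at 1; germinal counts are negative
  binomial (mean 200, dispersion 2 — spanning the printed 23–727 range),
  conditioned on ≥ 1 read since a site is only catalogued because it was
  observed. No count distribution is published for either class; these are
  the package's choices.
- **Reads**: per germinal site the count splits binomially between the two
  flanks; every read is `barcode + a random TIR expansion + flank` with
  flank length uniform in 91–140 bp, so nothing is lost to the length
  filter by construction. Truth alignments are emitted as SAM records so
  the test path needs no aligner; a few multi-mapping read pairs exercise
  the uniqueness filter. An optional causal insertion is placed in an exon
  of a gene at the centre of the mapping interval, that gene is the only
  strong DEG, and no decoy lands in it.
- **EMS variants**: requested lesion categories are realized as transitions
  at codon positions that force the category (bounded retries), strand-aware
  on the genome; transversion decoys and founder-panel-shared decoys are
  added for the filters to reject.
- **Determinism**: one seed drives everything; written datasets are
  byte-identical across runs.

What the generator does **not** emulate: sequencing error and quality
decay, PCR duplicates and amplification bias, flow-space homopolymer
artefacts, repeat-induced multi-mapping structure, partial TIR matches,
and anchor jitter from soft-clipped alignments. Passing tests therefore
demonstrate the logic of the pipeline — coordinate arithmetic, pairing,
classification, ranking, annotation — not robustness to instrument noise;
on real data the `max_mismatches`, `anchor_slop` and `min_mapq` knobs exist
precisely because those effects appear.

## Problem sizes used in the test suite

The classification checks run at the full published scale (471/251/82
sites) since catalogs without reads are cheap. Read-level and end-to-end
tests use a scaled genome (150–400 kb, 8–12 genes, 60/25/8 sites, somatic
noise on) — the spec of the recovery experiment is "one causal insertion
in a DEG gene in the interval among ≥ 50 decoys", which these sizes
satisfy while keeping the suite fast. The 20-seed recovery check requires
the causal gene ranked first in ≥ 95% of runs; with the causal gene the
only DEG in the interval this is expected to fail only when the causal
site's drawn read count collapses to the somatic threshold, which is rare
under the count model.

## Known limitations

- Shared-site matching is exact-coordinate; a germinal site sequenced with
  anchor jitter in one pool would escape removal at slop 0.
- Exon numbering reports the first exon a site overlaps; a site spanning
  an exon boundary is attributed to the earlier exon in transcription
  order.
- `allele_report` assigns each variant to the nearest gene model within
  50 kb when annotating from sequence; overlapping genes on opposite
  strands are reported on the first model only, flagged ambiguous at the
  site level but not re-annotated per strand.
- The DEG table and mapping interval are consumed, never computed: the
  linkage statistic and the differential-expression test belong to the
  upstream experiments.
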