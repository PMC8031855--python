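# Methods

## The locus and the analysis model

*C9orf72* (chr9, minus strand, GRCh38) carries a GGGGCC hexanucleotide
repeat (HR) in intron 1, between two alternative first exons: exon 1a
(variants V1/V3; the HR is spliced out with intron 1) and exon 1b (variant
V2, the majority transcript, initiated downstream of the HR).  Pathological
expansion of the HR on the risk (R) haplotype changes how the expanded
allele is transcribed and spliced relative to the normal allele in the same
cell.  Every estimator in this package is therefore *within-cell and
between-allele*: the normal allele is the control, which removes
donor-to-donor genetic and technical variation.

Three measurement models are implemented.

### Haplotype signature calling

The eight common haplotypes are encoded as columns of a 105-marker allele
matrix (plus-strand bases exactly as tabulated; transcript bases are their
complements, applied once by `to_transcript_strand`).  A diploid genotype is
scored against all 36 unordered haplotype pairs; the mismatch count of a
pair is the number of genotyped markers whose observed allele pair cannot be
drawn from the two columns.  Sub-haplotype wildcard cells ("A/G") match
either base and are never counted as haplotype-specific.  All
minimum-mismatch pairs are returned — no arbitrary tie-break.  When the best
pure pair still leaves more than `hybrid_threshold` mismatches (default 3,
configurable; the tolerated mismatch count for real samples is not
documented anywhere authoritative), a recombinant chromosome is tried: one
switch point scanned along marker order between every ordered haplotype pair
against every pure partner, which captures the observed F→K hybrid type.
Multi-switch chromosomes are out of scope.

Indel and short-repeat markers are opaque tokens compared by string
equality; no sequence realignment is attempted.  Frequency prediction from
population marker frequencies averages a haplotype's specific-marker minor
allele frequencies; the Q haplotype (no specific markers) is predicted as a
shared-marker frequency minus the partner haplotype's frequency, floored at
zero.

### Peak-height allelic ratios

At a heterozygous site the two alleles superimpose two base peaks whose
heights carry a base-specific multiplicative incorporation bias.  Writing
`h_x(b)` for the height of base `b` in source `x`, the estimator is

    ratio = (h_cDNA(a)/h_cDNA(b)) / (h_gDNA(a)/h_gDNA(b))

Genomic DNA contains the two alleles 1:1 by construction, so any
multiplicative bias cancels exactly — an algebraic identity, which the
property tests assert for arbitrary bias.  Allele-specific background is
subtracted first (clipped at zero); a site whose background exceeds 30% of
the peak on either allele (configurable — the published exclusion rule
states "high background" without a number) is flagged excluded, never
silently dropped.  Multiple heterozygous sites of one amplicon are combined
by geometric mean, since allelic ratios compose multiplicatively; the
intron-retention ratio of an amplicon is the intronic geometric mean over
the exonic geometric mean.  Normalization happens per sequencing run, then
runs are averaged.  Calibration uses the proportion form p = r/(1+r) against
known mixture proportions, fitted by OLS (statsmodels); the expression-vs-
HR-length regression excludes samples whose repeat length is an intermediate
sawtooth call, because their length — hence the x-value — is uncertain.

### Read classification and coverage-equivalents

A read "spans" the exon-2 boundary if it covers the exon-2 first base
(transcript orientation, i.e. the exon's highest plus-strand coordinate)
with ≥ `min_anchor_bp` (default 1) exonic bases and continues past it.  A
read terminating exactly at the boundary carries no splicing evidence and is
`outside`.  Spanning reads are labelled by exactly one rule: a junction
whose acceptor is the boundary and whose donor matches a V1/V2/V3 donor →
`authentic`; matches a registry site within ±2 bp (softclip jitter; exact
matching by config) → `cryptic:Ck`; junction-free coverage across the
boundary → `unspliced`; anything else → `ambiguous`.

Boundary counts are per-base coverages at the boundary base, so they are
commensurable with the mean per-base coverage `A` over exons 2–5 (shared by
all variants, measured away from the coverage-biased 5' end).  Transcript
fractions follow by subtraction: normal = (A − U − C)/A, clamped at zero
with a warning if U + C > A.  Intron-retention scores are per-base intron
density over per-base exon 2–5 density; intron 1 is masked for its first
500 bp downstream of the HR, where antisense transcripts co-localize, and
only sense-strand reads are counted when the library is stranded (an
unstranded run proceeds with a warning).  The allelic fold decomposition is
total = (intron-1 reads, allele X / allele Y), expression = the same ratio
over the gene body excluding introns 1–2, splicing = total/expression — an
exact identity before rounding.  The joint intron-1+2 retention estimate is
the ratio of length-normalized intron densities capped at 1; it assumes
intron-2 retention occurs on intron-1-retaining transcripts (sequential
retention) and is flagged approximate — no exact published estimator exists
for it.

## The synthetic-data generator

The generator produces what each stage assumes, with the truth recorded:

* genotypes are the two haplotype columns, optionally corrupted per site;
* trace heights are `scale · p · bias + N(0, noise_sd · scale)` plus
  background, with gDNA encoding p = 0.5;
* fragment profiles put single peaks on the 118 + 6u grid; intermediates
  are unit-spaced runs with geometric height decay (ratio 0.75) around the
  modal unit;
* reads are drawn per allele from {authentic V1/V2/V3, unspliced intron 1
  ± intron 2, cryptic C1–C4} with class probability proportional to
  fraction × transcript length (sampling RNA mass, as rRNA-depleted
  libraries do), placed uniformly along the transcript, carrying the
  originating haplotype's base at every single-base marker overlapped.
  Antisense reads (plus strand) are confined to the intron-1 zone within
  500 bp of the HR, matching where antisense transcription is observed.

Default conditions are the measured study conditions: expanded-allele class
fractions (0.57, 0.31, 0.12), normal-allele (0.91, 0.08, 0.01), allelic
expression weights 1.9:1, joint intron-2 retention 0.4, read length 75
(the sequencing kit's cycle count), depth 5000 for recovery tests.  Splits
not pinned by any published number are fixed once at plausible values:
authentic variant mix V1:V2:V3 = 0.10:0.85:0.05 (V2 is reported at 85–95%
of transcripts), cryptic-site mix 0.4:0.3:0.2:0.1 (C1 nearest the active
donor used most), cryptic exon length 150 bp, fragment stutter decay 0.75.

What the generator does *not* emulate — sequencing error beyond none,
fragment-size distributions, mappability, PCR duplicates, coverage bias
along the transcript — bounds what the tests show: parameter recovery under
the model's own assumptions, not robustness to real-library artefacts.

## Packaged data and coordinates

The map fixture transcribes the published allele matrix, marker order and
haplotype-specific flags verbatim, but the per-marker chromosome 9
coordinates are **synthetic placeholders**: evenly spaced (259 bp) over the
GRCh38 gene span in printed order, decreasing along the table as the
minus-strand gene runs.  The spacing was chosen so the printed biological
context holds (rs10757668 lands 18 bp into exon 2, rs3849945 in intron 1,
rs13691/rs9103 in the 3'UTR exon).  The gene model likewise anchors every
printed coordinate — C1–C4 (and the V2 donor at chr9:27,573,431 they
imply), the HR location, strand and assembly — and fills the remaining exon
intervals with synthetic-realistic values; it is not a transcription of the
Ensembl annotation, and analyses of real alignments should load a real
annotation via `GeneModel.from_gff3`.  One printed inconsistency is kept
as printed: the C2 offset (910 bp) implies a V2 donor 1 bp away from the
other three sites' value, so registry offsets are validated to ±1 bp.

## Numerical choices and degenerate inputs

* Fragment sizing tolerates ±1 bp off-grid (capillary jitter); more is an
  error, not a rounding.  Sawtooth detection requires ≥ 5 consecutive peaks
  spaced 6 ± 1 bp above 10% of the maximum height (no published algorithm
  exists; both knobs are configuration).  Two equal-length alleles collapse
  to one peak and are reported as one homozygous length.
* A monoallelic cDNA trace yields ratio 0 or ∞ with a flag rather than an
  exception; zero gDNA height is an error.
* Diploid calling with zero informative sites returns all 36 pairs tied and
  flagged ambiguous.  Adding genotyped sites can only shrink the best-pair
  set (mismatch counts are sums over sites), which is asserted as a
  property test.
* The Welch t-test is available by flag but the default is the classic
  pooled-variance Student's test, matching the study's stated convention;
  p-values are raw, with no multiplicity correction, and labelled as such.
* Statistical test sizes: recovery tests run at 5,000 reads (boundary
  statistics then rest on ~10²  boundary reads, giving ±0.03 absolute
  resolution on class fractions and ±20% on allelic folds); the classifier
  oracle-equivalence test enumerates 200 reads against an independent
  rule-by-rule re-derivation.

## Known limitations

* Haplotype calling assumes "pure" haplotypes plus at most one switch
  point; no imputation, phasing or LD modelling.
* The joint intron-1+2 retention estimator is a documented density-ratio
  stand-in, exact only under sequential retention and uniform coverage.
* AB1 chromatogram parsing is out of scope: the ratio stage consumes peak
  height tables.
* Large expansions are inferred only negatively (an expected second allele
  that fails to amplify); Southern-blot sizing is out of scope.
* The packaged marker positions and filler exon coordinates are synthetic;
  any position-sensitive conclusion on real data requires the real
  annotation and marker coordinates.
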