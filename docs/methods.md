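# Methods

This note documents the models, conventions and numerical choices behind
ssr-popscan, and what the synthetic-data generator does and does not
emulate.

## Repeat detection

A microsatellite is modelled as a *perfect* maximal tandem run of a
primitive unit of 2–6 bp.  The scanner compares each base with the base one
period downstream (vectorised over the whole sequence), extracts maximal
match runs, trims them to whole units anchored at the leftmost full unit
(`floor(run/period) × period` bp), and reports a locus when the repeat count
reaches `max(3, ceil(10 / period))` — i.e. 5/4/3/3/3 repeats for periods
2–6, the counts implied by a 10 bp tract floor and a 3-repeat floor.
Real-genome surveys typically use Tandem Repeats Finder, which tolerates
impurity; perfect-run detection is deliberate here: it has an exact
specification, admits an independent brute-force oracle (tested on hundreds
of random sequences), and makes planted-truth recovery an exact test.
Counts on real genomes will therefore differ somewhat from TRF-based
catalogues.

Conventions that close ambiguities:

- **Canonical motif.** The representative of a unit's orbit under rotation
  and reverse complement is the lexicographic minimum; this reproduces the
  convention of writing classes as AC/GT, AAAT/ATTT with the smaller strand
  first.  Non-primitive units (ACAC, AAAAAA) are rejected; a run is only
  ever described at its smallest period, which also disposes of
  "ambiguous" multi-period descriptions of the same tract.
- **Overlaps.** Every locus sharing ≥ 1 bp with another is dropped — both
  members, nested loci included.  Half-open adjacency is not overlap.
- **N** terminates runs and never participates in a repeat.
- Coordinates are 0-based half-open internally; BED stays as-is, GFF3 is
  converted from 1-based inclusive at the boundary.

Density is SSR bp per Mb of sequence (per chromosome, per period class) and
genome fraction is total SSR bp / genome bp.

## Region classification

Transcripts are decomposed into CDS, UTRs (exonic minus CDS, split 5′/3′ by
strand-aware position relative to the CDS), introns (gaps between exons),
non-coding exons, and a promoter of up to 2,000 bp upstream of the TSS
(strand-aware, clipped at chromosome edges).  Within one transcript a locus
takes the highest-priority feature it touches (CDS > UTR5/UTR3 > non-coding
exon > intron), with promoter assigned only when no exonic or intronic
feature of that transcript is touched.  Across transcripts, the summary
label uses CDS > UTR5 > UTR3 > non-coding exon > promoter > intron >
intergenic, so a promoter call beats intergenic; loci touching several
transcripts with conflicting labels are flagged `multi_transcript` and can
be tallied separately.  These priority rules are package choices — region
tallies in the literature are mutually exclusive but rarely state their
tie-breaks.

For region densities each genomic base is painted with exactly one class
(same priority order); a locus contributes its overlapping bp to every
class it spans, while tabulations by summary label assign the whole locus
to one class.  Zero-length regions get NaN densities, not 0.

## SINE-boundary enrichment

Both ends of each SINE interval are boundaries; the 200 bp outside each
boundary is split into ten 20 bp windows indexed by distance.  Windows
pool SSR bp (by overlap, not whole-locus assignment) and window bp across
all copies; clipped window bp is excluded from denominators.  The genome
fraction serves as the control level.  Windows do not extend into the
element body — the profile is about the flanking sequence.  Motif-stratified
profiles rank motifs by peak window density over that motif's own
genome-wide density, ties broken lexicographically.

## Genotype statistics and filtering

Genotype tables are lobSTR-style: one row per called sample × locus with
two tract lengths (bp), the allelotype likelihood-ratio score Q ∈ [0, 1)
and the supporting read count; missing calls are absent rows.  An
`--offsets` dialect accepts length offsets from the reference tract and
normalises them against the catalogue, which makes frameshift arithmetic
downstream direct.

Frequencies are counted over called chromosomes only.  PIC is implemented
exactly as 1 − Σ pᵢ² (expected heterozygosity); the classical Botstein PIC
subtracts an additional term and is *not* used.  MAF for multi-allelic loci
is the frequency of the second-most-frequent allele.  The high-quality
filter applies, in this order of wording: mean coverage **strictly** > 3×,
mean −log₁₀(1 − Q) **strictly** > 0.6, call rate ≥ 0.6 ("at least"),
reference tract ≤ 80 bp, MAF **strictly** > 0.1, plus polymorphism.  The
strict-vs-inclusive boundaries follow the criteria's phrasing verbatim,
since nothing finer is specified; each boundary has a dedicated test.
Mean coverage is reads over *called* samples.

## Conservation

Flank pairing: a species conserves a locus iff some left-flank hit and some
right-flank hit share the target chromosome and orientation, sit in the
correct relative order for that orientation (left upstream of right on +,
reversed on −), and are separated by a target-side gap in [0, 300) bp.  The
orientation-consistency and order requirements are the minimal reading of
"aligned co-ordinately"; a species counts once regardless of how many pairs
qualify.  The category is the number of conserving species (0–14; 0 =
lineage-specific).  The score track must already be in catalogue
coordinates (constructing a cross-genome coordinate map is out of scope);
the mean flank score skips unscored bases and is NaN when none are scored.

## Loss-of-function classification

For each non-reference allele and overlapping transcript: a CDS-overlapping
locus with length delta not divisible by 3 is a frameshift; otherwise
overlap with the first/last 2 bp of an intron (strand-aware donor/acceptor
cores) is a splice call; an in-frame CDS change is `inframe`; anything else
is `none`.  The 2 bp core is used rather than wider splice regions.
Whole-unit alleles of triplet motifs can never frameshift, which the tests
assert as a property.  Judgements beyond this arithmetic (e.g. whether a GT
insertion inside a GT-tandem donor is tolerated) are left to the analyst.

## Distances and neighbour joining

Distance = 1 − identical/(identical + distinct), where genotypes are
unordered allele pairs and loci missing in either sample are excluded from
both counts (complete-pair analysis; the formula's denominator contains
only compared loci).  A pair with zero shared called loci is an error, not
a distance.

NJ is the Saitou–Nei agglomeration on the standard Q criterion, ties broken
by the smallest (i, j) position pair in the current node order, final three
nodes joined by the three-point formulas.  On additive matrices the
topology and branch lengths are recovered exactly (tested to 1e-9 over
random trees up to 12 taxa).  Negative branch lengths are clamped to zero
at Newick serialisation only; raw values are kept for path-length queries.
Breed summaries report means for homozygous/heterozygous counts and the
median across windows for group comparisons of the windowed heterozygous
ratio (heterozygous pSSRs / pSSRs per 10 Mb non-overlapping window, windows
without data excluded as missing).

## Synthetic data

The generator emulates the structure of the study data at desk scale.
Defaults: 2 chromosomes × 1 Mb at GC 0.42; 500 planted loci
(150/120/110/70/50 for periods 2–6) with A/T-rich motif weights and rare
CG-containing classes, 4 dinucleotide loci with tracts > 80 bp; 30
three-exon coding genes (some minus-strand) with 10% of the trinucleotide
quota planted inside 5′ UTRs; 40 SINE copies of 300 bp with 40 extra
A/T-rich loci planted within 40 bp of their boundaries; 8 breeds × 2
samples in two groups ("CH" with per-genotype heterozygosity 0.25, "EU"
with 0.10), 10% missing calls, coverage 1 + Poisson(6), Q ~ U(0.8, 0.99).
Group- and breed-level allele-frequency divergence are lognormal
perturbations (σ = 1.5 each) of a Dirichlet base spectrum — strong enough
drift that each breed's two samples resemble each other more than any other
breed, as in real closed breeds, so the NJ topology check is not borderline.

Three constructions make tests exact rather than statistical:

- background sequence is re-sampled wherever an unplanned repeat would meet
  the scanner thresholds (and around any planted tract that accreted
  flanking matches), so the scanner's catalogue equals the truth table
  exactly;
- each genotyped locus has an *intent* — pass, or one named filter
  violation (coverage drawn in {1..3} reads so the mean cannot exceed 3;
  Q ~ U(0.3, 0.6) so mean −log₁₀(1 − Q) < 0.4; call rate forced to 0.55;
  a single minor-allele chromosome for MAF; a single allele for
  monomorphism; a planted tract > 80 bp for length) — and each locus is
  re-drawn until its realised statistics match the intent, so the filter's
  pass-set equals the engineered set exactly;
- conservation categories cycle 0–14 over loci; hit tables contain
  qualifying pairs for exactly the assigned species plus decoys that each
  violate one pairing rule (gap exactly 300, different target chromosome,
  wrong order, unpaired side, mismatched orientation), so category recovery
  is exact; flank score levels rise 0.15 per category with 0.01 jitter.

What the generator does **not** emulate: sequencing reads and their error
or GC-bias processes (quality and coverage are drawn, not caused),
imperfect/interrupted repeats, linkage between loci, Hardy–Weinberg
structure beyond the planted heterozygosity, allelic dropout correlated
with allele length, and realistic SINE sequence content (elements are
intervals, not sequence families).  Passing tests therefore demonstrate
correctness of the *computations* under controlled inputs, not robustness
to the noise processes of real resequencing data.

## Problem sizes

The default test suite simulates 2 Mb genomes with ~540 loci and 16
samples; oracle cross-checks use 10 kb sequences (200 in the acceptance
script, with a 3 kb/12-seed variant in the unit tests); NJ recovery uses
100 random trees of 4–12 taxa; statistical recovery uses 20 genotype
replicates over one genome.  These sizes keep the whole suite within a few
minutes on one CPU while leaving every check exact or tightly bounded.

## Known limitations

- Perfect repeats only; interrupted or compound repeats are fragmented or
  missed, so real-genome totals are not comparable with TRF-based numbers.
- Region densities require per-chromosome paint arrays (one byte per base),
  which is fine up to mammalian chromosome scale but assumes the genome
  fits in memory.
- The overlap-removal rule discards both members of a pair, which on dense
  repeat clusters removes more sequence than keep-longer policies.
- `pair_flank_hits` is quadratic in hits per (locus, species); hit tables
  are expected to be pre-filtered to near-best alignments.
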