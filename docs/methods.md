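# Methods

This note documents the models, rules and numerical choices behind
`ricelnc`, the assumptions they rest on, and what the synthetic-data tests
do and do not demonstrate about real data.

## Coordinates and containers

All internal coordinates are 0-based half-open on a named chromosome with
strand `+`, `-` or `.` (unstranded). GTF converts from its 1-based inclusive
convention on read/write; BED and bedGraph are already half-open. One
internal convention avoids off-by-one drift between tools that mix
conventions. Chromosome names are matched exactly — no "chr" prefix
normalization — so a namespace mismatch surfaces as an error rather than an
empty join. Unstranded is a first-class strand value because the first
identification filter removes strandless transcripts; they must be
representable, not rejected at parse time.

A transcript is an ordered tuple of non-overlapping exons on one
chromosome/strand; its length is the spliced (exon-sum) length everywhere a
length threshold applies. Expression lives in a pandas DataFrame
(transcript × sample FPKM); conservation in per-chromosome float arrays
with NaN meaning "no aligned base in the underlying multiple-genome
alignment", which keeps "unaligned" distinct from "score 0".

## Identification cascade

Six pure predicates, applied in a fixed order only for reporting purposes
(the surviving set is order-independent; the report's "first failed filter"
is order-dependent and documented as such):

| filter | rule | default |
|---|---|---|
| strandless | strand ∈ {+, −} | — |
| sense overlap | no exonic overlap with an annotated gene's exon on the same strand | ≥ 1 bp discards |
| length | spliced length | ≥ 200 nt kept |
| expression | max FPKM over samples | ≥ 0.5 multi-exon, ≥ 2 single-exon |
| single-exon proximity | nearest same-strand transcript gap | ≤ 500 bp discards |
| coding potential | external score > 0, domain hit, or surrogate ORF | ≥ 100 codons discards |

Notes on interpretation:

- The length boundary keeps exactly 200 nt. Published phrasings of this
  class of pipeline vary between "longer than 200" and "shorter than 200
  discarded"; we treat 200 as passing and pin the boundary in a test.
- "Expressed in at least one sample above threshold" and "not below
  threshold in all samples" are the same predicate; it is implemented once
  as max-over-samples ≥ threshold.
- The proximity rule exists to drop single-exon assembly fragments of a
  neighboring transcript. "Sense direction" is read as *same strand*
  (fragments share the strand of their source), measured between span ends
  with overlap counting as gap 0; a 3′-directional variant would be easy to
  add but is not the default. Unstranded neighbors never count as
  same-strand. The window is measured against annotation *and* all other
  candidates.
- The ORF surrogate (discard at ≥ 100 codons, ATG→stop with a required
  in-frame stop, three forward frames on the transcript-strand spliced
  sequence) is the conventional lncRNA ORF cutoff. It is a deliberately
  simple stand-in behind a pluggable interface: externally computed
  coding-potential scores (discard > 0) and protein-domain hit lists
  reproduce a classifier-based pipeline bit-for-bit when supplied.
  Candidates contained in known non-coding annotation receive no special
  treatment; they flow through the cascade like any other.

## Classification and neighbor geometry

lncNAT: ≥ 1 bp exon-to-exon overlap with a non-TE protein-coding mRNA on
the opposite strand. Intron-only antisense nesting is *not* a lncNAT (the
transcribed sequences never face each other). The overlap fraction divides
the base-union of antisense-covered exonic bases by the lncRNA's spliced
length, making it invariant to how the mRNA's exons are fragmented and
bounded by 1.

Closest-gene search is purely positional (minimal span gap, ties to the
lexicographically smaller gene id); whether a strand-aware search was ever
intended upstream is unknowable from published descriptions, and positional
search is the simplest defensible reading. Orientation: overlapping spans →
"overlapping"; same strand → tandem; opposite strands with the 5′ ends
facing across the gap → divergent, 3′ ends facing → convergent. Signed
distance is positive when the gene lies to the genomic right.

## Characterization

A/U content is computed on the transcribed sense (minus-strand transcripts
reverse-complemented, T counted as U) with N excluded from both numerator
and denominator. Repeat overlap is strand-agnostic (repeat annotations are
usually strandless); sRNA-locus overlap is strand-agnostic by default with
a stranded mode, since sRNA derivation is strand-informative. "Aligned
fraction" equates *aligned* with *score present in the supplied track*;
a stricter definition (aligned in all genomes) would need the alignment
itself, which this package deliberately does not consume. Conserved
elements are maximal runs of ≥ 15 consecutive bases with present score
≥ 0.8 — both thresholds are package choices with no published counterpart
and are configurable. Percentages are reported at one decimal,
round-half-even.

## Tissue specificity and categories

The JS score is `1 − sqrt(JSD(p, e_t))` maximized over tissues, with
base-2 entropy and `0·log 0 ≡ 0` (implemented via
`scipy.spatial.distance.jensenshannon`; an independent hand-rolled
evaluation serves as the test oracle). With base-2 logs JSD ∈ [0, 1], so
scores lie in [0, 1], equal 1 exactly for single-tissue expression, and are
scale-invariant and permutation-equivariant — all property-tested.

Categorization replaces an external clustering step with the specificity
argmax: a transcript with JS ≥ 0.5 (the `js_floor`) computed over the
grouped samples is assigned the group (reproductive / vegetative) of its
most specific tissue, otherwise "other". This surrogate produces the same
three categories a cluster-then-label analysis yields on cleanly separated
data, is deterministic, and has one interpretable parameter. Only samples
named in the tissue groups enter this computation (13-sample matrices with
an extra unassigned sample are supported); the groups must not overlap.

Per-transcript summary expression for set comparisons is the max FPKM
across samples — a cross-sample mean would erase exactly the
tissue-specific transcripts of interest (a mean mode exists). The default
two-sample location test is the Mann-Whitney U (FPKM is heavy-tailed);
a Welch t-test flag reproduces t-test-based analyses.

The lincRNA–neighbor expression correlation reports the mean Spearman ρ
over (lincRNA, closest coding gene) pairs against a positional-shuffle
control: each shuffle re-places every lincRNA uniformly at random in
intergenic space (gene bodies excluded, chromosome chosen
length-weighted), recomputes closest genes and the mean ρ. Pairs with a
constant expression vector have undefined ρ and are excluded and counted.
The default is 1,000 shuffles; the bundled pipeline and acceptance runs use
200, which stabilizes the control sd to well under the effect sizes of
interest at this problem size.

## miRNA decoy rules

Defaults: 3-nt target-side bulge allowed between the pairing partners of
miRNA positions p and p+1 for p ∈ {9, 10, 11} (bulge opposite positions
9–12 from the 5′ end); perfect Watson-Crick pairing at positions 2–8; at
most 3 combined mismatches + G:U wobbles at the remaining positions; no
other insertions or deletions; bulges on the miRNA side are not considered.
These constants follow the established endogenous-target-mimic conventions
and are all parameters of `DecoyRules` (G:U can also be treated as a full
match). The scanner slides every window of length |miRNA| + bulge; within
a window the admissible placement with the fewest mismatches + wobbles
(ties to the 5′-most bulge) is reported, and overlapping windows are all
reported. Equality with a brute-force (window × placement) enumeration is
asserted in tests.

## FST mapping

Exact local alignment (Biopython `PairwiseAligner`, match +1, mismatch −1,
linear gap −2, both orientations) of each FST against each lincRNA's
spliced body and 1-kb upstream region; the search space is small enough
that exactness is affordable and testable against an independent
Smith-Waterman oracle. Percent identity = matching columns / alignment
columns × 100; retention requires identity strictly greater than 90 (90.0
exactly is rejected) *and* the alignment to cover ≥ 80% of the FST — a pure
identity rule with no coverage floor would accept any ~10 bp perfect
micro-match at "100% identity". The original searches were BLAST-based,
which carries an implicit coverage/E-value floor; the explicit
`min_aligned_frac` parameter makes that floor visible and tunable. Whether
"similarity score" meant percent identity or a score ratio is ambiguous in
the source descriptions; percent identity is implemented. Hits spanning the
body/upstream boundary are classified by the FST 5′-end position alone; for
a reverse-complement hit the 5′ end maps to the right edge of the aligned
target stretch. One FST may hit several lincRNAs (all reported); per
(FST, lincRNA) the best-identity hit is kept.

The 1-kb upstream region is taken on the transcript's own strand
([start−1000, start) for +, [end, end+1000) reverse-complemented for −),
truncated and flagged at chromosome boundaries.

## Synthetic-data generator

The generator fabricates the study conditions end to end: a 2-Mb genome on
two chromosomes carrying 60 protein-coding genes, 10 TE-mRNAs, 40 true
lincRNAs, 20 true lncNATs and 15 noise transcripts per role
(`noise_short`, `noise_lowFPKM`, `noise_strandless`,
`noise_single_exon_proximal`, `noise_coding_orf`) — each noise transcript
violating *exactly* the one filter its role names and passing all others,
which is what makes single-filter ablation testable. Sample layout: 13
tissues, 7 reproductive (panicle, anther, pistil, seed 5/10 DAP, embryo and
endosperm 25 DAP), 5 vegetative (callus, seedling/shoot 14 DAG, leaf
20 DAG, root 14 DAG), plus one extra ungrouped sample.

Design targets (all recoverable from the emitted files): lincRNA exon count
truncated-geometric with mean ≈ 2.2 and length lognormal with median ≈ 850
nt in [250, 3000]; A/U fraction 0.62 for lncRNAs vs GC-biased codons in
CDS; lncNATs placed antisense over a host coding exon with overlap fraction
drawn in (0.04, 0.28); tissue-specific transcripts get one on-target FPKM
in [10, 60] (≥ 2× the retention threshold, so boundary flakiness cannot
arise) against off-target noise in [0.01, 0.1], giving planted JS scores
comfortably above the 0.5 floor; four lncNATs are broadly expressed
("other"). The tissue draw is anther-enriched (weight 3), reflecting the
male-gametophyte bias typical of plant lincRNA sets. Conservation is
painted in short runs: coding exons ~90% covered at mean score 0.85,
lincRNA exons ~25% at 0.2, TE exons ~12%, sparse intergenic background —
so the planted ordering coding > lincRNA in both aligned fraction and mean
score is testable. Decoy sites are verbatim perfect mimics inserted into
lincRNA bodies (2 miRNAs × 3 sites); FSTs are 300-nt copies of lincRNA
bodies or upstream regions at a 2% substitution rate (ends kept intact so
the planted identity equals the alignment identity), half
reverse-complemented, labeled with one of nine database names.

Mechanics worth knowing: all randomness flows through one
`numpy.random.Generator`, making bundles byte-identical per (config, seed).
Features are spread over the *whole* chromosome (the spare length is
distributed randomly into inter-feature gaps ≥ 1,500 bp) — leaving a long
featureless tail would bias the positional-shuffle control toward the last
gene of each chromosome. Intergenic spacing ≥ 1,500 bp guarantees the
500-bp proximity filter only fires where intended and every lincRNA has a
clean 1-kb promoter. Non-coding sequences are scrubbed of spurious ORFs by
inserting in-frame stops until no ORF reaches 80 codons (95 for lncNATs,
whose host-shared bases cannot be rewritten; an ORF that long cannot hide
entirely within the shared stretch), keeping a safety margin below the
100-codon filter.

What passing on this generator does **not** show: robustness to noisy
strand calls, fragmented or chimeric assemblies, FPKM estimation error,
overlapping gene models, paralogy (every planted sequence is unique, so
FST and decoy scans see no homology background), or realistic conservation
autocorrelation. The generator validates the *logic* of every rule and
threshold, not the field performance of the pipeline on real rice data.

## Numerical choices

- Round-half-even at one decimal for reported percentages.
- Expression TSVs are written at 17 significant digits and parsed with
  pandas' round-trip float parser, so matrix round trips are bit-exact.
- Threshold comparisons at boundaries: length ≥ 200 keeps, FPKM ≥ 0.5/2
  keeps, proximity gap ≤ 500 discards, ORF ≥ 100 codons discards, identity
  > 90 keeps (strict). Each boundary is pinned by a test.
- Spearman correlations are computed on ranks with constant-vector pairs
  excluded and counted rather than propagated as NaN.
- Degenerate inputs error early with the offending name: empty transcript
  sets for statistics, all-zero expression vectors for specificity,
  candidates missing from the FPKM matrix, conservation scores outside
  [0, 1].

## Problem sizes

Default test and acceptance runs use the generator defaults above
(135 candidates, 70 annotated genes, 2-Mb genome), 200 positional shuffles,
1,000 random vectors for the specificity oracle, 100 random pairs for the
alignment oracle, and 20 dinucleotide-shuffled decoy controls. The full
pytest suite completes in under two minutes on one CPU; the acceptance
script in about half a minute.

## Known limitations

- The ORF surrogate is weaker than a trained coding-potential classifier;
  on real data, supply external scores/domain hits for fidelity.
- The decoy scanner models a single contiguous target-side bulge; published
  mimic variants with miRNA-side bulges are out of scope (expressible only
  by rule extension, not configuration).
- FST mapping aligns against spliced bodies; an FST spanning an intron
  junction of a multi-exon lincRNA aligns with a gap and may fall below
  the coverage floor. At the generator's FST length and the typical exon
  sizes this is rare, but on real multi-exon loci genomic-body alignment
  would be the safer target space.
- The pipeline consumes an assembled transcriptome and precomputed tracks;
  alignment, assembly, repeat annotation and conservation-model fitting are
  explicitly out of scope.
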