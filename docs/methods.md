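# Methods

## Arm assignment and pairing

A mature miRNA is assigned to an arm by its id suffix (`-5p`/`-3p`) when
present — existing annotation always wins — and positionally otherwise:
with mature midpoint m = (start + end)/2 and hairpin length L, the call is
5p for m < L/2, 3p for m > L/2, and *ambiguous* when |m − L/2| ≤ 1 nt.
The tie band is deliberate: a mature straddling the loop is surfaced
rather than silently forced to an arm, because no positional rule is
defensible there.  A mature annotated on several precursors is located on
the first hairpin in its list (multicopy precursors: first copy wins), and
a hairpin contributes one 5p/3p pair iff exactly one mature per arm
annotates onto it.

## Composition statistics

Length comparisons use Student's t (equal variances) between independent
arm groups and the paired t on per-pair differences for 5p/3p pairs of the
same hairpin; all tests in the package are two-tailed.  Homopolymer-run
composition counts overlapping k-mers (a run of r identical nucleotides
contributes r − k + 1 k-mers), which is deterministic and makes
count(XXX) ≤ count(XX) hold by construction; percents for run tables are
normalized over the four homopolymer labels only, so each k's row sums
to 100.  Positional composition is anchored at the 5' end (position 1 =
first nucleotide), with per-position coverage as the denominator.
Chi-square comparisons are Pearson contingency tests without continuity
correction; positional tables are stacked into a single positions ×
nucleotides contingency (one pooled statistic rather than per-position
tests — the pooled form weights positions by coverage and yields a single
decision).  Categories empty in both groups are dropped; a zero expected
count raises with advice to merge categories.

## Alignment and divergence

Cross-species family arms (~22 nt, highly similar) are aligned with
Needleman–Wunsch (match +1, mismatch −1, gap −2, end gaps free) in a star
layout around the reference species (default `hsa`): each sequence is
pairwise-aligned to the reference and the alignments merged on reference
coordinates, padding to the longest insertion per slot.  Traceback ties
break diagonal > up > left, so alignments are deterministic.  Pre-aligned
FASTA is accepted wherever alignment exactness matters.  Core trimming
removes leading/trailing columns up to the first/last gap-free column —
terminal-length artifacts — while retaining internal gap columns (true
indels).  Divergence is profiled per core column against the reference
row: transition (purine↔purine, pyrimidine↔pyrimidine), transversion
(otherwise), indel (exactly one side gapped); gap-vs-gap pairs are
excluded from the comparison count.  The per-arm summary rate is total
substitutions over total comparisons.

The 5p-vs-3p comparison pairs each family's mean substitution rate in a
Wilcoxon signed-rank test (normal-approximation Z; an all-zero difference
vector returns Z = 0, p = 1 by convention), because positionwise pairing
across arms of different lengths is ill-defined; the Spearman correlation
uses the positionwise rate vectors truncated to each pair's common length.

## Diversity statistics

For n aligned sequences of core length L: k is the mean count of differing
non-gap column pairs over all C(n, 2) pairs; π = k/L; Hd =
(n/(n−1))(1 − Σ p_h²) over distinct haplotypes (algebraically the fraction
of sequence pairs with different haplotypes).  Sampling SDs follow Nei
(1987): the total variance of π (eq. 10.7) and the haplotype-diversity
variance (eq. 8.12) — the quantities population-genetics software prints
as "±".  A brute-force pair-enumeration oracle checks all three statistics
property-wise at n ≤ 8.

## Missing-arm inference

An unannotated arm is predicted by globally aligning the target hairpin to
the homologous human hairpin (same scoring, free end gaps) and reading off
the target segment under the human mature's columns, gaps removed.  The
prediction fails loudly if the segment is shorter than 15 nt or more than
half gaps — conservation is the premise of the transfer, and a mostly
deleted window means there is nothing to infer.

## IsomiR extraction and normalization

A collapsed read is resolved against a hairpin by removing the *shortest*
3' suffix (≤ `max_tail`, default 3 nt) that leaves an exact hairpin
substring; the removed suffix is the non-template tail, which by
construction cannot begin with the templated continuation.  The read joins
a locus iff its templated start lies within ± `window` (default 5 nt) of
the canonical start — observed end variability is 1–2 nt, so 5 nt gives
margin without reaching the loop.  Offsets are signed relative to the
canonical ends (negative offset5 = 5' extension).  With several candidate
loci, the closest canonical start wins; exact ties go to the 5'-most
(logged).  Expression is reported as RPM (count × 10⁶ / total mapped;
the read-set total stands in when a library total is unavailable) and as
the within-locus percent, which always sums to 100 per sample.  Summaries
use the sample (n−1) SD; isomiRs present in fewer than `min_samples`
samples (default 10% of passing samples) are pooled into an `other` row;
samples below `min_rpm` locus abundance (default 1.0) are dropped.
Dispersion comparisons pool per-isomiR SDs per cohort and compare the two
distributions with a two-tailed rank-sum test plus box summaries
(quartiles, 1.5 × IQR whiskers).

## Target scanning

The seed is positions 2–8 of the mature (7 nt).  A UTR is a target iff it
contains ≥ 1 exact occurrence of the seed's reverse complement; DNA input
is normalized to RNA.  This is deliberately *not* a TargetScan
reimplementation — no site-type hierarchy, conservation weighting or
context scores — so absolute target counts are not comparable to
TargetScan output; overlap statistics between two seeds scanned the same
way are the intended use.

## Synthetic data: what it emulates and what it does not

`generate_phylo_families` plants, per family, a root hairpin (default
82 nt) with a 5p mature starting 8 nt from the 5' end and a 3p mature
ending 8 nt from the 3' end (lengths ~N(22, 1) bounded [20, 24]).  The
reference species carries the root; every other species accumulates
i.i.d. per-position substitutions at `sub_rate_5p` = 0.02 in the 5p arm,
`sub_rate_3p` = 0.12 in the 3p arm and 1.5 × max(arm rates) elsewhere —
the loop/flank evolving faster than either arm — plus loop-confined
deletions (rate 0.01) and up to 2 nt of terminal jitter.  Keeping indels
out of the arms keeps family arms colinear across species, so the same
output serves as pre-aligned input and as material for the aligner; it
also means the generator does not exercise within-arm indel handling
(tested separately on constructed alignments).

`generate_isomir_readsets` draws per-sample isomiR proportions from a
Dirichlet centered on a template — 70% canonical, the rest spread over
(offset5, offset3) ∈ [−2, 2]² with weight 2^−(|o5|+|o3|) — with
concentration 50 for controls and 12.5 (4× more dispersed) for disease,
then multinomial counts at a uniform 50k–150k library size; 10% of each
isomiR's reads receive a 1–3 nt non-template tail whose first base is
forced off-template.  Twenty samples per condition.  The model reproduces
the analysis-relevant structure — a dominant canonical sequence, 1–2 nt
end variability, condition-dependent between-sample dispersion — but not
sequencing error, adapter artifacts, cross-mapping between paralogous
loci, or biased tail composition; passing tests therefore validate the
pipeline's statistics, not robustness to those artifacts.

`generate_utrs` plants reverse-complement seed sites independently per
seed at a configurable rate, at non-overlapping positions so the truth
table stays exact; background chance matches remain, with per-UTR
probability 1 − (1 − 4⁻⁷)^(L−6).

All generators draw from independent substreams of one seed, and every
generator writes a truth table beside its outputs.

## Problem sizes and numerical choices

The replicated experiments run at 10 species × 40 families with 200
replicates for substitution-rate recovery and the Wilcoxon arm comparison,
and 100 replicates for isomiR dominance and dispersion ordering — sizes at
which the binomial standard errors make the recovery checks sharp while a
full run stays at desk scale.  Recovery tolerances are 3 binomial SE for
rates and ≥ 95% replicate fractions for the qualitative orderings.
Floating-point guards: Hd is clamped to [0, 1]; identical groups
short-circuit t and χ² tests to (0, 1) exactly; variance expressions are
floored at zero before square roots.

## Known limitations

* Positional arm calls near the loop are reported ambiguous, not resolved.
* The star aligner is built for near-identical short sequences; deeply
  diverged families should be aligned externally and supplied pre-aligned.
* Exact reproduction of published diversity tables depends on the
  aligner used upstream; with pre-aligned input the statistics are
  deterministic.
* Seed-match target sets are a simplification; absolute counts carry no
  TargetScan meaning.
* Patient-scale tumor small RNA-seq is out of scope; the dispersion
  contrast is validated on the synthetic cohort model instead.
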