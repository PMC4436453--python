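# armiso

Arm classification, cross-species divergence and isomiR expression
profiling for microRNA 5p/3p pairs.

## The problem

A pre-miRNA hairpin can yield mature miRNAs from either arm: miR-#-5p from
the 5' arm, miR-#-3p from the 3' arm.  Which arm dominates (arm selection)
can flip between tissues, conditions and species (arm switching), and each
arm's locus expresses not one sequence but a population of end-variants
(isomiRs) whose 5' boundary sets the target-determining seed (nucleotides
2–8).  `armiso` is a library for quantifying this three-layer picture:

1. **Census** — locate matures on hairpins, call arms (id suffix first,
   position otherwise), pair the two arms of each precursor, and compare
   the arm groups: lengths (Student's/paired *t*), overall, homopolymer-run
   and per-position nucleotide composition (Pearson χ² contingency).
2. **Evolution** — find gene families shared across species, infer
   unannotated arms from the homologous human hairpin, trim alignments to
   their gap-free core, profile per-position divergence (transitions,
   transversions, indels) against the human reference, and summarize each
   family arm as a sequence population: nucleotide diversity π, haplotype
   diversity Hd (with the n/(n−1) correction), and mean pairwise
   differences k, with Nei (1987) sampling SDs.  Arm asymmetry is tested
   with the paired Wilcoxon signed-rank and Spearman correlation.
3. **Expression** — extract isomiRs from collapsed small-RNA reads
   (signed 5'/3' offsets plus non-template 3' tails), normalize as RPM and
   as within-locus relative expression (percent), rank isomiRs by
   dominance, and compare the between-sample SD distributions of disease
   vs control cohorts (rank-sum).
4. **Targets** — 7-mer seed extraction, 5' seed-shift detection, exact
   reverse-complement seed matching over UTRs, and overlap statistics
   (shared counts, fractions, Jaccard) between target sets.

A synthetic-data module generates all inputs with the statistical
structure the analysis assumes (arm-specific substitution rates,
Dirichlet–multinomial isomiR counts with condition-specific dispersion,
planted seed sites), so the whole pipeline is testable without downloads.

## Worked example

```sh
python examples/diversity_divergence.py
```

generates 40 families across 10 species with a conserved 5p arm
(0.02 substitutions/site vs human) and a variable 3p arm (0.12/site),
then recovers that asymmetry from sequence alone:

```
mir-1 5p: mean substitution rate 0.015, pi=0.025+/-0.025  Hd=0.51+/-0.16  k=0.56
mir-1 3p: mean substitution rate 0.095, pi=0.160+/-0.101  Hd=0.98+/-0.05  k=3.36
mir-2 5p: mean substitution rate 0.020, pi=0.036+/-0.032  Hd=0.53+/-0.18  k=0.80
mir-2 3p: mean substitution rate 0.143, pi=0.234+/-0.141  Hd=0.98+/-0.05  k=4.91
...
```

Per family arm: the mean per-position substitution rate against the human
reference row, then π ± SD, Hd ± SD and k for the ten sequences treated as
a population.  The conserved 5p arms sit near zero; the 3p arms show high
haplotype diversity and several pairwise differences — the generated
contrast, recovered by the pipeline.  The other example scripts
(`examples/*.py`) walk through arm annotation, the composition census,
isomiR profiling with cohort dispersion, and seed-shift/target overlap.

There is also a thin CLI (`armiso annotate-arms | composition | diversity |
divergence | isomir-profile | dispersion | target-overlap | simulate`);
every run writes a `run_manifest.json` with input digests and the seed.

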