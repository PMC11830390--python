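# Methods

This note documents the models, parameter choices, and numerical decisions
behind `bcrflow`, and what the synthetic-data tests do and do not establish
about real repertoires.

## The analysis model

A heavy-chain repertoire is a set of unique productive V(D)J sequences per
individual and sorted B-cell subset (CD27⁻CD21lo, CD27⁺CD21lo, early
plasmablasts, and a total-B reference).  Clonal relationship is operationally
defined: two sequences descend from one ancestral rearrangement when they
carry the same V gene, the same J gene, a junction of identical length, and
junctions within a normalized Hamming distance threshold, closed under
single linkage.  This is the standard hierarchical-clustering clonal model
for bulk heavy-chain data; it cannot see light chains, and identical
junctions arising independently (convergence) are indistinguishable from
clonality by construction.

### Threshold detection

The per-individual threshold is read off the distance-to-nearest
distribution: each sequence's minimum junction distance to any other
sequence in its V/J/length group.  In clonally expanded repertoires this
distribution is bimodal — a near-zero mode of clonal relatives and a broad
mode of unrelated sequences.  We estimate the density with a Gaussian KDE
(Silverman bandwidth, 512-point grid on [0, 1]) and place the threshold at
the density minimum between the two highest local maxima at least 0.05
apart (grid boundaries count as candidate maxima, since the clonal mode
often sits at zero).  Distributions that are unimodal by this rule, or hold
fewer than 50 distances, fall back to a fixed threshold of 0.1 with a
warning recorded in the pipeline manifest.  The fallback value is the
conventional default for heavy-chain junction clustering.

### Diversity

Clonal abundance is members-per-clone divided by the subset's unique
sequences; singletons participate with size 1.  Hill numbers ¹D (exponential
Shannon) and ²D (reciprocal Simpson) are reported as the mean over 1000
bootstrap iterations that resample records (not clones) with replacement,
with a Z-score 95% CI (mean ± 1.96 × bootstrap SD).  Per iteration and in
expectation 1 ≤ ²D ≤ ¹D ≤ richness.  Subsets are compared at a uniform
subsample depth (3195) so that depth differences do not masquerade as
diversity differences; shortfalls are reported, not silently accepted.

### Mutation profile

Mutations are substitutions of the observed sequence against the masked
germline (assigned V + N-fill + assigned J), counted over aligned V
positions strictly before the junction start; masked (N) and gap positions
are excluded from numerator and denominator.  The junction itself is never
counted: its germline state is unidentifiable.  The unit of analysis is the
clone (arithmetic mean over members) or the singleton, so expanded clones
do not dominate subset summaries; a unit is mutated when its (mean) count
exceeds 2 — an absolute count, which interacts with V length (~288
comparable positions here) and is therefore documented rather than scaled.
Replacement/silent status of CDR1+CDR2 substitutions is evaluated against
the germline codon with only the observed substitution applied
(one-at-a-time), the standard convention when several mutations share a
codon; units with zero silent mutations have an undefined ratio and are
excluded with a count.  Alignment gaps are excluded from mutation counting
entirely; indel-bearing SHM is out of scope.

### Lineage trees

Clones with more than 20 members spanning all three sorted subsets are
summarized as germline-rooted trees.  Unique haplotypes are attached
greedily, each step adding the haplotype closest (substitution distance over
unmasked positions) to any node already in the tree.  Because internal
nodes are restricted to observed haplotypes plus the root, this greedy
construction is Prim's algorithm and returns the exact minimum-substitution
spanning tree; tests verify equality with exhaustive enumeration for small
clones.  Relative to codon-model phylogenetics with hotspot/coldspot
awareness, nucleotide parsimony distorts branch lengths but preserves the
root-proximity ordering of subsets, which is the quantity reported.

## The synthetic cohort generator

The generator emulates the sorted-subset study design directly; its
defaults are the study conditions and are not tuned per run:

| parameter | CD27⁻CD21lo | CD27⁺CD21lo | PB | total B |
|---|---|---|---|---|
| cells per subset | 3195 | 3195 | 3195 | 3195 |
| singleton fraction | 0.50 | 0.15 | 0.05 | 0.70 |
| clone-size power-law exponent (max) | 2.5 (20) | 2.0 (60) | 1.6 (120) | 2.5 (20) |
| fraction of unmutated units | 0.60 | 0.15 | 0.09 | 0.70 |
| mutated-unit V mutation rate | 4.3% | 5.9% | 7.3% | 5.0% |

Sharing between the three sorted subsets defaults to 44 / 4 / 8 clones for
(CD27⁻, CD27⁺) / (CD27⁻, PB) / (CD27⁺, PB), three of them present in all
three subsets.  Shared clones are realized as descendants of one naive
rearrangement sampled into multiple subsets, with extra mutations along the
developmental order CD27⁻ → CD27⁺ → PB (+3 expected mutations per rank), so
shared clones are antigen-experienced and later subsets sit deeper in
lineage trees.  Total-B is an independent reference subset with
intermediate structure; the four mutated-unit rates above are per-base
expectations over the ~288 V positions before the junction.

Mutation status is drawn at the clone level (all members of a clone share
unmutated/mutated status), matching the unit-level classification of the
analysis.  Mutated units receive a shared trunk (~75% of the expected load,
floor 3 so the unit is classifiable as mutated) plus private per-member
mutations; positions are uniform over the V segment with an optional CDR
weight, and substitutions in CDR1/2 can be biased toward replacements
(default bias 1.2–2.5 by subset) to emulate antigen selection.  Junctions
of mutated units additionally receive Poisson(0.8) interior substitutions
per member, producing the near-zero mode of the distance-to-nearest
distribution.  Stops are never introduced, so simulated molecules stay
productive.

Two deliberate idealizations matter for interpreting test results:

- **Identifiability by construction.**  Naive junctions of distinct clones
  within one V/J/length group are kept at distance ≥ 0.2 (resampling on
  collision).  Real repertoires contain convergent junctions; the
  clone-recovery rates measured here (adjusted Rand ≈ 1) are therefore a
  correctness check of the clustering machinery, not an error rate for real
  data.
- **Quality-anticorrelated errors.**  Sequencing errors are substitutions at
  a configurable rate on the read payload, and miscalled bases draw low
  Phred scores (mean 12 vs. 36), as real base-callers produce.  The
  consensus tie-break is quality-aware, so the measured ≥ 99% exact
  consensus recovery at 5 reads/UMI and 2% error depends on this
  anticorrelation; with quality-blind errors, 2-2 ties among 5 reads break
  randomly and recovery drops to ~98%.

The generator does not model: light chains, isotypes/constant regions,
indels, SHM hotspot motifs (WRC/GYW), realistic gene-usage priors, UMI
collisions or chimeras, or paired-end assembly artifacts (reads are emitted
post-assembly as MID + UMI + primer + payload single-end amplicons; the MID
is error-free).

## The germline reference

The bundled reference is an invented stub, not IMGT data: 9 V genes in 4
families (~297 nt, FR1/CDR1/FR2/CDR2/FR3 tiling the sequence up to the
conserved cysteine codon at position 288), 8 D genes (12–24 nt), and 4 J
genes (42–51 nt with the conserved W/F codon annotated).  Families diverge
~40% and genes within a family ~8–12%, so gene-level assignment remains
unambiguous under SHM loads up to ~8% while still exercising
near-paralog discrimination.  Allele notation (`*01`) is carried but
collapsed to gene level for grouping and usage statistics.  The analysis
logic is reference-agnostic; any FASTA plus region table in the documented
format can be substituted.

## Numerical and design choices

- Coordinates are 0-based half-open internally; AIRR TSV exports are 1-based
  closed with `T`/`F` booleans.
- Gene assignment scores: match +1, mismatch −1, gap open −4, extend −1;
  glocal for V (germline consumed, read overhangs free), local for J on the
  read suffix after the V span; score floors 20 (V) and 10 (J) flag records
  unassignable (100/100 random 60-mers rejected in tests).  Ties break to
  fewest mismatches, then the lexicographically smallest name.  D genes are
  not assigned (`d_call` empty): no downstream statistic uses them and the
  germline masks the D segment regardless.
- Consensus ties break to the highest summed Phred for the tied base, then
  alphabetically; groups are majority-length-filtered before voting; no
  minimum reads-per-UMI is enforced by default (singleton UMIs pass), with a
  config knob to raise it.
- Clone ids are stable under input permutation (canonical sorting before
  clustering); ambiguous tied V calls would join the first matching group in
  deterministic order.
- Dunn's post-hoc uses rank-sum z statistics (tie-corrected for the
  Kruskal–Wallis flavor, within-block rank sums for the Friedman flavor)
  with a Bonferroni adjustment over all pairwise contrasts of the omnibus
  family; zero-difference pairs in the Wilcoxon signed-rank are dropped
  (scipy's convention), which is visible at small n.
- Wilcoxon/Friedman paired designs drop incomplete blocks and report how
  many; comparisons that cannot run (e.g. an individual with no shared
  clones) are skipped with a logged reason, never silently.
- Every stochastic pipeline stage derives its seed as
  `sha256(master_seed:stage)[:4] mod 2^31`, making full reruns
  byte-identical.

## Problem sizes used in the shipped checks

The test suite and the acceptance script run the default conditions at
three individuals × four subsets × 3195 cells (~38k sequences); the
preprocessing-recovery experiment uses 1000 molecules at 5 reads/UMI and 2%
error; brute-force oracles run on instances of ≤ 50 records (clustering) and
≤ 5 haplotypes (lineage trees); statistical calibration uses 200 null
replicates at n = 10 per group.  These sizes were chosen as the smallest at
which the targeted properties are statistically decidable.

## Known limitations

- Indels: alignments may contain gaps, but mutation counting is
  substitution-only and gap positions are excluded; repertoires with
  frequent V-region indels will be under-counted.
- The clonal threshold's fallback (0.1) is a convention; repertoires whose
  true within-clone divergence exceeds it will be over-split when the
  distance distribution is unimodal.
- CDR3 physicochemical properties beyond amino-acid length are not
  implemented.
- Contamination between individuals is reported (identical sequences under
  multiple MIDs) but not filtered.
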