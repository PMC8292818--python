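# Methods

## Markers and data model

Two marker classes are analysed. The five POALINs are dimorphic Alu
insertion loci in the MHC class II region, coded `*1` (insertion absent,
the ancestral state) and `*2` (insertion present); the fixed analysis
order is AluDPB2, AluDQA2, AluDQA1, AluDRB1, AluORF10, and every
five-locus haplotype vector follows it. HLA-DRB1 is multiallelic with
two-field allele strings (`12:02`). Genotypes are unordered allele pairs
(`2/1` ≡ `1/2`); phase is never observed. Individuals missing a locus are
excluded complete-case from any statistic at that locus, never dropped
from the table.

The packaged reference tables (15 populations: 12 Chinese minority
cohorts, Han-Yunnan, Japanese, Caucasians) are stored verbatim at their
printed 3-decimal precision. Blank printed cells are zero frequencies,
not missing data. Recomputation from genotype counts is a separate
operation and is never silently substituted for the printed values.
Japanese and Caucasians carry published sample sizes but no genotype
counts; the frequency-table type admits such frequency-only populations,
and count-based operations refuse them explicitly.

## Allele frequencies and exact HWE testing

Frequencies use direct counting, `p(a) = n_a / 2n`, computed in rational
arithmetic so they sum to exactly one before float conversion.

The HWE test is the conditional exact test on the Levene distribution:
given allele counts, a genotype configuration has probability
`n! 2^h ∏_a n_a! / ((2n)! ∏_g n_g!)` (`h` heterozygotes), and the p-value
sums the probabilities of all configurations no more probable than the
observed one (log-scale comparison with a 1e-9 tie slack). The space is
fully enumerated whenever it contains at most 10^6 configurations —
which covers every biallelic locus at survey sample sizes — and the
enumerated probabilities are asserted to total 1. Larger (multiallelic
HLA) problems fall back to a Monte-Carlo version with 170,000 seeded
replicates by default: each replicate shuffles the fixed pool of 2n
allele copies and pairs consecutive copies, and
`p = (1 + #{replicates ≤ observed}) / (1 + R)`. This is an
independent-replicates variant of the classic Markov-chain Monte-Carlo
exact test; both target the same conditional null, and independence
makes the Monte-Carlo standard error elementary. The variant is recorded
in the result's `method` field. Monomorphic loci return p = 1 with a
flag rather than an error.

Bonferroni adjustment multiplies by the family size and caps at 1. The
default family is the five Alu loci within one population, with
significance declared at adjusted p ≤ 0.01; both are configurable.

## EM haplotype inference

For a genotype heterozygous at `h` loci there are `2^(h−1)` compatible
unordered haplotype pairs. With haplotype frequencies `f`, a genotype's
probability is `Σ_pairs 2^{h1≠h2} f(h1) f(h2)`; the EM iteration
distributes each individual's two haplotype doses over its compatible
pairs proportionally to current pair probabilities (E-step) and sets
`f = expected dosage / 2n` (M-step). The log-likelihood is asserted
non-decreasing at every iteration. Identical genotype patterns are
collapsed before iteration, so cost scales with distinct patterns rather
than individuals.

Numerical choices: convergence when the largest absolute frequency
change falls below 1e-8 (cap 10,000 iterations); restart 0 starts
uniform over the compatible-haplotype union and further restarts
(default 10) draw symmetric Dirichlet(1) starts from the stated seed,
because the likelihood can be multimodal; the best restart by final
log-likelihood wins; frequencies below 1e-6 are pruned from the output
only. With no heterozygotes EM reduces exactly to gamete counting. The
independent check in the test suite is a simplex grid search (coarse
0.05 grid, then greedy mass-transfer refinement to a 0.001 lattice) on
instances with ≤ 4 haplotypes.

Five-locus haplotypes are labelled H1..Hk by sorting the union of
observed (frequency > 0) haplotypes lexicographically with "1" < "2" —
this reproduces the published H1–H30 naming exactly; unobserved allele
combinations receive no label.

## LD and percentage association

From a two-locus haplotype table: `D_ij = p_ij − p_i q_j`; `D_max` is the
standard Lewontin bound (`min(p_i q_j, (1−p_i)(1−q_j))` for negative D,
`min(p_i(1−q_j), (1−p_i)q_j)` otherwise); `D′_ij = D_ij / D_max` (0 when
the bound is 0); the multiallelic global `D′` is the
`p_i q_j`-weighted mean of `|D′_ij|`. A fixed allele at either locus
makes every `D_ij` zero and hence global D′ = 0.

Percentage association of an HLA allele with an insertion is
`100 × f(allele & Alu*2) / f(allele)`, computed from EM two-locus
(DRB1, Alu) haplotype frequencies — inferred haplotypes, not counted
phase — with the source recorded. The published category wording leaves
(79, 80) unassigned; the implementation uses exhaustive half-open bins
[80,100] / [50,80) / [20,50) / [0,20). Population comparisons build 2×2
tables of allele (or haplotype-as-allele) counts against the remainder
of 2n gametes per population and use the two-sided Fisher exact test
(scipy), with a configurable Bonferroni family.

## Distances, trees, PCA

Nei's `DA = 1 − (1/r) Σ_loci Σ_alleles √(x_a y_a)` accepts per-locus
profiles whose frequencies sum to 1 within 0.01 (printed rounding).
Three presets match the survey: the five Alu loci (r = 5), DRB1 alone
(r = 1), and DRB1/AluDRB1 haplotypes treated as alleles of one synthetic
locus (r = 1).

Neighbor joining is the Saitou–Nei Q-criterion agglomeration,
implemented in-package because the tie-break and clamping conventions
are part of the contract: the Q-minimum resolves to the lowest (row,
column) pair, and negative branch lengths are clamped to zero with the
deficit transferred to the sibling branch. On additive matrices the
algorithm recovers topology and branch lengths exactly; the test suite
verifies this on random binary trees and cross-checks topologies against
scikit-bio's independent implementation. Trees serialize to Newick as an
unrooted trifurcation.

PCA eigendecomposes the correlation matrix by default (the convention of
the classic desktop statistics packages this analysis chain emulates;
covariance is available) of a populations × variables matrix — one
insertion-allele (`*2`) frequency column per Alu locus for the POALIN
analysis, one column per allele for DRB1. Contributions are
`100 λ_k / Σλ`. Zero-variance variables are dropped with a warning under
the correlation convention. On the packaged 15 × 5 insertion-frequency
matrix the correlation convention yields PC1 = 43.51% and PC2 = 26.01%,
matching the published 43.53%/25.96% to within rounding of 3-decimal
inputs; the covariance convention would give 54.2%, which settles the
convention question in favour of correlation.

## Synthetic cohorts

The generator emulates the sampling process behind the survey tables:
diploid individuals formed by random union of two gametes drawn from a
declared haplotype frequency pool, phase discarded. Scenario pools
default to the packaged haplotype-table columns (nonzero entries
renormalized to 1); cohort sizes in tests mirror the published cohorts
(~75–150) or are stated per test. An inbreeding coefficient `f ∈ [0,1]`
duplicates a single draw with probability `f`, producing the
heterozygote deficit that the exact HWE test should detect (`f = 0` is
exact HWE; `f = 1` full autozygosity). A second generator samples loci
independently under HWE — linkage equilibrium by construction — as the
null for LD. All randomness derives from a single stated seed per
scenario; the pipeline derives per-stage substream seeds by hashing
(seed, stage, item), so full runs are replayable and report tables are
byte-identical across reruns.

What the generator does not emulate: genotyping error and allelic
dropout, missing-data patterns, recombination or mutation within the
sampled generation, and population substructure beyond the single
inbreeding coefficient. Passing tests therefore demonstrate correctness
of the inference machinery under the stated sampling model, not
robustness to those real-data artifacts.

## Problem sizes in the standard runs

The packaged checks use: full enumeration HWE at n = 149 (19
configurations); EM recovery on cohorts of 2,000–5,000 individuals
(recovery tolerance 0.02 per haplotype); 1,000 simulated cohorts of
n = 100 for the type-I error check and 200 cohorts for power at
f = 0.5; 200 random trees with up to 12 leaves for NJ recovery; 10,000
individuals for the LD null. These sizes give binomial/sampling error
comfortably inside the asserted tolerances.

## Known limitations

* The Monte-Carlo HWE p-values of the original Markov-chain software are
  not replicated run-for-run (chain length and dememorization are not
  part of this package's contract); only the inferential conclusions are.
* EM reports frequencies, not per-individual phase posteriors.
* DRB1-lineage aggregation of association percentages (e.g., DRB1*15
  over its four-digit alleles) is frequency-weighted; this choice is
  flagged in output metadata because the published tables do not state
  their aggregation rule.
* Bootstrap support, r², haplotype-block detection and ordinations other
  than PCA are out of scope.
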