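# alupop

Population-genetic analysis of the five polymorphic Alu insertions
(POALINs: *AluDPB2*, *AluDQA2*, *AluDQA1*, *AluDRB1*, *AluORF10*) in the
human MHC class II region and their haplotypic association with
HLA-DRB1 alleles.

POALINs are dimorphic insertion/deletion markers: allele `*1` means the Alu
insertion is absent (the ancestral state), `*2` means it is present.
Because an insertion arises once and is inherited by descent, POALIN
frequencies and their multi-locus haplotypes are informative lineage
markers for comparing human populations. `alupop` implements the full
analysis chain used in such surveys:

* **Allele frequencies** by direct counting, `p(a) = n_a / 2n`.
* **Exact Hardy–Weinberg tests** on the conditional (Levene) distribution
  of genotype configurations given allele counts,
  `P(config) = n! 2^h ∏_a n_a! / ((2n)! ∏_g n_g!)`, by full enumeration
  when the configuration space permits and otherwise by a seeded
  Monte-Carlo version (independent random pairings of the fixed allele
  pool); Bonferroni adjustment over the five-locus family.
* **EM haplotype inference**: maximum-likelihood haplotype frequencies
  from unphased genotypes (expectation–maximization over the
  `2^(h−1)` haplotype pairs compatible with each genotype), with the
  classic lexicographic H1–H30 labelling of five-locus Alu haplotypes.
* **Linkage disequilibrium**: per-allele-pair `D`, Lewontin `D′`, and the
  frequency-weighted global `D′ = Σ_ij p_i q_j |D′_ij|`.
* **Percentage haplotypic association**: the share of an HLA-DRB1
  allele's total frequency carried on haplotypes bearing an Alu
  insertion, classified very strong (80–100%), strong (50–80%),
  moderate (20–50%) or low/absent (<20%).
* **Population structure**: Nei's
  `DA = 1 − (1/r) Σ_loci Σ_alleles √(x_a y_a)` distances,
  neighbor-joining trees (Saitou–Nei), and correlation-matrix PCA of
  frequency matrices with per-component "contributions" (% of variance).
* **Synthetic cohorts**: diploid genotype tables simulated by random
  union of gametes from a declared haplotype pool, with an optional
  inbreeding coefficient `f` to induce HWE departures — so every
  inference stage is testable end to end without restricted data.

The published 15-population summary tables (HLA-DRB1 allele frequencies,
Alu allele frequencies and genotype counts, the 30 five-locus haplotypes,
and the DRB1×AluDRB1 association matrix) ship as TSV fixtures, exactly as
printed.

## Worked example

```python
import alupop as ap

# exact HWE test on published genotype counts: Hani population, AluDQA1
freqs, counts = ap.load_reference_table("T3")
gc = counts[("Hani", "AluDQA1")]
print(gc.counts)                       # {('1','1'): 14, ('1','2'): 9, ('2','2'): 126}
print(ap.allele_frequencies_direct(gc))# {'1': 0.1242, '2': 0.8758}
res = ap.hwe_exact(gc)
print(res.p_value)                     # 1.06e-12  -> heterozygote deficit
print(ap.bonferroni_adjust([res.p_value], 5)[0])  # 5.3e-12, << 0.01

# EM haplotype inference on a simulated cohort
hap = ap.load_reference_table("T4")
sc = ap.scenario_from_fixture(hap, "Hani", n=5000, seed=42)
cohort = ap.simulate_population(sc)
est = ap.em_haplotype_frequencies(cohort, ap.ALU_LOCUS_NAMES, "Hani",
                                  n_restarts=1)
print(est.frequency(("1", "1", "2", "1", "1")))   # ~0.33 (pool value 0.332)
```

The first block shows the hallmark result at *AluDQA1*: with only 9
heterozygotes where ~32 are expected, the exact test rejects HWE
decisively even after multiplying by the five-locus test family. The
second block simulates 5,000 diploid individuals from the Hani haplotype
pool, strips phase, and shows EM recovering the predominant
insertion-only-at-*AluDQA1* haplotype frequency.

A command-line interface mirrors the library
(`alupop freq | hwe | em | ld | assoc | distance | nj | pca | simulate |
compare | run`); `alupop run config.yaml` executes the whole pipeline and
writes report tables, a Newick tree and a reproducible run log.

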