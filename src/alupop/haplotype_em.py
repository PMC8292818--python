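"""Maximum-likelihood haplotype frequency estimation via EM.

Phase is unobserved: a genotype heterozygous at ``h`` loci is compatible
with ``2^(h-1)`` unordered haplotype pairs.  Under random mating the
likelihood of haplotype frequencies ``f`` is multinomial over genotypes,
each genotype probability being the sum of ``2^{h1 != h2} f(h1) f(h2)``
over its compatible pairs.  The EM iteration distributes each individual's
two haplotype "doses" over the compatible pairs in proportion to their
current probability (E-step) and re-estimates frequencies as expected
dosage over 2n (M-step); the log-likelihood never decreases.

The classic H1..H30 naming of five-locus Alu haplotypes is lexicographic
over the observed haplotype union with allele "1" < "2".
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .genotype_data import GenotypeTable, ValidationError

__all__ = [
    "Haplotype",
    "HaplotypeFrequencyTable",
    "enumerate_compatible_pairs",
    "em_haplotype_frequencies",
    "em_from_genotype_patterns",
    "label_haplotypes",
]

Haplotype = tuple[str, ...]

#: Estimated frequencies below this are pruned from the returned table.
PRUNE_THRESHOLD = 1e-6


@dataclass
class HaplotypeFrequencyTable:
    population: str
    loci: tuple[str, ...]
    frequencies: dict[Haplotype, float]
    log_likelihood: float
    labels: Optional[dict[Haplotype, str]] = None
    metadata: dict = field(default_factory=dict)

    def frequency(self, hap: Haplotype) -> float:
        return self.frequencies.get(tuple(hap), 0.0)


def enumerate_compatible_pairs(
    genotype: Sequence[tuple[str, str]]
) -> list[tuple[Haplotype, Haplotype]]:
    """All unordered haplotype pairs consistent with an unphased genotype.

    There are ``2^(h-1)`` pairs for ``h`` heterozygous loci (1 pair when
    fully homozygous): the orientation at the first heterozygous locus is
    fixed to avoid double-counting the unordered pair.
    """
    het_idx = [i for i, (a, b) in enumerate(genotype) if a != b]
    pairs: list[tuple[Haplotype, Haplotype]] = []
    n_free = max(len(het_idx) - 1, 0)
    for mask in range(2 ** n_free):
        h1 = [a for (a, _) in genotype]
        h2 = [b for (_, b) in genotype]
        for bit, idx in enumerate(het_idx[1:]):
            if (mask >> bit) & 1:
                h1[idx], h2[idx] = h2[idx], h1[idx]
        pairs.append((tuple(h1), tuple(h2)))
    return pairs


def _collect_patterns(table: GenotypeTable, loci: Sequence[str], population: str):
    """Distinct complete-case genotype patterns and their multiplicities."""
    patterns: dict[tuple[tuple[str, str], ...], int] = {}
    for ind in table.individuals:
        if ind.population != population:
            continue
        gs = [ind.genotypes.get(loc) for loc in loci]
        if any(g is None for g in gs):
            continue
        key = tuple(gs)  # type: ignore[arg-type]
        patterns[key] = patterns.get(key, 0) + 1
    return patterns


def em_from_genotype_patterns(
    patterns: dict[tuple[tuple[str, str], ...], int],
    loci: Sequence[str],
    population: str = "",
    tol: float = 1e-8,
    max_iter: int = 10_000,
    n_restarts: int = 10,
    seed: int = 0,
) -> HaplotypeFrequencyTable:
    """Run EM on pre-tallied genotype patterns (the core worker).

    Restart 0 starts uniform over the compatible-haplotype union; further
    restarts draw symmetric Dirichlet(1) starts.  The best restart by final
    log-likelihood is returned; frequencies < 1e-6 are pruned from the
    output (never during iteration).
    """
    if not patterns:
        raise ValidationError("no complete-case individuals for EM")
    n = sum(patterns.values())

    pair_sets = {g: enumerate_compatible_pairs(g) for g in patterns}
    hap_union = sorted({h for ps in pair_sets.values() for pair in ps for h in pair})
    hap_index = {h: i for i, h in enumerate(hap_union)}
    K = len(hap_union)

    # per pattern: arrays of (i, j, het_flag) over compatible pairs
    compiled = []
    for g, mult in patterns.items():
        ps = pair_sets[g]
        i_idx = np.array([hap_index[a] for a, _ in ps])
        j_idx = np.array([hap_index[b] for _, b in ps])
        coef = np.where(i_idx != j_idx, 2.0, 1.0)
        compiled.append((mult, i_idx, j_idx, coef))

    rng = np.random.default_rng(seed)
    best: Optional[tuple[float, np.ndarray, int, bool]] = None
    for restart in range(max(n_restarts, 1)):
        if restart == 0:
            f = np.full(K, 1.0 / K)
        else:
            f = rng.dirichlet(np.ones(K))
        prev_ll = -np.inf
        converged = False
        for it in range(1, max_iter + 1):
            dosage = np.zeros(K)
            ll = 0.0
            for mult, i_idx, j_idx, coef in compiled:
                w = coef * f[i_idx] * f[j_idx]
                tot = w.sum()
                if tot <= 0:
                    # degenerate start lost support for this pattern
                    ll = -np.inf
                    break
                ll += mult * math.log(tot)
                w *= mult / tot
                np.add.at(dosage, i_idx, w)
                np.add.at(dosage, j_idx, w)
            if not np.isfinite(ll):
                break
            assert ll >= prev_ll - 1e-9 * max(1.0, abs(prev_ll)), \
                "EM log-likelihood decreased"
            new_f = dosage / (2 * n)
            delta = np.abs(new_f - f).max()
            f = new_f
            if ll - prev_ll < 0 and abs(ll - prev_ll) < 1e-12:
                ll = prev_ll
            prev_ll = ll
            if delta < tol:
                converged = True
                break
        if np.isfinite(prev_ll) and (best is None or prev_ll > best[0]):
            best = (prev_ll, f.copy(), it, converged)
    assert best is not None
    ll, f, iters, converged = best
    freqs = {
        hap_union[i]: float(f[i]) for i in range(K) if f[i] >= PRUNE_THRESHOLD
    }
    return HaplotypeFrequencyTable(
        population=population,
        loci=tuple(loci),
        frequencies=freqs,
        log_likelihood=float(ll),
        metadata={
            "iterations": iters,
            "tolerance": tol,
            "n_restarts": n_restarts,
            "converged": converged,
            "n_individuals": n,
            "seed": seed,
        },
    )


def em_haplotype_frequencies(
    table: GenotypeTable,
    loci: Sequence[str],
    population: str,
    tol: float = 1e-8,
    max_iter: int = 10_000,
    n_restarts: int = 10,
    seed: int = 0,
) -> HaplotypeFrequencyTable:
    """ML haplotype frequencies for one population over the chosen loci.

    Individuals missing any of the analysis loci are excluded
    (complete-case); the number excluded is recorded in the metadata.
    """
    patterns = _collect_patterns(table, loci, population)
    n_pop = sum(1 for ind in table.individuals if ind.population == population)
    result = em_from_genotype_patterns(
        patterns, loci, population=population, tol=tol,
        max_iter=max_iter, n_restarts=n_restarts, seed=seed,
    )
    result.metadata["n_excluded_missing"] = n_pop - result.metadata["n_individuals"]
    return result


def label_haplotypes(
    tables: Sequence[HaplotypeFrequencyTable],
) -> dict[Haplotype, str]:
    """Assign H1..Hk labels over the union of observed haplotypes.

    All tables must share the same locus order.  Haplotypes with positive
    frequency in any table are collected, sorted lexicographically by
    allele vector ("1" < "2"), and labelled H1, H2, ... in that order.
    """
    if not tables:
        raise ValidationError("no haplotype tables given")
    loci = tables[0].loci
    for t in tables[1:]:
        if t.loci != loci:
            raise ValidationError(
                f"inconsistent locus order: {t.loci} vs {loci}"
            )
    union = sorted({h for t in tables for h, f in t.frequencies.items() if f > 0})
    labels = {h: f"H{k}" for k, h in enumerate(union, start=1)}
    for t in tables:
        t.labels = {h: labels[h] for h in t.frequencies if h in labels}
    return labels
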