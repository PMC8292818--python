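"""Linkage disequilibrium (D') and percentage haplotypic association.

For a pair of loci with haplotype frequencies ``p_ij`` and marginals
``p_i``, ``q_j``:

    D_ij  = p_ij - p_i q_j
    D'_ij = D_ij / D_max_ij            (Lewontin normalization)
    global D' = sum_ij p_i q_j |D'_ij|

The percentage association of an HLA allele with an Alu insertion is the
share of the allele's total frequency carried on haplotypes bearing the
insertion (Alu*2), classified very strong / strong / moderate / low.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

from scipy import stats

from .genotype_data import ValidationError
from .haplotype_em import Haplotype, HaplotypeFrequencyTable

__all__ = [
    "LDResult",
    "AssociationResult",
    "pairwise_d_prime",
    "percentage_association",
    "classify_association",
    "fisher_exact_2x2",
    "INSERTION_ALLELE",
]

#: Allele code for "Alu insertion present" at a dimorphic Alu locus.
INSERTION_ALLELE = "2"


@dataclass
class LDResult:
    locus_pair: tuple[str, str]
    d: dict[tuple[str, str], float]
    d_max: dict[tuple[str, str], float]
    d_prime: dict[tuple[str, str], float]
    global_d_prime: float
    source: str = "em_haplotypes"


def _marginals(freqs: Mapping[Haplotype, float]) -> tuple[dict[str, float], dict[str, float]]:
    p: dict[str, float] = {}
    q: dict[str, float] = {}
    for (a, b), f in freqs.items():
        p[a] = p.get(a, 0.0) + f
        q[b] = q.get(b, 0.0) + f
    return p, q


def pairwise_d_prime(hapfreqs: HaplotypeFrequencyTable,
                     source: str = "em_haplotypes") -> LDResult:
    """Per-allele-pair D, D_max, D' and the frequency-weighted global D'."""
    if len(hapfreqs.loci) != 2:
        raise ValidationError("pairwise LD needs a two-locus haplotype table")
    freqs = hapfreqs.frequencies
    total = sum(freqs.values())
    if abs(total - 1.0) > 1e-6:
        raise ValidationError(f"haplotype frequencies sum to {total}, not 1")
    p, q = _marginals(freqs)
    for hap in freqs:
        if p.get(hap[0], 0.0) <= 0 or q.get(hap[1], 0.0) <= 0:
            raise ValidationError(f"haplotype {hap} has a zero marginal")
    d: dict[tuple[str, str], float] = {}
    d_max: dict[tuple[str, str], float] = {}
    d_prime: dict[tuple[str, str], float] = {}
    g = 0.0
    for i, pi in p.items():
        for j, qj in q.items():
            dij = freqs.get((i, j), 0.0) - pi * qj
            if dij < 0:
                dm = min(pi * qj, (1 - pi) * (1 - qj))
            else:
                dm = min(pi * (1 - qj), (1 - pi) * qj)
            dp = dij / dm if dm > 0 else 0.0
            d[(i, j)] = dij
            d_max[(i, j)] = dm
            d_prime[(i, j)] = dp
            g += pi * qj * abs(dp)
    return LDResult(
        locus_pair=hapfreqs.loci, d=d, d_max=d_max, d_prime=d_prime,
        global_d_prime=g, source=source,
    )


@dataclass
class AssociationResult:
    hla_allele: str
    alu_locus: str
    population: str
    percent: float
    category: str
    hla_total_frequency: float


def classify_association(percent: float) -> str:
    """Strength category on half-open bins [80,100] / [50,80) / [20,50) / [0,20)."""
    if not (0.0 <= percent <= 100.0):
        raise ValidationError(f"percentage {percent} outside [0, 100]")
    if percent >= 80.0:
        return "very_strong"
    if percent >= 50.0:
        return "strong"
    if percent >= 20.0:
        return "moderate"
    return "low_or_absent"


def percentage_association(hapfreqs: HaplotypeFrequencyTable, hla_allele: str,
                           insertion_allele: str = INSERTION_ALLELE) -> AssociationResult:
    """Share of an HLA allele's frequency carried with the Alu insertion.

    ``hapfreqs`` must be a two-locus table ordered (HLA locus, Alu locus).
    """
    if len(hapfreqs.loci) != 2:
        raise ValidationError("association needs a two-locus (HLA, Alu) table")
    seen_alleles = {hap[0] for hap in hapfreqs.frequencies}
    if hla_allele not in seen_alleles:
        raise ValidationError(
            f"HLA allele {hla_allele!r} absent from the haplotype table for "
            f"population {hapfreqs.population!r} (either absent in the "
            "population or not estimated)"
        )
    total = sum(f for hap, f in hapfreqs.frequencies.items() if hap[0] == hla_allele)
    with_ins = sum(
        f for hap, f in hapfreqs.frequencies.items()
        if hap[0] == hla_allele and hap[1] == insertion_allele
    )
    if total <= 0:
        raise ValidationError(f"HLA allele {hla_allele!r} has zero total frequency")
    percent = 100.0 * with_ins / total
    percent = min(max(percent, 0.0), 100.0)
    return AssociationResult(
        hla_allele=hla_allele,
        alu_locus=hapfreqs.loci[1],
        population=hapfreqs.population,
        percent=percent,
        category=classify_association(percent),
        hla_total_frequency=total,
    )


def fisher_exact_2x2(count_table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher's exact p-value for a 2x2 count table.

    Sums hypergeometric probabilities of all tables no more probable than
    the observed one.  A zero margin makes the test degenerate: p = 1 is
    returned with a warning.
    """
    (a, b), (c, d) = count_table
    for x in (a, b, c, d):
        if x < 0 or x != int(x):
            raise ValidationError("counts must be non-negative integers")
    if min(a + b, c + d, a + c, b + d) == 0:
        warnings.warn("degenerate 2x2 table (zero margin); p = 1", stacklevel=2)
        return 1.0
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])
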