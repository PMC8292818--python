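"""Direct-counting allele frequencies and exact Hardy-Weinberg tests.

The HWE test is the conditional exact test: given the observed allele
counts, every genotype configuration has Levene probability

    P(config) = n! * 2^h * prod_a n_a! / ((2n)! * prod_g n_g!)

where ``h`` is the number of heterozygotes, ``n_a`` allele counts and
``n_g`` genotype counts.  The p-value sums P over all configurations no
more probable than the observed one.  Small configuration spaces are fully
enumerated; otherwise a plain Monte-Carlo version samples configurations by
random pairing of the fixed allele pool (an independent-replicates variant
of the Guo-Thompson Markov-chain test, targeting the same null
distribution).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterator, Optional, Sequence

import numpy as np

from .genotype_data import GenotypeCounts, ValidationError, canonical_pair

__all__ = [
    "HWEResult",
    "allele_frequencies_direct",
    "hwe_exact",
    "hwe_monte_carlo",
    "hwe_test",
    "bonferroni_adjust",
    "DEFAULT_MC_REPLICATES",
    "ENUMERATION_LIMIT",
]

#: Full enumeration is used when the configuration space is no larger than this.
ENUMERATION_LIMIT = 1_000_000
#: Default replicate count for the Monte-Carlo exact test.
DEFAULT_MC_REPLICATES = 170_000
#: Relative log-probability slack treating near-equal probabilities as ties.
_TIE_TOL = 1e-9


def allele_frequencies_direct(counts: GenotypeCounts) -> dict[str, float]:
    """Allele frequencies by direct counting: freq(a) = (# copies of a) / 2n.

    Computed in exact rational arithmetic so the frequencies sum to one
    before the final float conversion.
    """
    if counts.n < 1:
        raise ValidationError("need at least one individual")
    two_n = 2 * counts.n
    fracs = {a: Fraction(c, two_n) for a, c in counts.allele_counts().items()}
    assert sum(fracs.values()) == 1
    return {a: float(f) for a, f in fracs.items()}


@dataclass
class HWEResult:
    locus: str
    population: str
    p_value: float
    method: str  # "enumeration" | "monte_carlo"
    p_adjusted: Optional[float] = None
    n_configurations: Optional[int] = None
    n_replicates: Optional[int] = None
    seed: Optional[int] = None
    monomorphic: bool = False


def _log_config_prob(n: int, allele_counts: Sequence[int],
                     genotype_counts: Sequence[int], n_het: int) -> float:
    two_n = 2 * n
    lp = (math.lgamma(n + 1) + n_het * math.log(2.0)
          + sum(math.lgamma(c + 1) for c in allele_counts)
          - math.lgamma(two_n + 1)
          - sum(math.lgamma(c + 1) for c in genotype_counts))
    return lp


def _enumerate_biallelic(n1: int, n2: int) -> Iterator[tuple[int, int, int]]:
    """All (n11, n12, n22) with 2*n11 + n12 = n1 and n12 + 2*n22 = n2."""
    for h in range(n1 % 2, min(n1, n2) + 1, 2):
        yield ((n1 - h) // 2, h, (n2 - h) // 2)


def _enumerate_multiallelic(allele_counts: list[int]) -> Iterator[dict[tuple[int, int], int]]:
    """All symmetric genotype-count configurations with the given allele counts.

    Recursion over heterozygote counts involving the first allele, then the
    remaining alleles; aborts via StopIteration from the caller if too large.
    """
    k = len(allele_counts)

    def rec(remaining: list[int], offset: int) -> Iterator[dict[tuple[int, int], int]]:
        if not remaining:
            yield {}
            return
        n0 = remaining[0]
        rest = remaining[1:]
        # choose het counts h_j of allele 0 with each later allele j
        ranges = [range(0, min(n0, rj) + 1) for rj in rest]
        for hets in itertools.product(*ranges):
            used = sum(hets)
            if used > n0 or (n0 - used) % 2:
                continue
            sub = [rj - hj for rj, hj in zip(rest, hets)]
            base = {(offset, offset): (n0 - used) // 2}
            for j, h in enumerate(hets, start=1):
                if h:
                    base[(offset, offset + j)] = h
            for tail in rec(sub, offset + 1):
                out = dict(base)
                out.update(tail)
                yield out

    yield from rec(list(allele_counts), 0)


def _observed_stats(counts: GenotypeCounts) -> tuple[list[str], list[int], float]:
    acounts = counts.allele_counts()
    alleles = sorted(acounts)
    n_het = sum(c for (a, b), c in counts.counts.items() if a != b)
    lobs = _log_config_prob(
        counts.n, [acounts[a] for a in alleles], list(counts.counts.values()), n_het
    )
    return alleles, [acounts[a] for a in alleles], lobs


def hwe_exact(counts: GenotypeCounts, enumeration_limit: int = ENUMERATION_LIMIT) -> HWEResult:
    """Exact conditional HWE test by full enumeration.

    Monomorphic data has a single configuration and returns p = 1 with the
    ``monomorphic`` flag.  Raises if the configuration space exceeds
    ``enumeration_limit`` (use :func:`hwe_monte_carlo` or :func:`hwe_test`).
    """
    alleles, acounts, lobs = _observed_stats(counts)
    if len(alleles) == 1:
        return HWEResult(counts.locus.name, counts.population, 1.0,
                         "enumeration", n_configurations=1, monomorphic=True)
    n = counts.n
    p_sum = 0.0
    total = 0.0
    n_configs = 0
    if len(alleles) == 2:
        configs = (
            {(0, 0): a, (0, 1): h, (1, 1): b}
            for a, h, b in _enumerate_biallelic(*acounts)
        )
    else:
        configs = _enumerate_multiallelic(acounts)
    for cfg in configs:
        n_configs += 1
        if n_configs > enumeration_limit:
            raise ValidationError(
                f"configuration space exceeds {enumeration_limit}; "
                "use the Monte-Carlo test"
            )
        n_het = sum(c for (i, j), c in cfg.items() if i != j)
        lp = _log_config_prob(n, acounts, [c for c in cfg.values() if c > 0], n_het)
        pr = math.exp(lp)
        total += pr
        if lp <= lobs + _TIE_TOL:
            p_sum += pr
    # the conditional probabilities must cover the space
    assert abs(total - 1.0) < 1e-6, f"enumeration incomplete: total={total}"
    return HWEResult(counts.locus.name, counts.population, min(p_sum, 1.0),
                     "enumeration", n_configurations=n_configs)


def hwe_monte_carlo(counts: GenotypeCounts, n_replicates: int = DEFAULT_MC_REPLICATES,
                    seed: int = 0) -> HWEResult:
    """Monte-Carlo exact HWE test by independent random pairings.

    Each replicate shuffles the fixed pool of 2n allele copies and pairs
    consecutive copies into genotypes; the p-value is
    ``(1 + #{replicates at most as probable as observed}) / (1 + R)``.
    """
    if n_replicates < 1000:
        raise ValidationError("n_replicates must be >= 1000")
    alleles, acounts, lobs = _observed_stats(counts)
    if len(alleles) == 1:
        return HWEResult(counts.locus.name, counts.population, 1.0,
                         "monte_carlo", n_replicates=n_replicates, seed=seed,
                         monomorphic=True)
    rng = np.random.default_rng(seed)
    pool = np.repeat(np.arange(len(alleles)), acounts)
    n = counts.n
    hits = 0
    for _ in range(n_replicates):
        rng.shuffle(pool)
        pairs = pool.reshape(n, 2)
        lo = pairs.min(axis=1)
        hi = pairs.max(axis=1)
        codes = lo * len(alleles) + hi
        gcounts = np.bincount(codes)
        gcounts = gcounts[gcounts > 0]
        n_het = int((lo != hi).sum())
        lp = _log_config_prob(n, acounts, gcounts.tolist(), n_het)
        if lp <= lobs + _TIE_TOL:
            hits += 1
    p = (1 + hits) / (1 + n_replicates)
    return HWEResult(counts.locus.name, counts.population, p, "monte_carlo",
                     n_replicates=n_replicates, seed=seed)


def _count_configurations(allele_counts: Sequence[int], limit: int) -> int:
    """Size of the configuration space, counting lazily up to ``limit`` + 1."""
    if len(allele_counts) == 2:
        n1, n2 = allele_counts
        return min(n1, n2) // 2 + 1
    n = 0
    for _ in _enumerate_multiallelic(list(allele_counts)):
        n += 1
        if n > limit:
            return n
    return n


def hwe_test(counts: GenotypeCounts, n_replicates: int = DEFAULT_MC_REPLICATES,
             seed: int = 0, enumeration_limit: int = ENUMERATION_LIMIT) -> HWEResult:
    """Exact test by enumeration when feasible, Monte-Carlo otherwise."""
    acounts = sorted(counts.allele_counts().values())
    if _count_configurations(acounts, enumeration_limit) <= enumeration_limit:
        return hwe_exact(counts, enumeration_limit)
    return hwe_monte_carlo(counts, n_replicates=n_replicates, seed=seed)


def bonferroni_adjust(p_values: Sequence[float], m: int) -> list[float]:
    """Bonferroni family-wise adjustment: min(1, p * m)."""
    if m < len(p_values):
        raise ValidationError("family size m must be >= number of p-values")
    for p in p_values:
        if not (0.0 <= p <= 1.0):
            raise ValidationError(f"p-value {p} outside [0, 1]")
    return [min(1.0, p * m) for p in p_values]
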