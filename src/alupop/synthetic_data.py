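"""Synthetic diploid cohorts with the structure the analyses assume.

Cohorts are formed by random union of gametes: each individual draws two
haplotypes independently from a declared haplotype frequency pool (random
mating), or, with probability ``f`` (an inbreeding coefficient), draws one
haplotype and duplicates it, inducing the heterozygote deficit that the
exact HWE test should detect.  Phase is discarded: only per-locus unordered
genotypes are emitted, which is exactly what EM haplotype inference has to
undo.  A second generator samples loci independently (linkage equilibrium),
the null for LD statistics.

Cohort sizes and haplotype pools default to the study conditions: pools are
taken from the packaged five-locus haplotype table's population columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .genotype_data import (
    ALU_LOCUS_NAMES,
    GenotypeTable,
    Individual,
    Locus,
    ValidationError,
    alu_locus,
    canonical_pair,
)
from .haplotype_em import Haplotype

__all__ = [
    "SimulationScenario",
    "scenario_from_fixture",
    "simulate_population",
    "simulate_frequency_only_population",
]


@dataclass
class SimulationScenario:
    population_name: str
    haplotype_pool: dict[Haplotype, float]
    n_individuals: int
    inbreeding_f: float = 0.0
    seed: int = 0
    loci: tuple[str, ...] = ALU_LOCUS_NAMES

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ValidationError("n_individuals must be >= 1")
        if not (0.0 <= self.inbreeding_f <= 1.0):
            raise ValidationError("inbreeding_f must be in [0, 1]")
        total = sum(self.haplotype_pool.values())
        if total <= 0:
            raise ValidationError("haplotype pool has zero total frequency")
        self.haplotype_pool = {
            tuple(h): f / total for h, f in self.haplotype_pool.items() if f > 0
        }
        for h in self.haplotype_pool:
            if len(h) != len(self.loci):
                raise ValidationError(
                    f"haplotype {h} length != number of loci {len(self.loci)}"
                )


def scenario_from_fixture(table: pd.DataFrame, population: str, n: int,
                          seed: int = 0, inbreeding_f: float = 0.0) -> SimulationScenario:
    """Scenario whose pool is a population column of the packaged
    five-locus haplotype table, renormalized over its nonzero entries."""
    if population not in table.columns:
        raise ValidationError(f"population {population!r} not in haplotype table")
    pool: dict[Haplotype, float] = {}
    for _, row in table.iterrows():
        f = float(row[population])
        if f > 0:
            hap = tuple(str(row[loc]) for loc in ALU_LOCUS_NAMES)
            pool[hap] = f
    if not pool:
        raise ValidationError(f"population {population!r} has an all-zero column")
    return SimulationScenario(
        population_name=population, haplotype_pool=pool, n_individuals=n,
        inbreeding_f=inbreeding_f, seed=seed,
    )


def _loci_objects(scenario: SimulationScenario) -> list[Locus]:
    loci = []
    for idx, name in enumerate(scenario.loci):
        alleles = sorted({h[idx] for h in scenario.haplotype_pool})
        if set(alleles) <= {"1", "2"}:
            loci.append(alu_locus(name))
        else:
            loci.append(Locus(name=name, kind="multiallelic",
                              allele_codes=tuple(alleles)))
    return loci


def simulate_population(scenario: SimulationScenario) -> GenotypeTable:
    """Diploid cohort by random union of gametes from the haplotype pool.

    With probability ``inbreeding_f`` an individual is autozygous (one
    haplotype drawn and duplicated); otherwise two independent draws.
    Reproducible from the scenario seed.
    """
    rng = np.random.default_rng(scenario.seed)
    haps = list(scenario.haplotype_pool)
    probs = np.array([scenario.haplotype_pool[h] for h in haps])
    probs = probs / probs.sum()
    n = scenario.n_individuals
    first = rng.choice(len(haps), size=n, p=probs)
    second = rng.choice(len(haps), size=n, p=probs)
    if scenario.inbreeding_f > 0:
        auto = rng.random(n) < scenario.inbreeding_f
        second = np.where(auto, first, second)
    table = GenotypeTable(loci=_loci_objects(scenario))
    width = len(str(n))
    for i in range(n):
        h1, h2 = haps[first[i]], haps[second[i]]
        genotypes = {
            name: canonical_pair(h1[k], h2[k])
            for k, name in enumerate(scenario.loci)
        }
        table.individuals.append(Individual(
            sample_id=f"{scenario.population_name}_{i + 1:0{width}d}",
            population=scenario.population_name,
            genotypes=genotypes,
        ))
    return table


def simulate_frequency_only_population(
    freqs: Mapping[str, Mapping[str, float]],
    n: int,
    seed: int = 0,
    population_name: str = "sim",
) -> GenotypeTable:
    """Cohort with each locus sampled independently under HWE.

    Loci are in linkage equilibrium by construction - the null model for
    LD statistics.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    rng = np.random.default_rng(seed)
    loci = []
    draws: dict[str, list[tuple[str, str]]] = {}
    for name, alleles in freqs.items():
        codes = list(alleles)
        p = np.array([alleles[a] for a in codes], dtype=float)
        if p.sum() <= 0:
            raise ValidationError(f"locus {name!r} has zero total frequency")
        p = p / p.sum()
        if set(codes) <= {"1", "2"} and len(codes) == 2:
            loci.append(alu_locus(name))
        else:
            loci.append(Locus(name=name, kind="multiallelic",
                              allele_codes=tuple(sorted(codes))))
        a1 = rng.choice(len(codes), size=n, p=p)
        a2 = rng.choice(len(codes), size=n, p=p)
        draws[name] = [canonical_pair(codes[i], codes[j]) for i, j in zip(a1, a2)]
    table = GenotypeTable(loci=loci)
    width = len(str(n))
    for i in range(n):
        table.individuals.append(Individual(
            sample_id=f"{population_name}_{i + 1:0{width}d}",
            population=population_name,
            genotypes={name: draws[name][i] for name in freqs},
        ))
    return table
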