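"""Data model and I/O for loci, unphased genotypes and allele-frequency tables.

The package analyses two kinds of marker in the MHC class II region:

* dimorphic Alu insertion loci (POALINs), coded ``"1"`` (insertion absent)
  and ``"2"`` (insertion present);
* the multiallelic HLA-DRB1 locus, coded by two-field allele strings such
  as ``"12:02"``.

Genotypes are unordered allele pairs; phase is never observed.  The genotype
file dialect is a TSV with columns ``sample_id``, ``population``, then one
column per locus holding ``a/b`` (missing genotype: ``./.``).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

__all__ = [
    "ALU_LOCUS_NAMES",
    "POPULATIONS",
    "Locus",
    "Individual",
    "GenotypeTable",
    "GenotypeCounts",
    "AlleleFrequencyTable",
    "alu_locus",
    "drb1_locus",
    "read_genotype_table",
    "write_genotype_table",
    "genotype_counts",
    "load_reference_table",
    "load_sample_sizes",
]

#: The five Alu insertion loci in the fixed analysis order used throughout;
#: all five-locus haplotype vectors follow this order.
ALU_LOCUS_NAMES = ("AluDPB2", "AluDQA2", "AluDQA1", "AluDRB1", "AluORF10")

#: The 15 study populations (12 minority groups newly typed, plus the three
#: literature reference populations which are frequency-only for some tables).
POPULATIONS = (
    "Hani", "Jinuo", "Lisu", "Nu", "Jingpo", "Bulang", "Wa", "Dai",
    "Maonan", "Zhuang", "Tu", "Yugur", "Han-Yunnan", "Japanese", "Caucasians",
)

MISSING = "./."


class ValidationError(ValueError):
    """Raised when an input violates the data-model contracts."""


@dataclass(frozen=True)
class Locus:
    """A polymorphic locus with its valid allele codes.

    ``kind`` is ``"dimorphic_alu"`` (allele codes exactly ``("1", "2")``) or
    ``"multiallelic"`` (arbitrary unique allele strings, e.g. DRB1).
    """

    name: str
    kind: str
    allele_codes: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.kind not in ("dimorphic_alu", "multiallelic"):
            raise ValidationError(f"unknown locus kind: {self.kind!r}")
        if self.kind == "dimorphic_alu" and self.allele_codes != ("1", "2"):
            raise ValidationError(
                f"dimorphic Alu locus {self.name} must have alleles ('1','2'), "
                f"got {self.allele_codes}"
            )
        if not self.allele_codes:
            raise ValidationError(f"locus {self.name} has no allele codes")
        if len(set(self.allele_codes)) != len(self.allele_codes):
            raise ValidationError(f"locus {self.name} has duplicate allele codes")


def alu_locus(name: str) -> Locus:
    """A dimorphic Alu insertion locus (``*1`` = absent, ``*2`` = present)."""
    return Locus(name=name, kind="dimorphic_alu", allele_codes=("1", "2"))


def drb1_locus(allele_codes: Optional[Sequence[str]] = None) -> Locus:
    """The multiallelic HLA-DRB1 locus.

    By default the allele universe is the 57 alleles of the packaged
    frequency table; pass ``allele_codes`` to widen or narrow it.
    """
    if allele_codes is None:
        df = _read_fixture("table_drb1_frequencies.tsv")
        allele_codes = [a.split("*", 1)[1] for a in df["allele"]]
    return Locus(name="DRB1", kind="multiallelic", allele_codes=tuple(allele_codes))


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    """Order-free representation of an unphased genotype: sorted pair."""
    return (a, b) if a <= b else (b, a)


@dataclass
class Individual:
    sample_id: str
    population: str
    #: locus name -> canonical allele pair, or None if missing at that locus
    genotypes: dict[str, Optional[tuple[str, str]]]


@dataclass
class GenotypeTable:
    """Per-individual unphased multilocus genotypes grouped by population."""

    loci: list[Locus]
    individuals: list[Individual] = field(default_factory=list)

    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for ind in self.individuals:
            seen.setdefault(ind.population, None)
        return list(seen)

    def locus(self, name: str) -> Locus:
        for loc in self.loci:
            if loc.name == name:
                return loc
        raise KeyError(f"locus {name!r} not in table")

    def validate(self) -> None:
        seen_ids: set[tuple[str, str]] = set()
        for ind in self.individuals:
            key = (ind.population, ind.sample_id)
            if key in seen_ids:
                raise ValidationError(
                    f"duplicate sample_id {ind.sample_id!r} in population "
                    f"{ind.population!r}"
                )
            seen_ids.add(key)
            for loc in self.loci:
                g = ind.genotypes.get(loc.name)
                if g is None:
                    continue
                for allele in g:
                    if allele not in loc.allele_codes:
                        raise ValidationError(
                            f"sample {ind.sample_id}: allele {allele!r} not valid "
                            f"for locus {loc.name}"
                        )


@dataclass
class GenotypeCounts:
    """Genotype counts for one locus in one population (complete cases)."""

    locus: Locus
    population: str
    n: int
    counts: dict[tuple[str, str], int]

    def __post_init__(self) -> None:
        if sum(self.counts.values()) != self.n:
            raise ValidationError("genotype counts do not sum to n")

    def allele_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for (a, b), c in self.counts.items():
            out[a] = out.get(a, 0) + c
            out[b] = out.get(b, 0) + c
        return out


def read_genotype_table(path_or_buf, loci: Sequence[Locus]) -> GenotypeTable:
    """Read the genotype TSV dialect and validate it against ``loci``.

    Unknown allele codes and duplicate sample ids raise ``ValidationError``
    naming the offending row; missing genotypes (``./.``) are kept as missing.
    """
    df = pd.read_csv(path_or_buf, sep="\t", dtype=str)
    expected = ["sample_id", "population"] + [loc.name for loc in loci]
    if list(df.columns) != expected:
        raise ValidationError(
            f"genotype TSV columns {list(df.columns)} != expected {expected}"
        )
    table = GenotypeTable(loci=list(loci))
    for i, row in df.iterrows():
        genotypes: dict[str, Optional[tuple[str, str]]] = {}
        for loc in loci:
            cell = row[loc.name]
            if pd.isna(cell) or cell == MISSING:
                genotypes[loc.name] = None
                continue
            parts = str(cell).split("/")
            if len(parts) != 2:
                raise ValidationError(
                    f"row {i} ({row['sample_id']}), locus {loc.name}: "
                    f"malformed genotype {cell!r}"
                )
            for allele in parts:
                if allele not in loc.allele_codes:
                    raise ValidationError(
                        f"row {i} ({row['sample_id']}), locus {loc.name}: "
                        f"unknown allele code {allele!r}"
                    )
            genotypes[loc.name] = canonical_pair(*parts)
        table.individuals.append(
            Individual(str(row["sample_id"]), str(row["population"]), genotypes)
        )
    table.validate()
    return table


def write_genotype_table(table: GenotypeTable, path_or_buf) -> None:
    """Write a genotype table in the same TSV dialect (canonical pair order)."""
    rows = []
    for ind in table.individuals:
        row: dict[str, str] = {"sample_id": ind.sample_id, "population": ind.population}
        for loc in table.loci:
            g = ind.genotypes.get(loc.name)
            row[loc.name] = MISSING if g is None else f"{g[0]}/{g[1]}"
        rows.append(row)
    cols = ["sample_id", "population"] + [loc.name for loc in table.loci]
    pd.DataFrame(rows, columns=cols).to_csv(path_or_buf, sep="\t", index=False)


def genotype_counts(table: GenotypeTable, locus: Locus | str, population: str) -> GenotypeCounts:
    """Tally canonical genotype pairs for one locus/population.

    Individuals missing at the locus are excluded from ``n`` (complete-case
    per locus); an empty population after exclusions is an error.
    """
    if isinstance(locus, str):
        locus = table.locus(locus)
    counts: dict[tuple[str, str], int] = {}
    n = 0
    present = False
    for ind in table.individuals:
        if ind.population != population:
            continue
        present = True
        g = ind.genotypes.get(locus.name)
        if g is None:
            continue
        counts[g] = counts.get(g, 0) + 1
        n += 1
    if not present:
        raise ValidationError(f"population {population!r} not present in table")
    if n == 0:
        raise ValidationError(
            f"no complete-case individuals for {locus.name} in {population!r}"
        )
    return GenotypeCounts(locus=locus, population=population, n=n, counts=counts)


@dataclass
class AlleleFrequencyTable:
    """Long-format population x locus x allele relative frequencies.

    ``sample_sizes`` may omit populations for which only published
    frequencies (no genotype counts) are available.
    """

    #: (population, locus, allele) -> frequency
    entries: dict[tuple[str, str, str], float]
    sample_sizes: dict[str, int] = field(default_factory=dict)

    def frequency(self, population: str, locus: str, allele: str) -> float:
        return self.entries.get((population, locus, allele), 0.0)

    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for (pop, _, _) in self.entries:
            seen.setdefault(pop, None)
        return list(seen)

    def loci(self) -> list[str]:
        seen: dict[str, None] = {}
        for (_, loc, _) in self.entries:
            seen.setdefault(loc, None)
        return list(seen)

    def profile(self, population: str, loci: Sequence[str]) -> dict[str, dict[str, float]]:
        """Per-locus allele->frequency maps for one population."""
        out: dict[str, dict[str, float]] = {loc: {} for loc in loci}
        found = False
        for (pop, loc, allele), f in self.entries.items():
            if pop == population and loc in out:
                out[loc][allele] = f
                found = True
        if not found:
            raise KeyError(f"population {population!r} has no frequencies for {loci}")
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"population": p, "locus": l, "allele": a, "frequency": f}
            for (p, l, a), f in sorted(self.entries.items())
        ]
        return pd.DataFrame(rows, columns=["population", "locus", "allele", "frequency"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame,
                   sample_sizes: Optional[Mapping[str, int]] = None) -> "AlleleFrequencyTable":
        entries = {
            (str(r.population), str(r.locus), str(r.allele)): float(r.frequency)
            for r in df.itertuples()
        }
        return cls(entries=entries, sample_sizes=dict(sample_sizes or {}))


# ---------------------------------------------------------------------------
# Packaged in-source reference tables
# ---------------------------------------------------------------------------

def _read_fixture(name: str) -> pd.DataFrame:
    text = (resources.files("alupop") / "fixtures" / name).read_text()
    return pd.read_csv(io.StringIO(text), sep="\t", dtype={"allele": str, "genotype": str})


def load_sample_sizes() -> dict[str, int]:
    df = _read_fixture("sample_sizes.tsv")
    return dict(zip(df["population"], df["n"].astype(int)))


def _fixture_drb1_frequencies() -> AlleleFrequencyTable:
    df = _read_fixture("table_drb1_frequencies.tsv").fillna(0.0)
    entries: dict[tuple[str, str, str], float] = {}
    for _, row in df.iterrows():
        allele = str(row["allele"]).split("*", 1)[1]
        for pop in POPULATIONS:
            f = float(row[pop])
            if f > 0:
                entries[(pop, "DRB1", allele)] = f
    return AlleleFrequencyTable(entries=entries, sample_sizes=load_sample_sizes())


def _fixture_alu_frequencies() -> AlleleFrequencyTable:
    df = _read_fixture("table_alu_frequencies.tsv").fillna(0.0)
    entries: dict[tuple[str, str, str], float] = {}
    for _, row in df.iterrows():
        for pop in POPULATIONS:
            # zeros are kept: printed dimorphic frequencies include 0.000
            entries[(pop, str(row["locus"]), str(row["allele"]))] = float(row[pop])
    return AlleleFrequencyTable(entries=entries, sample_sizes=load_sample_sizes())


def _fixture_alu_genotype_counts() -> dict[tuple[str, str], GenotypeCounts]:
    """(population, locus) -> GenotypeCounts for the 13 populations with counts."""
    df = _read_fixture("table_alu_genotype_counts.tsv")
    count_pops = [c for c in df.columns if c not in ("locus", "genotype")]
    out: dict[tuple[str, str], GenotypeCounts] = {}
    for locus_name in dict.fromkeys(df["locus"]):
        loc = alu_locus(locus_name)
        sub = df[df["locus"] == locus_name]
        for pop in count_pops:
            counts: dict[tuple[str, str], int] = {}
            for _, row in sub.iterrows():
                g = str(row["genotype"])
                counts[(g[0], g[1])] = int(row[pop])
            counts = {g: c for g, c in counts.items() if c > 0}
            out[(pop, locus_name)] = GenotypeCounts(
                locus=loc, population=pop, n=sum(counts.values()), counts=counts
            )
    return out


def _fixture_alu_haplotypes() -> pd.DataFrame:
    """The 30 labelled five-locus haplotypes with per-population frequencies."""
    return _read_fixture("table_alu_haplotypes.tsv").fillna(0.0)


def _fixture_association() -> pd.DataFrame:
    """Published percentage association, DRB1 lineage x AluDRB1 (blank = absent)."""
    return _read_fixture("table_drb1_alu_association.tsv")


def load_reference_table(table_id: str):
    """Return a packaged reference table, values verbatim as printed.

    ``T2`` -> HLA-DRB1 :class:`AlleleFrequencyTable` (57 alleles, 15 populations);
    ``T3`` -> ``(AlleleFrequencyTable, {(population, locus): GenotypeCounts})``
    for the five Alu loci (counts exist for 13 populations);
    ``T4`` -> DataFrame of the 30 labelled five-locus haplotypes;
    ``T5`` -> DataFrame of published DRB1-lineage x AluDRB1 association percentages.

    Blank printed cells are zero frequencies, not missing data.
    """
    table_id = table_id.upper()
    if table_id == "T2":
        return _fixture_drb1_frequencies()
    if table_id == "T3":
        return _fixture_alu_frequencies(), _fixture_alu_genotype_counts()
    if table_id == "T4":
        return _fixture_alu_haplotypes()
    if table_id == "T5":
        return _fixture_association()
    raise ValueError(f"unknown fixture table id: {table_id!r} (expected T2..T5)")
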