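"""End-to-end orchestration: frequencies -> HWE -> EM haplotypes -> LD ->
association -> distances / NJ / PCA, with report tables shaped like the
classic population-survey layout (per-population frequency + genotype-count
+ HWE table, labelled haplotype table, association matrix).

A run is a pure function of (inputs, config, seed); rerunning with the same
config reproduces the report tables byte for byte.  Report tables round
frequencies to 3 decimals and association to whole percent; full-precision
TSVs are written alongside.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .genotype_data import (
    ALU_LOCUS_NAMES,
    AlleleFrequencyTable,
    GenotypeTable,
    ValidationError,
    genotype_counts,
    load_reference_table,
    read_genotype_table,
    alu_locus,
    drb1_locus,
)
from .freq_hwe import (
    DEFAULT_MC_REPLICATES,
    allele_frequencies_direct,
    bonferroni_adjust,
    hwe_test,
)
from .haplotype_em import (
    HaplotypeFrequencyTable,
    em_haplotype_frequencies,
    label_haplotypes,
)
from .ld_assoc import fisher_exact_2x2, pairwise_d_prime, percentage_association
from .popgen_distance import distance_matrix, neighbor_joining, pca_frequencies
from .synthetic_data import SimulationScenario, scenario_from_fixture, simulate_population

__all__ = ["PipelineConfig", "run_pipeline", "compare_populations"]


@dataclass
class PipelineConfig:
    """Everything a run depends on; serializable, so runs are replayable."""

    seed: int = 0
    #: genotype TSV paths (may be empty when simulating or fixture-only)
    genotype_paths: list[str] = field(default_factory=list)
    #: simulation scenarios: {population, n, fixture_population?, pool?, inbreeding_f?}
    scenarios: list[dict] = field(default_factory=list)
    #: loci analysed from genotype data
    loci: list[str] = field(default_factory=lambda: list(ALU_LOCUS_NAMES))
    hwe_family_size: int = 5
    hwe_alpha: float = 0.01
    hwe_mc_replicates: int = DEFAULT_MC_REPLICATES
    em_tol: float = 1e-8
    em_max_iter: int = 10_000
    em_n_restarts: int = 3
    pca_convention: str = "correlation"
    #: run distance/NJ/PCA on the packaged frequency fixture instead of data
    fixture_frequencies: bool = False
    output_dir: str = "alupop_out"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def _stage_seed(base_seed: int, stage: str, item: str = "") -> int:
    """Deterministic per-stage substream seed below 2^31."""
    digest = hashlib.sha256(f"{base_seed}:{stage}:{item}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _parse_pool(pool: dict[str, float]) -> dict[tuple[str, ...], float]:
    return {tuple(k.split("-")): float(v) for k, v in pool.items()}


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def compare_populations(
    freqs: AlleleFrequencyTable, locus: str, allele: str,
    pop_a: str, pop_b: str, m: int = 1,
) -> tuple[float, float]:
    """Fisher's exact comparison of an allele (or haplotype-as-allele)
    between two populations on 2n gametes each; returns (p, Bonferroni p)."""
    counts = []
    for pop in (pop_a, pop_b):
        if pop not in freqs.sample_sizes:
            raise ValidationError(
                f"population {pop!r} is frequency-only (no sample size); "
                "gamete counts cannot be derived"
            )
        two_n = 2 * freqs.sample_sizes[pop]
        c = round(freqs.frequency(pop, locus, allele) * two_n)
        counts.append([c, two_n - c])
    p = fisher_exact_2x2(counts)
    return p, bonferroni_adjust([p], m)[0]


def _assemble_genotypes(config: PipelineConfig) -> Optional[GenotypeTable]:
    tables: list[GenotypeTable] = []
    for i, sc in enumerate(config.scenarios):
        seed = sc.get("seed", _stage_seed(config.seed, "simulate", sc["population"]))
        if "fixture_population" in sc:
            scenario = scenario_from_fixture(
                load_reference_table("T4"), sc["fixture_population"],
                n=int(sc["n"]), seed=seed,
                inbreeding_f=float(sc.get("inbreeding_f", 0.0)),
            )
            scenario.population_name = sc["population"]
        else:
            scenario = SimulationScenario(
                population_name=sc["population"],
                haplotype_pool=_parse_pool(sc["pool"]),
                n_individuals=int(sc["n"]),
                inbreeding_f=float(sc.get("inbreeding_f", 0.0)),
                seed=seed,
                loci=tuple(sc.get("loci", config.loci)),
            )
        tables.append(simulate_population(scenario))
    for path in config.genotype_paths:
        loci = [
            drb1_locus() if name == "DRB1" else alu_locus(name)
            for name in config.loci
        ]
        tables.append(read_genotype_table(path, loci))
    if not tables:
        return None
    merged = GenotypeTable(loci=tables[0].loci)
    for t in tables:
        merged.individuals.extend(t.individuals)
    merged.validate()
    return merged


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Run every applicable stage; returns a report manifest.

    With genotype data (simulated and/or read) all stages run; in
    fixture-frequency mode only the frequency-based stages (distance, NJ,
    PCA) run and the genotype-based ones are skipped with a notice.  Any
    stage failure removes the partial outputs and re-raises, naming the
    stage.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    log: dict[str, Any] = {
        "alupop_version": __version__,
        "python": platform.python_version(),
        "config": config.to_dict(),
        "stages": [],
        "notices": [],
    }

    def emit(name: str, df: pd.DataFrame, index: bool = False) -> Path:
        path = outdir / name
        df.to_csv(path, sep="\t", index=index)
        written.append(path)
        return path

    stage = "setup"
    try:
        table = _assemble_genotypes(config)
        alu_loci = [l for l in config.loci if l != "DRB1"]
        freq_entries: dict[tuple[str, str, str], float] = {}
        sample_sizes: dict[str, int] = {}
        hap_tables: dict[str, HaplotypeFrequencyTable] = {}

        if table is not None:
            pops = table.populations()
            stage = "frequencies_hwe"
            rows = []
            for pop in pops:
                pvals, recs = [], []
                for locus in alu_loci:
                    gc = genotype_counts(table, locus, pop)
                    freqs = allele_frequencies_direct(gc)
                    res = hwe_test(
                        gc, n_replicates=config.hwe_mc_replicates,
                        seed=_stage_seed(config.seed, "hwe", f"{pop}:{locus}"),
                    )
                    pvals.append(res.p_value)
                    recs.append((locus, gc, freqs, res))
                    sample_sizes[pop] = max(sample_sizes.get(pop, 0), gc.n)
                adj = bonferroni_adjust(pvals, config.hwe_family_size)
                for (locus, gc, freqs, res), p_adj in zip(recs, adj):
                    res.p_adjusted = p_adj
                    for allele, f in sorted(freqs.items()):
                        freq_entries[(pop, locus, allele)] = f
                    rows.append({
                        "population": pop, "locus": locus, "n": gc.n,
                        **{f"freq_{a}": round(f, 6) for a, f in sorted(freqs.items())},
                        **{f"n_{a}{b}": c for (a, b), c in sorted(gc.counts.items())},
                        "hwe_p": res.p_value, "hwe_p_adjusted": p_adj,
                        "hwe_method": res.method,
                        "significant": p_adj <= config.hwe_alpha,
                    })
            emit("frequencies_hwe.tsv", pd.DataFrame(rows))
            log["stages"].append({"name": stage, "populations": pops})

            stage = "em_haplotypes"
            for pop in pops:
                hap_tables[pop] = em_haplotype_frequencies(
                    table, alu_loci, pop,
                    tol=config.em_tol, max_iter=config.em_max_iter,
                    n_restarts=config.em_n_restarts,
                    seed=_stage_seed(config.seed, "em", pop),
                )
            labels = label_haplotypes(list(hap_tables.values()))
            rows = []
            for hap, lab in labels.items():
                row = {"label": lab,
                       **{loc: a for loc, a in zip(alu_loci, hap)}}
                for pop in pops:
                    row[pop] = round(hap_tables[pop].frequency(hap), 3)
                rows.append(row)
            emit("haplotypes.tsv", pd.DataFrame(rows))
            rows = [
                {"population": pop, "haplotype": "-".join(h), "label": labels.get(h, ""),
                 "frequency": f, "log_likelihood": t.log_likelihood}
                for pop, t in hap_tables.items()
                for h, f in sorted(t.frequencies.items())
            ]
            emit("haplotypes_full.tsv", pd.DataFrame(rows))
            log["stages"].append({"name": stage, "n_haplotypes": len(labels)})

            stage = "ld"
            rows = []
            for pop in pops:
                for la, lb in itertools.combinations(alu_loci, 2):
                    two = em_haplotype_frequencies(
                        table, [la, lb], pop,
                        tol=config.em_tol, max_iter=config.em_max_iter,
                        n_restarts=config.em_n_restarts,
                        seed=_stage_seed(config.seed, "ld", f"{pop}:{la}:{lb}"),
                    )
                    ld = pairwise_d_prime(two)
                    rows.append({"population": pop, "locus_a": la, "locus_b": lb,
                                 "global_d_prime": ld.global_d_prime})
            emit("ld_global_dprime.tsv", pd.DataFrame(rows))
            log["stages"].append({"name": stage, "n_pairs": len(rows)})

            if "DRB1" in config.loci:
                stage = "association"
                rows = []
                for pop in pops:
                    for alu in alu_loci:
                        two = em_haplotype_frequencies(
                            table, ["DRB1", alu], pop,
                            tol=config.em_tol, max_iter=config.em_max_iter,
                            n_restarts=config.em_n_restarts,
                            seed=_stage_seed(config.seed, "assoc", f"{pop}:{alu}"),
                        )
                        for allele in sorted({h[0] for h in two.frequencies}):
                            r = percentage_association(two, allele)
                            rows.append({
                                "population": pop, "hla_allele": allele,
                                "alu_locus": alu, "percent": round(r.percent),
                                "category": r.category,
                                "hla_total_frequency": r.hla_total_frequency,
                            })
                emit("association.tsv", pd.DataFrame(rows))
                log["stages"].append({"name": stage, "n_rows": len(rows)})
            else:
                log["notices"].append("association skipped: no DRB1 locus in config")

        stage = "distances"
        if config.fixture_frequencies:
            freq_table, _ = load_reference_table("T3")
            log["notices"].append(
                "fixture-frequency mode: genotype-based stages skipped; "
                "distance/NJ/PCA computed from the packaged frequency table"
            )
        elif table is not None:
            freq_table = AlleleFrequencyTable(
                entries=freq_entries, sample_sizes=sample_sizes)
        else:
            raise ValidationError(
                "no inputs: provide genotype paths, scenarios, or set "
                "fixture_frequencies: true"
            )
        pops = freq_table.populations()
        if len(pops) >= 2:
            dm = distance_matrix(freq_table, alu_loci, pops)
            emit("distance_matrix.tsv", dm.to_frame().round(6), index=True)
            if len(pops) >= 3:
                stage = "nj_tree"
                tree = neighbor_joining(dm)
                tree_path = outdir / "nj_tree.nwk"
                tree_path.write_text(tree.to_newick() + "\n")
                written.append(tree_path)
            stage = "pca"
            mat = pd.DataFrame(
                {loc: [freq_table.frequency(p, loc, "2") for p in pops]
                 for loc in alu_loci},
                index=pops,
            )
            pca = pca_frequencies(mat, convention=config.pca_convention)
            emit("pca_scores.tsv", pca.scores.round(6), index=True)
            emit("pca_contributions.tsv", pd.DataFrame({
                "component": pca.scores.columns,
                "percent_of_variance": np.round(pca.proportion_of_variance, 4),
            }))
            log["stages"].append({
                "name": "distances_nj_pca", "populations": pops,
                "pca_convention": config.pca_convention,
            })
        else:
            log["notices"].append("distance/NJ/PCA skipped: fewer than 2 populations")

        log["outputs"] = {p.name: _digest(p) for p in written}
        log_path = outdir / "run_log.json"
        log_path.write_text(json.dumps(log, indent=2, sort_keys=True, default=str) + "\n")
        return log
    except Exception as exc:
        for p in written:
            p.unlink(missing_ok=True)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
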