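"""EM haplotype inference: pair enumeration, likelihood oracle, labelling."""

import numpy as np
import pytest

import alupop as ap
from alupop.genotype_data import ValidationError
from alupop.haplotype_em import em_from_genotype_patterns, enumerate_compatible_pairs
from conftest import grid_search_max_loglik, pattern_log_likelihood

ALU = ap.ALU_LOCUS_NAMES


class TestCompatiblePairs:
    @pytest.mark.parametrize("genotype, n_pairs", [
        ((("1", "1"), ("2", "2")), 1),                       # fully homozygous
        ((("1", "2"), ("1", "2")), 2),                       # het at 2 loci
        (tuple([("1", "2")] * 5), 16),                       # het at all 5
    ])
    def test_pair_counts(self, genotype, n_pairs):
        assert len(enumerate_compatible_pairs(genotype)) == n_pairs

    def test_pairs_reconstitute_the_genotype(self):
        genotype = (("1", "2"), ("1", "1"), ("1", "2"), ("2", "2"))
        for h1, h2 in enumerate_compatible_pairs(genotype):
            for k, (a, b) in enumerate(genotype):
                assert tuple(sorted((h1[k], h2[k]))) == (a, b)

    def test_pairs_are_distinct_unordered(self):
        genotype = tuple([("1", "2")] * 3)
        pairs = enumerate_compatible_pairs(genotype)
        canon = {frozenset([h1, h2]) for h1, h2 in pairs}
        assert len(canon) == len(pairs) == 4


def patterns_em(patterns, loci=("A", "B"), **kw):
    kw.setdefault("n_restarts", 5)
    kw.setdefault("seed", 3)
    return em_from_genotype_patterns(dict(patterns), loci, population="p", **kw)


class TestEM:
    def test_phase_known_homozygotes(self):
        res = patterns_em({
            ((("1", "1"), ("1", "1"))): 1,
            ((("2", "2"), ("2", "2"))): 1,
        })
        assert res.frequency(("1", "1")) == pytest.approx(0.5, abs=1e-9)
        assert res.frequency(("2", "2")) == pytest.approx(0.5, abs=1e-9)

    def test_single_double_heterozygote_uniform_start_is_stationary(self):
        # the symmetric point f = 1/4 is a fixed point of the EM map
        res = patterns_em({((("1", "2"), ("1", "2"))): 1}, n_restarts=1, seed=0)
        for hap in [("1", "1"), ("1", "2"), ("2", "1"), ("2", "2")]:
            assert res.frequency(hap) == pytest.approx(0.25, abs=1e-9)

    def test_matches_grid_search_oracle_on_three_individuals(self):
        patterns = {
            ((("1", "1"), ("1", "1"))): 2,
            ((("1", "2"), ("1", "2"))): 1,
        }
        res = patterns_em(patterns)
        hap_order, f_star, ll_star = grid_search_max_loglik(patterns)
        for i, hap in enumerate(hap_order):
            assert res.frequency(hap) == pytest.approx(f_star[i], abs=2e-3)
        assert res.log_likelihood >= ll_star - 1e-6

    @pytest.mark.parametrize("seed", range(6))
    def test_em_likelihood_not_below_grid_oracle(self, seed):
        """On random small two-locus datasets the EM optimum must match the
        simplex grid search within 1e-6 log-likelihood units."""
        rng = np.random.default_rng(seed)
        patterns = {}
        for _ in range(rng.integers(2, 6)):
            g = (tuple(sorted(rng.choice(["1", "2"], 2))),
                 tuple(sorted(rng.choice(["1", "2"], 2))))
            patterns[g] = patterns.get(g, 0) + int(rng.integers(1, 4))
        res = patterns_em(patterns, n_restarts=10, seed=seed)
        _, _, ll_star = grid_search_max_loglik(patterns)
        assert res.log_likelihood >= ll_star - 1e-6

    def test_frequencies_sum_to_one(self):
        res = patterns_em({
            ((("1", "2"), ("1", "1"))): 3,
            ((("1", "1"), ("1", "2"))): 2,
            ((("2", "2"), ("1", "2"))): 1,
        })
        assert sum(res.frequencies.values()) == pytest.approx(1.0, abs=1e-9)

    def test_no_heterozygotes_equals_gamete_counting(self):
        patterns = {
            ((("1", "1"), ("1", "1"))): 3,
            ((("2", "2"), ("2", "2"))): 1,
            ((("1", "1"), ("2", "2"))): 4,
        }
        res = patterns_em(patterns)
        assert res.frequency(("1", "1")) == pytest.approx(6 / 16, abs=1e-12)
        assert res.frequency(("2", "2")) == pytest.approx(2 / 16, abs=1e-12)
        assert res.frequency(("1", "2")) == pytest.approx(8 / 16, abs=1e-12)

    def test_no_complete_cases_is_an_error(self):
        table = ap.GenotypeTable(loci=[ap.alu_locus(n) for n in ALU])
        with pytest.raises(ValidationError):
            ap.em_haplotype_frequencies(table, ALU, "nobody")

    def test_parameter_recovery_from_simulated_cohort(self, hap_fixture):
        """EM recovers the generating pool from phase-stripped cohorts."""
        errs = []
        for seed in range(3):
            sc = ap.scenario_from_fixture(hap_fixture, "Bulang", n=2000, seed=seed)
            table = ap.simulate_population(sc)
            est = ap.em_haplotype_frequencies(
                table, ALU, "Bulang", n_restarts=1, seed=seed)
            errs.append(max(
                abs(est.frequency(h) - f) for h, f in sc.haplotype_pool.items()))
        assert max(errs) < 0.02


class TestLabelling:
    def test_fixture_union_reproduces_the_published_h_labels(self, hap_fixture):
        tables = []
        for pop in ap.POPULATIONS:
            freqs = {}
            for _, row in hap_fixture.iterrows():
                if row[pop] > 0:
                    freqs[tuple(str(row[l]) for l in ALU)] = float(row[pop])
            tables.append(ap.HaplotypeFrequencyTable(pop, ALU, freqs, 0.0))
        labels = ap.label_haplotypes(tables)
        assert len(labels) == 30
        assert labels[("1", "1", "1", "1", "1")] == "H1"
        assert labels[("1", "1", "2", "1", "1")] == "H5"
        assert labels[("2", "1", "2", "1", "1")] == "H21"
        assert labels[("2", "2", "2", "2", "2")] == "H30"
        # every published row keeps its label under lexicographic naming
        for _, row in hap_fixture.iterrows():
            hap = tuple(str(row[l]) for l in ALU)
            assert labels[hap] == row["label"]

    def test_single_haplotype_union(self):
        t = ap.HaplotypeFrequencyTable("p", ALU, {("1",) * 5: 1.0}, 0.0)
        assert ap.label_haplotypes([t]) == {("1",) * 5: "H1"}

    def test_inconsistent_locus_order_rejected(self):
        a = ap.HaplotypeFrequencyTable("p", ALU, {("1",) * 5: 1.0}, 0.0)
        b = ap.HaplotypeFrequencyTable("q", tuple(reversed(ALU)),
                                       {("1",) * 5: 1.0}, 0.0)
        with pytest.raises(ValidationError):
            ap.label_haplotypes([a, b])
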