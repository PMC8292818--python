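"""Nei DA distances, neighbor joining, frequency PCA."""

import numpy as np
import pandas as pd
import pytest

import alupop as ap
from alupop.genotype_data import ValidationError
from conftest import random_additive_tree


def profile(**loci):
    return {k: dict(v) for k, v in loci.items()}


class TestNeiDA:
    def test_identical_profiles_give_zero(self):
        x = profile(L={"1": 0.3, "2": 0.7})
        assert ap.nei_da(x, x, ["L"]) == 0.0

    def test_fixed_opposite_profiles_give_one(self):
        x = profile(L={"1": 1.0, "2": 0.0})
        y = profile(L={"1": 0.0, "2": 1.0})
        assert ap.nei_da(x, y, ["L"]) == 1.0

    def test_arithmetic_example(self):
        x = profile(L={"1": 0.9, "2": 0.1})
        y = profile(L={"1": 0.1, "2": 0.9})
        assert ap.nei_da(x, y, ["L"]) == pytest.approx(0.4)

    def test_missing_locus_rejected(self):
        with pytest.raises(ValidationError):
            ap.nei_da(profile(L={"1": 1.0}), profile(M={"1": 1.0}), ["L"])

    def test_symmetric_and_bounded(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            px, py = rng.dirichlet([1] * 3), rng.dirichlet([1] * 3)
            x = profile(L=dict(zip("abc", px)))
            y = profile(L=dict(zip("abc", py)))
            d = ap.nei_da(x, y, ["L"])
            assert d == ap.nei_da(y, x, ["L"])
            assert 0 <= d <= 1


class TestDistanceMatrix:
    def test_identical_populations_off_diagonal_zero(self):
        entries = {}
        for pop in ("a", "b"):
            entries[(pop, "L", "1")] = 0.4
            entries[(pop, "L", "2")] = 0.6
        dm = ap.distance_matrix(ap.AlleleFrequencyTable(entries), ["L"], ["a", "b"])
        assert dm.values[0, 1] == 0.0

    def test_fixture_15_population_matrix_properties(self, alu_freqs):
        pops = list(ap.POPULATIONS)
        dm = ap.distance_matrix(alu_freqs, list(ap.ALU_LOCUS_NAMES), pops)
        v = dm.values
        assert v.shape == (15, 15)
        assert np.allclose(v, v.T) and np.allclose(np.diag(v), 0)
        assert (v >= 0).all() and (v <= 1).all()
        off = v[~np.eye(15, dtype=bool)]
        assert (off > 0).all()

    def test_single_population(self, alu_freqs):
        dm = ap.distance_matrix(alu_freqs, list(ap.ALU_LOCUS_NAMES), ["Hani"])
        assert dm.values.shape == (1, 1) and dm.values[0, 0] == 0

    def test_missing_population_named_in_error(self, alu_freqs):
        with pytest.raises(KeyError, match="Atlantis"):
            ap.distance_matrix(alu_freqs, list(ap.ALU_LOCUS_NAMES), ["Atlantis"])


class TestNeighborJoining:
    def test_three_taxon_branch_lengths(self):
        dm = ap.DistanceMatrix(["A", "B", "C"],
                               np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0.]]))
        tree = ap.neighbor_joining(dm)
        lengths = {c.name: c.length for c in tree.children}
        assert lengths == pytest.approx({"A": 1.0, "B": 1.0, "C": 3.0})

    def test_four_taxon_additive_exact_recovery(self):
        # tree ((A:1,B:2):1,(C:1,D:1))
        d = np.array([[0, 3, 3, 3], [3, 0, 4, 4], [3, 4, 0, 2], [3, 4, 2, 0.]])
        tree = ap.neighbor_joining(ap.DistanceMatrix(list("ABCD"), d))
        assert frozenset({"A", "B"}) in tree.bipartitions()
        # leaf branch lengths recovered exactly
        lengths = {}
        def collect(node):
            if node.is_leaf():
                lengths[node.name] = node.length
            for c in node.children:
                collect(c)
        collect(tree)
        assert lengths == pytest.approx({"A": 1, "B": 2, "C": 1, "D": 1})

    def test_fewer_than_three_labels_rejected(self):
        with pytest.raises(ValidationError):
            ap.neighbor_joining(ap.DistanceMatrix(["A", "B"], np.zeros((2, 2))))

    def test_equal_distances_tie_break_is_deterministic(self):
        d = np.ones((5, 5)) - np.eye(5)
        dm = ap.DistanceMatrix(list("ABCDE"), d)
        assert ap.neighbor_joining(dm).to_newick() == \
            ap.neighbor_joining(dm).to_newick()

    def test_topology_recovery_on_random_additive_matrices(self):
        rng = np.random.default_rng(7)
        for _ in range(40):
            n = int(rng.integers(4, 11))
            labels, d, true_sides = random_additive_tree(rng, n)
            tree = ap.neighbor_joining(ap.DistanceMatrix(labels, d))
            assert tree.bipartitions() == true_sides

    def test_agrees_with_independent_nj_implementation(self):
        skbio = pytest.importorskip("skbio")
        from skbio import DistanceMatrix as SkDM
        from skbio.tree import nj as sk_nj
        rng = np.random.default_rng(21)
        labels, d, _ = random_additive_tree(rng, 8)
        d += rng.uniform(0, 0.02, d.shape)  # mild noise, keep symmetric
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        ours = ap.neighbor_joining(ap.DistanceMatrix(labels, d))
        theirs = sk_nj(SkDM(d, ids=labels))
        their_sides = set()
        all_leaves = frozenset(labels)
        for node in theirs.non_tips():
            side = frozenset(t.name for t in node.tips())
            if 1 < len(side) < len(labels) - 1:
                their_sides |= {side, all_leaves - side}
        assert ours.bipartitions() == their_sides

    def test_fixture_tree_groups_the_daic_populations(self, alu_freqs):
        """The five-Alu DA tree puts Dai, Zhuang and Maonan (Daic language
        subfamily) in one clade."""
        pops = list(ap.POPULATIONS)
        dm = ap.distance_matrix(alu_freqs, list(ap.ALU_LOCUS_NAMES), pops)
        tree = ap.neighbor_joining(dm)
        assert frozenset({"Dai", "Zhuang", "Maonan"}) in tree.bipartitions()


class TestPCA:
    def test_perfectly_correlated_pair_loads_on_pc1(self):
        x = np.linspace(0.1, 0.9, 8)
        mat = pd.DataFrame({"a": x, "b": 2 * x})
        res = ap.pca_frequencies(mat, convention="correlation")
        assert res.proportion_of_variance[0] == pytest.approx(100.0)

    def test_uncorrelated_standardized_variables_share_variance(self):
        rng = np.random.default_rng(5)
        raw = rng.normal(size=(40, 3))
        q, _ = np.linalg.qr(raw - raw.mean(axis=0))  # centered orthogonal columns
        mat = pd.DataFrame(q, columns=list("abc"))
        res = ap.pca_frequencies(mat, convention="correlation")
        assert res.proportion_of_variance == pytest.approx([100 / 3] * 3, abs=1e-6)

    def test_proportions_sum_to_100(self, alu_freqs):
        pops = list(ap.POPULATIONS)
        mat = pd.DataFrame(
            {l: [alu_freqs.frequency(p, l, "2") for p in pops]
             for l in ap.ALU_LOCUS_NAMES}, index=pops)
        for conv in ("correlation", "covariance"):
            res = ap.pca_frequencies(mat, convention=conv)
            assert res.proportion_of_variance.sum() == pytest.approx(100.0, abs=1e-6)
            assert (res.proportion_of_variance >= 0).all()

    def test_zero_variance_variable_dropped_with_warning(self):
        mat = pd.DataFrame({"a": [0.1, 0.5, 0.9], "b": [0.2, 0.2, 0.2]})
        with pytest.warns(UserWarning, match="zero-variance"):
            res = ap.pca_frequencies(mat, convention="correlation")
        assert res.variables == ["a"]

    def test_all_constant_rejected(self):
        mat = pd.DataFrame({"a": [0.2, 0.2], "b": [0.3, 0.3]})
        with pytest.raises(ValidationError):
            ap.pca_frequencies(mat)
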