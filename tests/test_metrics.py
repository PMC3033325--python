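"""Forest evaluation metrics: DRR, ECR, MRCA levels, haplotype diversity."""

import numpy as np
import pytest

from ldforest import (Coding, Forest, SnpMatrix, dimension_reduction_rate,
                      entropy_compression_rate, forest_grouping,
                      layer_statistics, most_common_haplotypes, mrca_levels,
                      tree_count)
from ldforest.metrics import SENTINEL, joint_entropy
from conftest import toy_forest


def isolated_forest(p):
    f = Forest()
    for i in range(p):
        f.add_observed(f"S{i + 1}", 2, prior=np.array([0.5, 0.5]))
    return f


class TestDrrAndTreeCount:
    def test_all_isolated(self):
        f = isolated_forest(7)
        assert dimension_reduction_rate(f) == 1.0
        assert tree_count(f) == 7

    def test_single_tree_over_ten_snps(self):
        f = Forest()
        for i in range(10):
            f.add_observed(f"S{i}", 2)
        f.add_latent("H1_1", 4, [f"S{i}" for i in range(10)],
                     np.full(4, 0.25), [np.full((2, 4), 0.5)] * 10,
                     np.zeros(3, dtype=np.int64))
        assert dimension_reduction_rate(f) == pytest.approx(0.1)
        assert tree_count(f) == 1 == len(f.roots())

    def test_toy_forest(self):
        f = toy_forest()
        assert tree_count(f) == 2  # H2_1 tree + isolated S5
        assert dimension_reduction_rate(f) == pytest.approx(2 / 5)


class TestEcr:
    def test_all_singletons_is_one(self, rng):
        m = SnpMatrix(rng.integers(0, 2, size=(100, 4)), Coding.haplotype_01)
        grouping = [[n] for n in m.marker_names]
        assert entropy_compression_rate(grouping, m) == pytest.approx(1.0)

    def test_two_identical_snps_halve_entropy(self, rng):
        col = rng.integers(0, 2, 100)
        m = SnpMatrix(np.column_stack([col, col]), Coding.haplotype_01,
                      marker_names=["A", "B"])
        assert entropy_compression_rate([["A", "B"]], m) == pytest.approx(0.5)

    def test_subadditivity_bound(self, rng):
        m = SnpMatrix(rng.integers(0, 3, size=(60, 6)), Coding.genotype_012)
        grouping = [m.marker_names[:4], m.marker_names[4:]]
        assert entropy_compression_rate(grouping, m) <= 1 + 1e-9

    def test_incomplete_grouping_rejected(self, rng):
        m = SnpMatrix(rng.integers(0, 2, size=(10, 3)), Coding.haplotype_01)
        with pytest.raises(ValueError):
            entropy_compression_rate([m.marker_names[:2]], m)

    def test_constant_matrix_undefined(self):
        m = SnpMatrix(np.zeros((10, 2), dtype=int), Coding.haplotype_01)
        with pytest.raises(ValueError):
            entropy_compression_rate([[n] for n in m.marker_names], m)

    def test_joint_entropy_matches_tuple_counts(self):
        data = np.array([[0, 0], [0, 0], [1, 1], [1, 0]])
        # tuples: (0,0)x2, (1,1), (1,0) -> H = 1.5 bits
        assert joint_entropy(data) == pytest.approx(1.5)


class TestMrca:
    def test_toy_levels(self):
        mm = mrca_levels(toy_forest())
        names = mm.marker_names
        lv = {(a, b): mm.levels[names.index(a), names.index(b)]
              for a in names for b in names}
        assert lv[("S1", "S2")] == 1      # siblings under H1_1
        assert lv[("S1", "S3")] == 2      # cousins under H2_1
        assert lv[("S1", "S5")] == SENTINEL
        assert lv[("S1", "S1")] == 0

    def test_sentinel_rendered_as_N(self):
        df = mrca_levels(toy_forest()).to_dataframe()
        assert df.loc["S1", "S5"] == "N"

    def test_matches_brute_force_on_random_forests(self, rng):
        for trial in range(10):
            f = isolated_forest(0)
            n_obs = int(rng.integers(4, 12))
            for i in range(n_obs):
                f.add_observed(f"S{i}", 2, prior=np.array([0.5, 0.5]))
            # randomly merge roots until <=30 nodes or few roots remain
            h = 0
            while len(f.roots()) > 2 and f.n_nodes < 30 and rng.random() < 0.9:
                roots = f.roots()
                k = min(len(roots), int(rng.integers(2, 4)))
                pick = list(rng.choice(roots, size=k, replace=False))
                h += 1
                f.add_latent(f"H_{h}", 2, pick, np.array([0.5, 0.5]),
                             [np.full((f.nodes[c].cardinality, 2), 0.5)
                              for c in pick], np.zeros(2, dtype=np.int64))
            mm = mrca_levels(f)
            names = mm.marker_names
            for i in range(len(names)):
                for j in range(i + 1, len(names)):
                    anc_i = set(f.ancestors(names[i]))
                    common = [a for a in f.ancestors(names[j]) if a in anc_i]
                    expected = (SENTINEL if not common
                                else f.nodes[common[0]].layer)
                    assert mm.levels[i, j] == expected


class TestHaplotypeDiversity:
    def test_single_haplotype(self):
        assert most_common_haplotypes(np.zeros((20, 3), dtype=int)) == 1

    def test_four_equifrequent_needs_three(self):
        data = np.repeat(np.array([[0, 0], [0, 1], [1, 0], [1, 1]]), 5, axis=0)
        assert most_common_haplotypes(data, coverage=0.75) == 3

    def test_skewed_frequencies(self):
        rows = ([[0, 0]] * 5 + [[0, 1]] * 3 + [[1, 0]] * 1 + [[1, 1]] * 1)
        assert most_common_haplotypes(np.array(rows), coverage=0.75) == 2

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            most_common_haplotypes(np.empty((0, 2), dtype=int))


class TestLayerStatistics:
    def test_forest_without_latents(self, rng):
        f = isolated_forest(4)
        m = SnpMatrix(rng.integers(0, 2, size=(30, 4)), Coding.haplotype_01,
                      marker_names=[f"S{i + 1}" for i in range(4)])
        stats = layer_statistics(f, m)
        assert len(stats) == 1
        assert stats.loc[0, "n_variables"] == 4
        assert np.isnan(stats.loc[0, "mean_scaled_mi"])

    def test_toy_counts(self, rng):
        f = toy_forest()
        # toy imputed data has n=8 rows; build a matching matrix
        m = SnpMatrix(rng.integers(0, 2, size=(8, 5)), Coding.haplotype_01,
                      marker_names=[f"S{i + 1}" for i in range(5)])
        stats = layer_statistics(f, m)
        assert list(stats.n_variables) == [5, 2, 1]

    def test_grouping_covers_all_snps(self):
        groups = forest_grouping(toy_forest())
        flat = sorted(n for g in groups for n in g)
        assert flat == ["S1", "S2", "S3", "S4", "S5"]
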