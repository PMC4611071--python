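"""Hypergeometric enrichment, overlap distance, UPGMA dendrograms."""

import itertools
from math import comb

import numpy as np
import pytest

from senscreen.fixtures import GeneUniverseSpec, gen_gene_fixture
from senscreen.netprofiles import (
    Dendrogram,
    DistanceMatrix,
    ProcessNetwork,
    enrich_profile,
    hypergeom_upper_tail,
    profile_distance_matrix,
    profile_heatmap_table,
    profile_overlap_distance,
    read_gmt,
    upgma,
    write_gmt,
)


def tail_by_summation(k, K, n, N):
    """Independent oracle: direct summation of the hypergeometric tail."""
    total = comb(N, n)
    return sum(comb(K, j) * comb(N - K, n - j) for j in range(k, min(K, n) + 1)) / total


class TestUpperTail:
    def test_k_zero_is_certain(self):
        assert hypergeom_upper_tail(0, 4, 5, 10) == 1.0

    def test_small_case_equals_enumeration(self):
        # N=10, K=4, n=5, k>=3: 66 of the C(10,5)=252 draws
        assert hypergeom_upper_tail(3, 4, 5, 10) == pytest.approx(66 / 252, abs=1e-12)
        assert tail_by_summation(3, 4, 5, 10) == pytest.approx(66 / 252, abs=1e-15)

    def test_total_overlap_forced(self):
        assert hypergeom_upper_tail(7, 7, 7, 7) == pytest.approx(1.0)

    def test_matches_summation_oracle_widely(self, rng):
        for _ in range(200):
            N = int(rng.integers(2, 2000))
            K = int(rng.integers(1, N + 1))
            n = int(rng.integers(1, N + 1))
            k = int(rng.integers(0, min(K, n) + 1))
            assert hypergeom_upper_tail(k, K, n, N) == pytest.approx(
                tail_by_summation(k, K, n, N), abs=1e-12
            )

    def test_non_increasing_in_k(self):
        ps = [hypergeom_upper_tail(k, 40, 30, 200) for k in range(0, 31)]
        assert all(b <= a + 1e-15 for a, b in zip(ps, ps[1:]))

    def test_inconsistent_arguments_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_upper_tail(5, 4, 5, 10)
        with pytest.raises(ValueError):
            hypergeom_upper_tail(1, 11, 5, 10)


class TestEnrichment:
    def _networks(self):
        return [
            ProcessNetwork("n1", "one", frozenset(f"G{i}" for i in range(10))),
            ProcessNetwork("n2", "two", frozenset(f"G{i}" for i in range(10, 15))),
        ]

    def test_disjoint_list_p_one(self):
        profile = enrich_profile(
            [f"G{i}" for i in range(20, 25)], self._networks(), universe_size=100
        )
        assert profile.pvalues["n2"] == 1.0 or profile.pvalues["n2"] < 1.0
        # G20..G24 intersect neither network
        assert profile.pvalues["n1"] == 1.0
        assert "n1" not in profile.significant

    def test_identical_list_minimizes_p(self):
        networks = self._networks()
        profile = enrich_profile(sorted(networks[1].genes), networks, universe_size=100)
        assert profile.pvalues["n2"] < profile.pvalues["n1"]
        assert profile.pvalues["n2"] == pytest.approx(
            tail_by_summation(5, 5, 5, 100), abs=1e-15
        )

    def test_planted_fixture_matches_oracle(self):
        spec = GeneUniverseSpec(
            n_genes=1000,
            network_sizes=(50,) * 5,
            planted_lists={"L": {"net000": 20}},
            list_size=40,
            seed=3,
        )
        networks, lists = gen_gene_fixture(spec)
        profile = enrich_profile(lists["L"], networks, universe_size=1000, label="L")
        assert profile.pvalues["net000"] == pytest.approx(
            tail_by_summation(20, 50, 40, 1000), abs=1e-12
        )

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            enrich_profile([], self._networks())

    def test_gmt_roundtrip(self, tmp_path):
        networks = self._networks()
        write_gmt(networks, tmp_path / "nets.gmt")
        back = read_gmt(tmp_path / "nets.gmt")
        assert [(n.id, n.genes) for n in back] == [(n.id, n.genes) for n in networks]


class TestOverlapDistance:
    def test_disjoint_sets_distance_one(self):
        a = {f"n{i}" for i in range(5)}
        b = {f"n{i}" for i in range(5, 12)}
        assert profile_overlap_distance(a, b, 169) == 1.0

    def test_identical_sets_match_forced_tail(self):
        a = {f"n{i}" for i in range(5)}
        assert profile_overlap_distance(a, a, 169) == pytest.approx(
            tail_by_summation(5, 5, 5, 169), abs=1e-15
        )

    def test_symmetry(self, rng):
        universe = [f"n{i}" for i in range(169)]
        for _ in range(20):
            a = set(rng.choice(universe, size=rng.integers(1, 40), replace=False))
            b = set(rng.choice(universe, size=rng.integers(1, 40), replace=False))
            assert profile_overlap_distance(a, b) == pytest.approx(
                profile_overlap_distance(b, a), abs=1e-15
            )

    def test_self_distance_below_random_expectation(self, rng):
        universe = [f"n{i}" for i in range(169)]
        a = set(universe[:8])
        d_self = profile_overlap_distance(a, a)
        draws = [
            profile_overlap_distance(
                a, set(rng.choice(universe, size=8, replace=False))
            )
            for _ in range(1000)
        ]
        assert d_self <= np.mean(draws)

    def test_oversized_set_rejected(self):
        with pytest.raises(ValueError):
            profile_overlap_distance({f"n{i}" for i in range(10)}, set(), n_networks=5)


def _matrix(labels, entries):
    n = len(labels)
    values = np.zeros((n, n))
    for (i, j), v in entries.items():
        values[i, j] = values[j, i] = v
    return DistanceMatrix(labels=labels, values=values)


class TestUPGMA:
    def test_two_leaves(self):
        tree = upgma(_matrix(["A", "B"], {(0, 1): 0.4}))
        assert tree.heights == [0.4]

    def test_three_leaf_hand_example(self):
        tree = upgma(
            _matrix(["A", "B", "C"], {(0, 1): 0.2, (0, 2): 0.6, (1, 2): 0.8})
        )
        assert tree.heights == pytest.approx([0.2, 0.7])
        assert tree.merges[0][:2] == (0, 1)  # A joins B first

    def test_merge_heights_non_decreasing(self, rng):
        for _ in range(20):
            n = 6
            d = rng.uniform(0.1, 1.0, size=(n, n))
            d = (d + d.T) / 2
            np.fill_diagonal(d, 0)
            tree = upgma(DistanceMatrix(labels=[f"L{i}" for i in range(n)], values=d))
            assert all(b >= a - 1e-12 for a, b in zip(tree.heights, tree.heights[1:]))

    def test_agrees_with_reference_linkage(self, rng):
        from scipy.cluster.hierarchy import linkage
        from scipy.spatial.distance import squareform

        for _ in range(30):
            n = 5
            d = rng.uniform(0.05, 1.0, size=(n, n))
            d = (d + d.T) / 2
            np.fill_diagonal(d, 0)
            tree = upgma(DistanceMatrix(labels=[f"L{i}" for i in range(n)], values=d))
            Z = linkage(squareform(d, checks=False), method="average")
            np.testing.assert_allclose(sorted(tree.heights), sorted(Z[:, 2]), atol=1e-10)

    def test_label_permutation_preserves_topology(self):
        entries = {(0, 1): 0.2, (0, 2): 0.6, (1, 2): 0.8}
        t1 = upgma(_matrix(["A", "B", "C"], entries))
        # permute rows: C,A,B with the same underlying distances
        perm = _matrix(
            ["C", "A", "B"], {(1, 2): 0.2, (0, 1): 0.6, (0, 2): 0.8}
        )
        t2 = upgma(perm)
        assert t1.heights == pytest.approx(t2.heights)

    def test_newick_export_parses(self):
        tree = upgma(
            _matrix(["A", "B", "C"], {(0, 1): 0.2, (0, 2): 0.6, (1, 2): 0.8})
        )
        nwk = tree.to_newick()
        import io

        from Bio import Phylo

        parsed = Phylo.read(io.StringIO(nwk), "newick")
        assert {t.name for t in parsed.get_terminals()} == {"A", "B", "C"}


class TestHeatmapTable:
    def _profiles(self):
        networks = [
            ProcessNetwork(f"n{i}", f"N{i}", frozenset(f"G{j}" for j in range(5 * i, 5 * i + 5)))
            for i in range(10)
        ]
        profiles = []
        for i in range(3):
            genes = sorted(networks[i].genes)
            profiles.append(
                enrich_profile(genes, networks, universe_size=100, label=f"P{i}")
            )
        return profiles

    def test_dimensions_and_flags(self):
        table = profile_heatmap_table(self._profiles())
        value_cols = [c for c in table.columns if not c.endswith("__sig")]
        assert table.shape[0] == 3 and len(value_cols) == 10

    def test_p_one_maps_to_zero(self):
        table = profile_heatmap_table(self._profiles())
        # P0 is disjoint from n5, so its tail p is 1 -> -log10 = 0
        assert table.loc["P0", "n5"] == 0.0

    def test_significance_is_strict(self):
        from senscreen.netprofiles import ProfileVector

        p = ProfileVector(
            label="x", pvalues={"a": 0.05, "b": 0.049}, n_genes=5, universe_size=100
        )
        assert p.significant == {"b"}

    def test_distance_matrix_construction(self):
        profiles = self._profiles()
        dm = profile_distance_matrix(profiles, n_networks=10)
        assert np.allclose(np.diag(dm.values), 0)
        assert np.allclose(dm.values, dm.values.T)
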