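import itertools

import networkx as nx
import numpy as np
import pytest

from chipsmith.genotype_qc import GenotypeMatrix
from chipsmith.haplotypes import (
    extract_gene_haplotypes,
    hamming,
    haplotype_diversity,
    median_joining_network,
    minimum_spanning_network,
    subset_saturation,
)


def matrix_from(calls, **meta):
    calls = np.asarray(calls, dtype=np.int8)
    return GenotypeMatrix(
        samples=[f"s{i}" for i in range(calls.shape[0])],
        snps=[f"m{j}" for j in range(calls.shape[1])],
        calls=calls,
        snp_meta=meta,
    )


class TestExtraction:
    def test_two_patterns_equal_frequency(self):
        m = matrix_from([[0, 0], [0, 0], [2, 2], [2, 2]])
        t = extract_gene_haplotypes(m, ["m0", "m1"])
        assert t.n == 4 and t.n_haplotypes == 2
        assert sorted(t.frequencies.values()) == [0.5, 0.5]

    def test_missing_call_excludes_sample_by_default(self):
        m = matrix_from([[0, 0], [0, -1], [2, 2]])
        t = extract_gene_haplotypes(m, ["m0", "m1"])
        assert t.n == 2 and "s1" not in t.assignments

    def test_het_call_excludes_sample_by_default(self):
        m = matrix_from([[0, 1], [2, 2]])
        t = extract_gene_haplotypes(m, ["m0", "m1"])
        assert list(t.assignments) == ["s1"]

    def test_het_as_missing_policy_keeps_samples(self):
        m = matrix_from([[0, 1], [2, 2]])
        t = extract_gene_haplotypes(m, ["m0", "m1"], policy="het-as-missing")
        assert t.n == 2 and t.assignments["s0"] == "AN"

    def test_uses_allele_labels_when_present(self):
        m = matrix_from([[0, 2]], ref=["A", "C"], alt=["G", "T"])
        t = extract_gene_haplotypes(m, ["m0", "m1"])
        assert t.assignments["s0"] == "AT"

    def test_no_assignable_samples_errors(self):
        m = matrix_from([[1, 1]])
        with pytest.raises(ValueError):
            extract_gene_haplotypes(m, ["m0", "m1"])

    def test_partition_equals_string_grouping_oracle(self):
        rng = np.random.default_rng(14)
        calls = rng.choice([0, 2], size=(30, 6)).astype(np.int8)
        m = matrix_from(calls)
        t = extract_gene_haplotypes(m, m.snps)
        from collections import Counter

        oracle = Counter("".join("AB"[c // 2] for c in row) for row in calls)
        assert t.counts == dict(sorted(oracle.items(), key=lambda kv: (-kv[1], kv[0])))


class TestDiversity:
    def test_monomorphic_is_zero(self):
        assert haplotype_diversity({"h": 1.0}, n=10) == 0.0

    def test_two_distinct_of_two_is_one(self):
        assert haplotype_diversity({"a": 0.5, "b": 0.5}, n=2) == pytest.approx(1.0)

    def test_closed_form_example(self):
        hd = haplotype_diversity({"a": 0.5, "b": 0.25, "c": 0.25}, n=8)
        assert hd == pytest.approx(8 / 7 * (1 - 0.375))

    def test_undefined_below_two_samples(self):
        with pytest.raises(ValueError):
            haplotype_diversity({"a": 1.0}, n=1)

    def test_relabeling_invariance_and_equal_freq_maximum(self):
        freqs = [0.4, 0.35, 0.25]
        perms = {
            haplotype_diversity(dict(zip("abc", p)), n=20)
            for p in itertools.permutations(freqs)
        }
        assert len(perms) == 1
        uneven = haplotype_diversity(dict(zip("abc", freqs)), n=20)
        even = haplotype_diversity({k: 1 / 3 for k in "abc"}, n=20)
        assert even > uneven


class TestNetwork:
    def test_single_mutation_pair(self):
        g = median_joining_network(["AA", "AB"])
        assert list(g.edges(data="weight")) == [("AA", "AB", 1)]
        assert not any(nx.get_node_attributes(g, "median").values())

    def test_triangle_gains_one_median(self):
        g = median_joining_network(["BAA", "ABA", "AAB"])
        medians = [n for n, m in g.nodes(data="median") if m]
        assert medians == ["AAA"]
        assert sorted(g.edges("AAA")) == [("AAA", "AAB"), ("AAA", "ABA"), ("AAA", "BAA")]
        assert g.nodes["AAA"]["frequency"] == 0

    def test_unequal_lengths_error(self):
        with pytest.raises(ValueError):
            median_joining_network(["AA", "AAB"])

    def test_node_count_at_least_observed_and_connected(self):
        rng = np.random.default_rng(18)
        for _ in range(20):
            haps = {"".join(rng.choice(list("AB"), size=6)) for _ in range(rng.integers(2, 8))}
            g = median_joining_network(sorted(haps))
            assert g.number_of_nodes() >= len(haps)
            assert nx.is_connected(g)

    def test_contains_brute_force_mst_as_subgraph(self):
        rng = np.random.default_rng(27)
        for _ in range(20):
            haps = sorted({"".join(rng.choice(list("AB"), size=7)) for _ in range(rng.integers(2, 9))})
            g = median_joining_network(haps)
            full = nx.Graph()
            nodes = list(g.nodes)
            for i, u in enumerate(nodes):
                for v in nodes[i + 1 :]:
                    full.add_edge(u, v, weight=hamming(u, v))
            mst = nx.minimum_spanning_tree(full)
            for u, v in mst.edges:
                assert g.has_edge(u, v)
            # equal total weight: the network's own spanning tree is minimum
            net_mst = nx.minimum_spanning_tree(g)
            assert net_mst.size(weight="weight") == mst.size(weight="weight")

    def test_edge_weights_equal_hamming_and_paths_bounded_below(self):
        haps = ["AAAA", "AABB", "BBAA", "ABAB"]
        g = median_joining_network(haps)
        for u, v, w in g.edges(data="weight"):
            assert w == hamming(u, v) >= 1
        for u, v in itertools.combinations(haps, 2):
            assert nx.shortest_path_length(g, u, v, weight="weight") >= hamming(u, v)

    def test_msn_is_union_of_msts(self):
        rng = np.random.default_rng(4)
        haps = sorted({"".join(rng.choice(list("AB"), size=5)) for _ in range(8)})
        msn = minimum_spanning_network(haps)
        # every MSN edge belongs to some MST: removing it must not allow a
        # strictly cheaper spanning tree, and forcing it must not cost more
        full = nx.Graph()
        for i, u in enumerate(haps):
            for v in haps[i + 1 :]:
                full.add_edge(u, v, weight=hamming(u, v))
        best = nx.minimum_spanning_tree(full).size(weight="weight")
        for u, v in msn.edges:
            g2 = full.copy()
            w = g2.edges[u, v]["weight"]
            g2.edges[u, v]["weight"] = w - 0.5  # strictly prefer this edge
            forced = nx.minimum_spanning_tree(g2)
            assert forced.has_edge(u, v)
            assert forced.size(weight="weight") + 0.5 == pytest.approx(best)


class TestSaturation:
    def _gene_matrix(self, n_samples=40, n_snps=12, seed=2):
        rng = np.random.default_rng(seed)
        calls = rng.choice([0, 2], size=(n_samples, n_snps)).astype(np.int8)
        return matrix_from(calls)

    def test_full_size_returns_full_count(self):
        m = self._gene_matrix()
        full = extract_gene_haplotypes(m, m.snps).n_haplotypes
        out = subset_saturation(m, m.snps, sizes=[len(m.snps)], replicates=2, seed=1)
        assert all(c == full for c in out.values())

    def test_single_biallelic_snp_bound(self):
        m = self._gene_matrix()
        out = subset_saturation(m, m.snps, sizes=[1], replicates=5, seed=3)
        assert all(c <= 2 for c in out.values())

    def test_subset_counts_never_exceed_full(self):
        m = self._gene_matrix()
        full = extract_gene_haplotypes(m, m.snps).n_haplotypes
        out = subset_saturation(m, m.snps, sizes=[2, 4, 8, 12], replicates=5, seed=7)
        assert all(c <= full for c in out.values())

    def test_mean_count_non_decreasing_in_size(self):
        m = self._gene_matrix(n_samples=60, seed=9)
        sizes = [1, 3, 6, 12]
        out = subset_saturation(m, m.snps, sizes=sizes, replicates=100, seed=11)
        means = [np.mean([out[(s, r)] for r in range(100)]) for s in sizes]
        assert all(a <= b + 1e-9 for a, b in zip(means, means[1:]))

    def test_oversized_subset_errors(self):
        m = self._gene_matrix()
        with pytest.raises(ValueError):
            subset_saturation(m, m.snps, sizes=[13], seed=0)

    def test_seed_determinism(self):
        m = self._gene_matrix()
        a = subset_saturation(m, m.snps, sizes=[4], replicates=3, seed=5)
        b = subset_saturation(m, m.snps, sizes=[4], replicates=3, seed=5)
        assert a == b
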