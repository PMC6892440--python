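"""PPI connectivity, communities, permutation nulls, set enrichment, membership."""

import itertools

import networkx as nx
import numpy as np
import pytest

import helpers
from sibnet.datasets import SIGNALING_COHORT_SIZE, load_signaling_membership
from sibnet.genesets import GeneSetCollection
from sibnet.membership import build_membership_matrix
from sibnet.network import (
    community_enrichment,
    connectivity_permutation_p,
    curate_gene_sets,
    density,
    detect_communities,
    evaluate_communities,
    induced_subgraph,
    jaccard,
)


class TestInducedSubgraph:
    def test_full_cover_returns_network(self):
        g = nx.cycle_graph(5)
        sub, unmatched = induced_subgraph(g, list(g.nodes) + [99])
        assert set(sub.edges) == set(g.edges)
        assert unmatched == [99]

    def test_disjoint_list_empty(self):
        sub, unmatched = induced_subgraph(nx.path_graph(3), ["x", "y"])
        assert sub.number_of_nodes() == 0
        assert unmatched == ["x", "y"]

    def test_clique_restriction(self):
        sub, _ = induced_subgraph(nx.complete_graph(5), [0, 1, 2])
        assert sub.number_of_edges() == 3  # triangle


class TestDensity:
    def test_examples(self):
        assert density(nx.complete_graph(3)) == pytest.approx(1.0)
        assert density(nx.path_graph(3)) == pytest.approx(2 / 3)
        assert density(nx.empty_graph(1)) is None

    def test_monotone_under_edge_addition(self):
        g = nx.empty_graph(6)
        prev = density(g)
        for u, v in itertools.combinations(range(6), 2):
            g.add_edge(u, v)
            cur = density(g)
            assert cur >= prev
            prev = cur


class TestDetectCommunities:
    def test_two_disjoint_cliques(self):
        g = nx.disjoint_union(nx.complete_graph(5), nx.complete_graph(5))
        res = detect_communities(g)
        assert sorted(sorted(c) for c in res.communities.values()) == [
            list(range(5)),
            list(range(5, 10)),
        ]

    def test_single_node_singleton(self):
        res = detect_communities(nx.empty_graph(1))
        assert res.communities == {0: {0}}

    def test_isolated_nodes_become_singletons(self):
        g = nx.complete_graph(4)
        g.add_nodes_from(["iso1", "iso2"])
        res = detect_communities(g)
        sizes = sorted(len(c) for c in res.communities.values())
        assert sizes == [1, 1, 4]
        assert {g for c in res.communities.values() for g in c} == set(g.nodes)

    def test_planted_partition_recovery(self):
        from sklearn.metrics import adjusted_rand_score

        sizes = [25, 25, 25, 25]
        g = nx.stochastic_block_model(sizes, np.where(np.eye(4), 0.9, 0.02).tolist(), seed=5)
        res = detect_communities(g)
        truth = [b for b, size in enumerate(sizes) for _ in range(size)]
        member = res.membership()
        pred = [member[i] for i in range(100)]
        assert adjusted_rand_score(truth, pred) > 0.9


class TestConnectivityPermutation:
    def test_edgeless_list_p_one(self):
        g = nx.path_graph(10)
        # nodes 0,2,4 induce no edges: nothing can be less connected
        res = connectivity_permutation_p(g, [0, 2, 4], n_perm=99, seed=0)
        assert res.observed == 0
        assert res.p == pytest.approx(1.0)

    def test_all_nodes_p_one(self):
        g = nx.complete_graph(6)
        res = connectivity_permutation_p(g, list(g.nodes), n_perm=49, seed=0)
        assert res.p == pytest.approx(1.0)

    def test_matches_enumeration_on_small_graph(self):
        # 8-cycle, listed genes {0,1,2} (observed 2 internal edges); all nodes
        # share one degree bin, so the null enumerates 3-subsets of {3..7}
        g = nx.cycle_graph(8)
        genes = [0, 1, 2]
        res = connectivity_permutation_p(
            g, genes, n_perm=4000, seed=2, exact_degree=True
        )
        obs = g.subgraph(genes).number_of_edges()
        hits = total = 0
        for sel in itertools.combinations(range(3, 8), 3):
            total += 1
            hits += g.subgraph(sel).number_of_edges() >= obs
        assert (hits, total) == (3, 10)  # hand-checked enumeration
        assert res.p == pytest.approx(hits / total, abs=0.03)

    def test_reproducible_given_seed(self):
        g = nx.gnm_random_graph(30, 60, seed=1)
        a = connectivity_permutation_p(g, list(range(8)), n_perm=200, seed=7)
        b = connectivity_permutation_p(g, list(range(8)), n_perm=200, seed=7)
        assert a.p == b.p

    def test_no_intersection_raises(self):
        with pytest.raises(ValueError):
            connectivity_permutation_p(nx.path_graph(4), ["zz"], n_perm=10)


class TestEvaluateCommunities:
    def test_scores_filled_and_planted_module_significant(self):
        sizes = [20, 20, 20]
        g = nx.stochastic_block_model(sizes, np.where(np.eye(3), 0.8, 0.02).tolist(), seed=9)
        genes = list(range(20)) + [45, 55]
        res, unmatched = evaluate_communities(g, genes, n_perm=199, seed=0)
        assert unmatched == []
        assert set(res.densities) == set(res.communities)
        top = max(res.communities, key=lambda c: len(res.communities[c]))
        assert res.permutation_p[top] <= 0.01
        assert res.densities[top] > 0.5


class TestCommunityEnrichment:
    def _communities(self, members):
        from sibnet.network import CommunityResult

        return CommunityResult(communities={0: set(members)})

    def test_single_set_adjusted_equals_raw(self):
        universe = [f"g{i}" for i in range(12)]
        sets = GeneSetCollection()
        sets.add("S1", universe[:4])
        df = community_enrichment(self._communities(universe[:4]), sets, universe)
        assert df.loc[0, "p_bonferroni"] == pytest.approx(df.loc[0, "p"])

    def test_no_overlap_p_one(self):
        universe = [f"g{i}" for i in range(12)]
        sets = GeneSetCollection()
        sets.add("S1", universe[6:])
        df = community_enrichment(self._communities(universe[:4]), sets, universe)
        assert df.loc[0, "overlap"] == 0
        assert df.loc[0, "p"] == pytest.approx(1.0)

    def test_matches_hypergeometric_oracle_small_universes(self):
        for N in (6, 9, 12):
            universe = [f"g{i}" for i in range(N)]
            sets = GeneSetCollection()
            sets.add("S1", universe[: N // 2])
            sets.add("S2", universe[N // 3:])
            df = community_enrichment(self._communities(universe[: N // 2]), sets, universe)
            for _, row in df.iterrows():
                expected = helpers.hypergeom_upper_tail(
                    N, row["set_size"], row["community_size"], row["overlap"]
                )
                assert row["p"] == pytest.approx(float(expected), abs=1e-12)
                assert row["p_bonferroni"] == pytest.approx(min(1.0, float(expected) * 2))

    def test_set_outside_universe_skipped(self):
        universe = [f"g{i}" for i in range(6)]
        sets = GeneSetCollection()
        sets.add("IN", universe[:3])
        sets.add("OUT", ["zz"] + universe[:2])
        df = community_enrichment(self._communities(universe[:3]), sets, universe)
        assert list(df["gene_set"]) == ["IN"]


class TestJaccardAndCuration:
    def test_jaccard_examples(self):
        assert jaccard({"a", "b"}, {"a", "b"}) == 1.0
        assert jaccard({"a", "b", "c"}, {"b", "c", "d"}) == 0.5
        with pytest.raises(ValueError):
            jaccard(set(), set())

    def test_jaccard_matches_set_arithmetic(self):
        rng = np.random.default_rng(0)
        pool = [f"g{i}" for i in range(30)]
        for _ in range(20):
            a = set(rng.choice(pool, size=rng.integers(1, 15)))
            b = set(rng.choice(pool, size=rng.integers(1, 15)))
            assert jaccard(a, b) == len(a & b) / len(a | b)

    def test_identical_sets_deduplicated(self):
        sets = GeneSetCollection()
        sets.add("A", {"x", "y", "z"})
        sets.add("B", {"x", "y", "z"})
        kept = curate_gene_sets(sets)
        assert kept.names() == ["A"]

    def test_disjoint_sets_all_kept(self):
        sets = GeneSetCollection()
        sets.add("A", {"a1", "a2"})
        sets.add("B", {"b1", "b2"})
        assert sorted(curate_gene_sets(sets).names()) == ["A", "B"]

    def test_greedy_chain(self):
        # J(A,B) > 0.5 drops B; J(A,C) <= 0.5 keeps C
        a = set(range(10))
        b = set(range(2, 10)) | {20, 21}
        c = {0, 1, 20, 21} | set(range(30, 36))
        assert jaccard(a, b) > 0.5 and jaccard(a, c) <= 0.5
        sets = GeneSetCollection()
        for name, members in (("A", a), ("B", b), ("C", c)):
            sets.add(name, members)
        assert sorted(curate_gene_sets(sets).names()) == ["A", "C"]

    def test_output_pairwise_jaccard_bounded(self, small_study):
        kept = curate_gene_sets(small_study.gene_sets, max_jaccard=0.5)
        names = kept.names()
        for i, n1 in enumerate(names):
            for n2 in names[i + 1:]:
                assert jaccard(kept[n1], kept[n2]) <= 0.5


class TestMembershipMatrix:
    def test_packaged_example_tallies(self):
        genes, networks, counts = load_signaling_membership()
        mm = build_membership_matrix(genes, networks, counts, SIGNALING_COHORT_SIZE)
        assert len(mm.genes) == 20
        assert mm.gene_counts()["NGF-PC12"] == 9
        assert mm.patient_sums()["NGF-PC12"] == 50

    def test_empty_network_column(self):
        mm = build_membership_matrix(["g1", "g2"], {"EMPTY": set()}, {"g1": 1, "g2": 2})
        assert mm.gene_counts()["EMPTY"] == 0
        assert mm.patient_sums()["EMPTY"] == 0

    def test_unknown_network_gene_ignored(self, caplog):
        mm = build_membership_matrix(["g1"], {"N": {"g1", "gX"}}, {"g1": 3})
        assert mm.gene_counts()["N"] == 1

    def test_tallies_recomputable_from_matrix(self):
        genes, networks, counts = load_signaling_membership()
        mm = build_membership_matrix(genes, networks, counts, SIGNALING_COHORT_SIZE)
        for net in mm.networks:
            members = mm.membership.index[mm.membership[net]]
            assert mm.gene_counts()[net] == len(members)
            assert mm.patient_sums()[net] == sum(counts[g] for g in members)

    def test_missing_patient_count_raises(self):
        with pytest.raises(ValueError):
            build_membership_matrix(["g1"], {}, {})

    def test_count_exceeding_cohort_raises(self):
        with pytest.raises(ValueError):
            build_membership_matrix(["g1"], {}, {"g1": 200}, total_patients=126)
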