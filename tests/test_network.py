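"""Network construction: components, intermediates, hubs, ambiguity."""

import numpy as np
import pytest

from haplopars.distances import count_steps, distance_matrix
from haplopars.network import (
    build_networks,
    infer_intermediates,
    membership,
    network_stats,
)
from haplopars.parsimony import connection_limit
from tests.conftest import make_table


def single_linkage_components(seqs, j_max):
    """Brute-force oracle: union-find over all pairs within the limit."""
    n = len(seqs)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if count_steps(seqs[i], seqs[j]) <= j_max:
                parent[find(i)] = find(j)
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), set()).add(i)
    return {frozenset(g) for g in groups.values()}


def components_of(networks, codes):
    index = {c: i for i, c in enumerate(codes)}
    return {frozenset(index[c] for c in net.observed) for net in networks}


def random_table(rng, n_max=12, L=40):
    """Random clustered sequences: a few seeds with scattered mutations."""
    bases = "ACGT"
    n_seeds = rng.integers(1, 4)
    seeds = ["".join(rng.choice(list(bases), L)) for _ in range(n_seeds)]
    seqs = set()
    while len(seqs) < rng.integers(2, n_max + 1):
        s = list(seeds[rng.integers(n_seeds)])
        for _ in range(rng.integers(0, 6)):
            i = rng.integers(L)
            s[i] = bases[(bases.index(s[i]) + rng.integers(1, 4)) % 4]
        seqs.add("".join(s))
    return make_table(sorted(seqs))


class TestInferIntermediates:
    def test_adjacent_no_intermediates(self):
        assert infer_intermediates("AAAA", "AAAT") == []

    def test_three_steps_two_intermediates(self):
        mids = infer_intermediates("AAAA", "TTTA")
        assert len(mids) == 2
        chain = ["AAAA"] + mids + ["TTTA"]
        assert all(count_steps(a, b) == 1 for a, b in zip(chain, chain[1:]))

    def test_ascending_site_order(self):
        assert infer_intermediates("AAAA", "TATT") == ["TAAA", "TATA"]

    def test_identical_sequences_error(self):
        with pytest.raises(ValueError):
            infer_intermediates("AAAA", "AAAA")


class TestBuildNetworks:
    def test_single_haplotype_single_network(self):
        nets = build_networks(make_table(["ACGTACGT"]), 5)
        assert len(nets) == 1 and nets[0].is_singleton
        assert nets[0].graph.number_of_edges() == 0

    def test_toy_trio_splits_beyond_limit(self):
        # A-B = 1 step, C is 5 and 6 steps away; limit 3
        A = "AAAAAAAAAA"
        B = "AAAAAAAAAT"
        C = "CCCCCAAAAT"  # 5 from B, 6 from A
        table = make_table([A, B, C])
        nets = build_networks(table, 3)
        comps = components_of(nets, table.codes)
        assert comps == {frozenset({0, 1}), frozenset({2})}

    def test_shared_intermediate_merged(self):
        # B and C both two steps from hub A through the same first site
        A, B, C = "AAAA", "TTAA", "TATA"
        table = make_table([A, B, C])
        nets = build_networks(table, 3)
        assert len(nets) == 1
        g = nets[0].graph
        inferred = [n for n, d in g.nodes(data=True) if d["kind"] == "inferred"]
        assert len(inferred) == 1
        assert g.nodes[inferred[0]]["seq"] == "TAAA"
        assert g.degree(inferred[0]) >= 2

    def test_every_edge_is_one_step(self, sim_default):
        from haplopars.sequence_io import collapse_haplotypes

        table = collapse_haplotypes(sim_default.records)
        nets = build_networks(table, connection_limit(table.L).j_max)
        for net in nets:
            for u, v in net.graph.edges:
                assert count_steps(net.graph.nodes[u]["seq"], net.graph.nodes[v]["seq"]) == 1

    def test_intermediates_never_dangle(self, sim_default):
        from haplopars.sequence_io import collapse_haplotypes

        table = collapse_haplotypes(sim_default.records)
        for net in build_networks(table, connection_limit(table.L).j_max):
            for n, d in net.graph.nodes(data=True):
                if d["kind"] == "inferred":
                    assert net.graph.degree(n) >= 2

    def test_path_length_at_least_step_distance(self):
        import networkx as nx

        rng = np.random.default_rng(7)
        table = random_table(rng)
        nets = build_networks(table, 6)
        seq_of = {h.code: h.seq for h in table}
        for net in nets:
            for i, a in enumerate(net.observed):
                for b in net.observed[i + 1 :]:
                    plen = nx.shortest_path_length(net.graph, a, b)
                    assert plen >= count_steps(seq_of[a], seq_of[b])

    def test_partition_matches_single_linkage_oracle(self):
        rng = np.random.default_rng(11)
        for trial in range(30):
            table = random_table(rng)
            j_max = int(rng.integers(1, 7))
            nets = build_networks(table, j_max)
            assert components_of(nets, table.codes) == single_linkage_components(
                table.seqs, j_max
            ), f"trial {trial}"

    def test_all_haplotypes_covered_once(self):
        rng = np.random.default_rng(3)
        table = random_table(rng)
        nets = build_networks(table, 4)
        seen = [c for net in nets for c in net.observed]
        assert sorted(seen) == sorted(table.codes)

    def test_lower_confidence_never_splits(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            table = random_table(rng)
            for j_lo, j_hi in [(1, 3), (2, 5), (3, 8)]:
                assert len(build_networks(table, j_hi)) <= len(build_networks(table, j_lo))

    def test_deterministic_numbering_by_size(self):
        # two clusters of different sizes: bigger cluster is network 1
        A = "A" * 30
        cluster1 = [A, A[:-1] + "T", A[:-2] + "TT"]
        B = "C" * 15 + "A" * 15
        cluster2 = [B]
        table = make_table(cluster2 + cluster1)  # insertion order scrambled
        nets = build_networks(table, 3)
        assert nets[0].n_observed == 3 and nets[1].n_observed == 1

    def test_empty_limit_zero_all_singletons(self):
        table = make_table(["AAAA", "AAAT", "AATT"])
        assert len(build_networks(table, 0)) == 3

    def test_ambiguous_equal_length_alternatives_flagged(self):
        # two 2-haplotype clusters joined by two alternative 3-step paths
        A1 = "AAAAAAAAAA"
        A2 = "AAAAAAAAAT"  # 1 step from A1
        B1 = "TTTAAAAAAA"  # 3 steps from A1
        B2 = "TTTAAAAAAT"  # 1 step from B1, 3 steps from A2
        table = make_table([A1, A2, B1, B2])
        nets = build_networks(table, 3)
        assert len(nets) == 1
        types = [d["edge_type"] for _, _, d in nets[0].graph.edges(data=True)]
        assert "ambiguous-loop" in types


class TestNetworkStats:
    def test_singleton_stats(self):
        table = make_table(["ACGTACGT"])
        net = build_networks(table, 3)[0]
        s = network_stats(net, table)
        assert s.is_singleton and s.hub == "H001" and s.hub_degree == 0

    def test_star_hub_degree(self, small_star_table):
        nets = build_networks(small_star_table, 5)
        assert len(nets) == 1
        s = network_stats(nets[0], small_star_table)
        assert s.hub == "H001"  # the high-count center
        assert s.hub_degree == 4
        assert s.n_direct == 4 and s.n_one_node_away == 0

    def test_two_step_leaves_counted_one_node_away(self):
        hub = "A" * 20
        one = [hub[:i] + "T" + hub[i + 1 :] for i in (0, 3)]
        two = hub[:6] + "TT" + hub[8:]
        table = make_table([hub] + one + [two], counts=[5, 1, 1, 1])
        s = network_stats(build_networks(table, 4)[0], table)
        assert s.n_direct == 2 and s.n_one_node_away == 1

    def test_membership_map(self, small_star_table):
        nets = build_networks(small_star_table, 5)
        m = membership(nets)
        assert set(m) == set(small_star_table.codes)
        assert set(m.values()) == {1}
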