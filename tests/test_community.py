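"""Community detection, hub classification and fingerprints."""

import numpy as np
import networkx as nx
import pytest

from longiconn.community import (Partition, classify_global_hubs, louvain_consensus,
                                 modular_fingerprints, modularity_q, node_roles,
                                 partition_similarity, rsn_overlap,
                                 select_reference_partition)


def two_cliques(k=4, bridge=False):
    n = 2 * k
    w = np.zeros((n, n))
    for block in (range(k), range(k, n)):
        for i in block:
            for j in block:
                if i != j:
                    w[i, j] = 1.0
    if bridge:
        w[0, k] = w[k, 0] = 1.0
    return w


def partition_from_sets(sets, n):
    a = np.empty(n, dtype=int)
    for m, s in enumerate(sets, start=1):
        for node in s:
            a[node] = m
    return Partition(assignment=a, q=0.0)


class TestModularityQ:
    def test_single_module_zero(self):
        w = two_cliques(3)
        assert modularity_q(w, np.ones(6, dtype=int)) == pytest.approx(0.0)

    def test_two_disconnected_cliques_half(self):
        w = two_cliques(4)
        q = modularity_q(w, np.array([1] * 4 + [2] * 4))
        assert q == pytest.approx(0.5)

    def test_random_assignment_zero_in_expectation(self, rng):
        # the permutation average of Q vanishes up to the O(1/n) bias from
        # same-node terms, so a large-ish graph keeps it near zero
        w = (rng.random((40, 40)) < 0.4).astype(float)
        w = np.triu(w, 1)
        w = w + w.T
        qs = [modularity_q(w, rng.integers(1, 4, size=40)) for _ in range(300)]
        assert abs(np.mean(qs)) < 0.03

    def test_matches_networkx(self, rng):
        w = np.triu((rng.random((10, 10)) < 0.5).astype(float) * rng.random((10, 10)), 1)
        w = w + w.T
        c = rng.integers(1, 4, size=10)
        g = nx.from_numpy_array(w)
        comms = [set(np.flatnonzero(c == m)) for m in (1, 2, 3) if (c == m).any()]
        assert modularity_q(w, c) == pytest.approx(
            nx.community.modularity(g, comms, weight="weight"), abs=1e-12)


class TestLouvainConsensus:
    def test_two_cliques_unambiguous(self):
        part = louvain_consensus(two_cliques(4), n_runs=100, seed=0)
        assert part.mode_frequency == 1.0
        assert part.n_modules == 2
        assert len(set(part.assignment[:4])) == 1
        assert len(set(part.assignment[4:])) == 1
        assert part.q == pytest.approx(0.5)

    def test_same_seed_identical(self, rng):
        w = np.triu(rng.random((12, 12)), 1)
        w = w + w.T
        a = louvain_consensus(w, n_runs=20, seed=5)
        b = louvain_consensus(w, n_runs=20, seed=5)
        np.testing.assert_array_equal(a.assignment, b.assignment)
        assert a.q == b.q

    def test_planted_blocks_recovered_with_exact_q(self, rng):
        blocks = [range(0, 5), range(5, 10), range(10, 15), range(15, 20)]
        w = np.zeros((20, 20))
        for b in blocks:
            for i in b:
                for j in b:
                    if i != j:
                        w[i, j] = 1.0
        # sparse weak inter-block edges
        for _ in range(8):
            i, j = rng.integers(0, 20, 2)
            if i != j and w[i, j] == 0:
                w[i, j] = w[j, i] = 0.05
        part = louvain_consensus(w, n_runs=50, seed=1)
        truth = np.repeat([1, 2, 3, 4], 5)
        if part.n_modules == 4:
            # Q of the returned partition equals brute-force Q of truth
            assert part.q == pytest.approx(modularity_q(w, truth), abs=1e-12)

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            louvain_consensus(np.zeros((4, 4)), n_runs=1, seed=0)


class TestPartitionSimilarity:
    def test_identical_partitions_give_one(self):
        p = partition_from_sets([{0, 1}, {2, 3}], 4)
        assert partition_similarity(p, p) == 1.0
        assert partition_similarity(p, p, symmetrize=True) == 1.0

    def test_split_versus_merged_is_half(self):
        p1 = partition_from_sets([{0, 1}, {2, 3}], 4)
        p2 = partition_from_sets([{0, 1, 2, 3}], 4)
        assert partition_similarity(p1, p2) == pytest.approx(0.5)

    def test_crossed_partitions_one_third(self):
        p1 = partition_from_sets([{0, 1}, {2, 3}], 4)
        p2 = partition_from_sets([{0, 2}, {1, 3}], 4)
        assert partition_similarity(p1, p2) == pytest.approx(1 / 3)

    def test_symmetrized_variant_is_symmetric(self, rng):
        a = Partition(assignment=rng.integers(1, 4, 10), q=0.0)
        b = Partition(assignment=rng.integers(1, 3, 10), q=0.0)
        a.assignment[0] = 1
        b.assignment[0] = 1
        sym_ab = partition_similarity(a, b, symmetrize=True)
        sym_ba = partition_similarity(b, a, symmetrize=True)
        assert sym_ab == pytest.approx(sym_ba)


class TestGlobalHubs:
    def test_all_equal_no_hubs(self):
        df = classify_global_hubs(np.ones(5))
        assert not df.is_hub.any()

    def test_direct_arithmetic_example(self):
        df = classify_global_hubs(np.array([1.0, 1, 1, 1, 2]))
        hubs = df[df.is_hub].node.tolist()
        assert hubs == [5]
        assert df.normalized.iloc[0] == pytest.approx(2 / 1.2)

    def test_hub_and_spoke_center_is_hub(self):
        n = 8
        w = np.zeros((n, n))
        w[0, 1:] = w[1:, 0] = 1.0
        from longiconn.metrics import efficiencies, shortest_path_lengths
        e_nodal = efficiencies(shortest_path_lengths(w))[1]
        df = classify_global_hubs(e_nodal)
        assert df[df.is_hub].node.tolist() == [1]


class TestNodeRoles:
    def test_participation_coefficient_values(self):
        w = two_cliques(4, bridge=False)
        part = partition_from_sets([set(range(4)), set(range(4, 8))], 8)
        roles = node_roles(w, part)
        np.testing.assert_allclose(roles.pc, 0.0)

        # node with 2 edges in-module, 2 in the other module -> PC = 0.5
        w2 = np.zeros((6, 6))
        for i, j in ((0, 1), (0, 2), (0, 4), (0, 5), (1, 2), (4, 5)):
            w2[i, j] = w2[j, i] = 1.0
        part2 = partition_from_sets([{0, 1, 2}, {3, 4, 5}], 6)
        roles2 = node_roles(w2, part2)
        assert roles2.pc.iloc[0] == pytest.approx(0.5)

    def test_high_degree_bridge_is_connector_hub(self):
        # module 1 (nodes 0-6): node 0 is a star centre (within-degree 6),
        # the rest form sparse pairs; module 2 (nodes 7-13) is a clique.
        # node 0 also reaches 3 nodes of module 2, so PC = 0.44 > 0.3.
        n = 14
        w = np.zeros((n, n))
        for j in range(1, 7):
            w[0, j] = w[j, 0] = 1.0
        for i, j in ((1, 2), (3, 4), (5, 6)):
            w[i, j] = w[j, i] = 1.0
        for i in range(7, 14):
            for j in range(i + 1, 14):
                w[i, j] = w[j, i] = 1.0
        for j in (7, 8, 9):
            w[0, j] = w[j, 0] = 1.0
        part = partition_from_sets([set(range(7)), set(range(7, 14))], n)
        roles = node_roles(w, part)
        assert roles.pc.iloc[0] == pytest.approx(1 - (6 / 9) ** 2 - (3 / 9) ** 2)
        assert roles.role.iloc[0] == "connector hub"

    def test_roles_invariant_to_module_relabeling(self, rng):
        w = two_cliques(4, bridge=True)
        p1 = partition_from_sets([set(range(4)), set(range(4, 8))], 8)
        p2 = partition_from_sets([set(range(4, 8)), set(range(4))], 8)
        r1 = node_roles(w, p1)
        r2 = node_roles(w, p2)
        assert (r1.role == r2.role).all()
        np.testing.assert_allclose(r1.z_within, r2.z_within)


class TestRsnOverlap:
    def test_single_module_all_hundred(self, rng):
        part = Partition(assignment=np.ones(6, dtype=int), q=0.0)
        vols = rng.random((6, 3))
        out = rsn_overlap(part, vols)
        np.testing.assert_allclose(out.to_numpy(), 100.0)

    def test_columns_sum_to_hundred(self, rng):
        part = Partition(assignment=rng.integers(1, 4, 10), q=0.0)
        part.assignment[:3] = [1, 2, 3]
        vols = rng.random((10, 7))
        out = rsn_overlap(part, vols)
        np.testing.assert_allclose(out.sum(axis=0), 100.0, atol=1e-9)

    def test_zero_volume_rsn_rejected(self):
        part = Partition(assignment=np.ones(3, dtype=int), q=0.0)
        with pytest.raises(ValueError):
            rsn_overlap(part, np.zeros((3, 2)))


class TestFingerprints:
    def test_disconnected_cliques(self):
        w = two_cliques(4)
        part = partition_from_sets([set(range(4)), set(range(4, 8))], 8)
        with pytest.warns(UserWarning, match="no connector hubs"):
            fp = modular_fingerprints(w, part, connector_hubs=[])
        assert not fp.inter.any()
        np.testing.assert_array_equal(fp.intra, [6, 6])
        assert fp.no_connector_hubs

    def test_bridge_hub_drives_intermodular_entry(self):
        w = two_cliques(4, bridge=True)
        part = partition_from_sets([set(range(4)), set(range(4, 8))], 8)
        fp = modular_fingerprints(w, part, connector_hubs=[1])  # node 1 = bridge end
        assert fp.hub_driven[0, 1] == 1
        assert fp.overall_hub_connectivity == 1

    def test_hub_connectivity_scales_with_hub_edges(self):
        w = two_cliques(4, bridge=True)
        w[1, 5] = w[5, 1] = 1.0      # second inter-module edge from node 1
        part = partition_from_sets([set(range(4)), set(range(4, 8))], 8)
        fp = modular_fingerprints(w, part, connector_hubs=[1, 2])
        assert fp.overall_hub_connectivity == 2


class TestReferenceSelection:
    def test_single_candidate_returned(self, rng):
        w = two_cliques(3)
        cand = partition_from_sets([set(range(3)), set(range(3, 6))], 6)
        assert select_reference_partition([w], [cand]) is cand

    def test_true_partition_beats_random(self, rng):
        mats = [two_cliques(4) + rng.normal(0, 0.01, (8, 8)) for _ in range(4)]
        mats = [np.abs((m + m.T) / 2) for m in mats]
        truth = partition_from_sets([set(range(4)), set(range(4, 8))], 8)
        random_p = Partition(assignment=np.array([1, 2, 1, 2, 1, 2, 1, 2]), q=0.0)
        assert select_reference_partition(mats, [random_p, truth]) is truth

    def test_tie_keeps_first(self):
        w = two_cliques(3)
        a = partition_from_sets([set(range(3)), set(range(3, 6))], 6)
        b = partition_from_sets([set(range(3)), set(range(3, 6))], 6)
        assert select_reference_partition([w], [a, b]) is a
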