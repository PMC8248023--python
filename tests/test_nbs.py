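"""Paired network-based statistics: F statistics, components, permutations."""

import numpy as np
import pandas as pd
import pytest

from longiconn.build import CohortPair
from longiconn.atlas import DEMO_COMPONENT
from longiconn.nbs import (NetworkComponent, component_summaries, edgewise_paired_f,
                           extract_components, nbs_paired, select_primary_threshold,
                           threshold_sweep)


def make_pair(sc_t1, sc_t2, mask=None):
    sc_t1 = np.asarray(sc_t1, dtype=float)
    n = sc_t1.shape[1]
    if mask is None:
        mask = np.ones((n, n), dtype=bool)
        np.fill_diagonal(mask, False)
    return CohortPair(sc_t1=sc_t1, sc_t2=np.asarray(sc_t2, dtype=float),
                      subject_ids=[f"s{i}" for i in range(sc_t1.shape[0])],
                      mask=mask)


def symmetric_stack(rng, n_sub, n):
    w = rng.random((n_sub, n, n))
    w = (w + w.transpose(0, 2, 1)) / 2
    for s in w:
        np.fill_diagonal(s, 0)
    return w


class TestEdgewisePairedF:
    def test_identical_timepoints_give_zero(self, rng):
        sc = symmetric_stack(rng, 4, 5)
        f = edgewise_paired_f(make_pair(sc, sc.copy()))
        assert not f.any()

    def test_closed_form_hand_computation(self, rng):
        sc1 = symmetric_stack(rng, 3, 4)
        sc2 = sc1.copy()
        for s, d in enumerate((0.1, 0.2, 0.3)):
            sc2[s, 0, 1] += d
            sc2[s, 1, 0] += d
        f = edgewise_paired_f(make_pair(sc1, sc2))
        t = 0.2 / (0.1 / np.sqrt(3))
        assert f[0, 1] == pytest.approx(t ** 2)

    def test_constant_nonzero_difference_capped(self, rng):
        sc1 = symmetric_stack(rng, 4, 4)
        sc2 = sc1.copy()
        sc2[:, 0, 1] += 1.0
        sc2[:, 1, 0] += 1.0
        with pytest.warns(UserWarning, match="capped"):
            f = edgewise_paired_f(make_pair(sc1, sc2))
        assert f[0, 1] >= 1e12


class TestExtractComponents:
    def test_threshold_above_max_gives_empty_list(self, rng):
        f = np.abs(symmetric_stack(rng, 1, 5)[0])
        assert extract_components(f, f.max() + 1) == []

    def test_toy_components_sizes_two_and_one(self):
        f = np.zeros((9, 9))
        for i, j in ((0, 1), (1, 2), (6, 7)):
            f[i, j] = f[j, i] = 5.0
        comps = extract_components(f, 1.0)
        assert [c.size for c in comps] == [2, 1]
        assert comps[0].nodes == {1, 2, 3}

    def test_complete_supra_graph_single_component(self):
        f = np.full((5, 5), 9.0)
        np.fill_diagonal(f, 0)
        comps = extract_components(f, 1.0)
        assert len(comps) == 1 and comps[0].size == 10


class TestNbsPaired:
    def test_identity_permutation_bounds_p_value(self, rng):
        # the identity sign pattern is as extreme as the observation, so
        # p_fwer can never be smaller than 1/(n_perm + 1); with an injected
        # strong effect the observed component must be recovered
        sc1 = symmetric_stack(rng, 8, 8)
        sc2 = sc1 + 0.0
        for i, j in ((0, 1), (1, 2)):
            sc2[:, i, j] += rng.normal(0.5, 0.05, size=8)
            sc2[:, j, i] = sc2[:, i, j]
        res = nbs_paired(make_pair(sc1, sc2), primary_threshold=10.0,
                         n_perm=200, seed=0)
        assert res.components
        for c in res.components:
            assert c.p_fwer >= 1 / 201

    def test_reproducible_under_seed(self, small_null_pair):
        a = nbs_paired(small_null_pair, 8.0, n_perm=100, seed=3)
        b = nbs_paired(small_null_pair, 8.0, n_perm=100, seed=3)
        np.testing.assert_array_equal(a.null_max_size, b.null_max_size)

    def test_small_n_perm_rejected(self, small_null_pair):
        with pytest.raises(ValueError):
            nbs_paired(small_null_pair, 8.0, n_perm=50)

    def test_exhaustive_enumeration_matches_monte_carlo(self, rng):
        # n = 6 subjects -> 64 sign patterns; the Monte-Carlo null of the max
        # component size must match full enumeration in distribution
        n_sub, n = 6, 6
        sc1 = symmetric_stack(rng, n_sub, n)
        sc2 = sc1 + rng.normal(0, 0.2, size=sc1.shape)
        sc2 = (sc2 + sc2.transpose(0, 2, 1)) / 2
        for s in sc2:
            np.fill_diagonal(s, 0)
        pair = make_pair(sc1, sc2)
        thr = 6.0

        iu, ju = np.triu_indices(n, 1)
        d = (pair.sc_t2 - pair.sc_t1)[:, iu, ju]
        exact = []
        for bits in range(2 ** n_sub):
            signs = np.array([1.0 if bits >> k & 1 else -1.0 for k in range(n_sub)])
            ds = d * signs[:, None]
            m, v = ds.mean(axis=0), ds.var(axis=0, ddof=1)
            f = np.where(v > 0, n_sub * m ** 2 / v, 0.0)
            supra = f > thr
            if not supra.any():
                exact.append(0)
                continue
            fm = np.zeros((n, n))
            fm[iu[supra], ju[supra]] = 9.9
            fm += fm.T
            comps = extract_components(fm, 1.0)
            exact.append(comps[0].size)
        mc = nbs_paired(pair, thr, n_perm=4000, seed=1).null_max_size
        # compare distributions via all integer cut points
        for k in range(0, max(exact) + 1):
            p_exact = np.mean(np.array(exact) >= k)
            p_mc = np.mean(mc >= k)
            assert abs(p_exact - p_mc) < 0.05


class TestThresholdSweep:
    def test_census_monotone_and_tail_empty(self, small_null_pair):
        f = edgewise_paired_f(small_null_pair)
        grid = list(np.linspace(0.5, f.max() + 1, 12))
        sweep = threshold_sweep(small_null_pair, grid)
        assert (np.diff(sweep.largest_size) <= 0).all()
        assert sweep.largest_size.iloc[-1] == 0

    def test_unsorted_thresholds_rejected(self, small_null_pair):
        with pytest.raises(ValueError):
            threshold_sweep(small_null_pair, [3.0, 1.0])

    def test_selection_rule(self):
        sweep = pd.DataFrame({"threshold": [1.0, 2.0, 3.0, 4.0],
                              "n_components": [2, 1, 1, 0],
                              "largest_size": [6, 5, 2, 0],
                              "n_nodes_involved": [8, 6, 3, 0]})
        assert select_primary_threshold(sweep) == 2.0
        assert select_primary_threshold(sweep[sweep.threshold > 2.5]) is None


class TestComponentSummaries:
    def test_single_edge_halving_gives_minus_50(self):
        sc1 = np.full((5, 4, 4), 0.0)
        sc2 = sc1.copy()
        sc1[:, 0, 1] = sc1[:, 1, 0] = 0.2
        sc2[:, 0, 1] = sc2[:, 1, 0] = 0.1
        comp = NetworkComponent(edges=[(1, 2, -0.1)])
        _, changes = component_summaries(make_pair(sc1, sc2), comp)
        row = changes[(changes.network == "all") & (changes.stratum == "all")]
        assert row.percent_change.iloc[0] == pytest.approx(-50.0)

    def test_demo_component_stratum_census(self, rng):
        # the 16-edge demo template: increases 2 intra-left / 0 intra-right /
        # 5 inter; decreases 3 / 5 / 1
        sc = symmetric_stack(rng, 3, 90) + 0.1
        comp = NetworkComponent(edges=list(DEMO_COMPONENT))
        _, changes = component_summaries(make_pair(sc, sc + 0.01), comp)
        census = changes.set_index(["network", "stratum"]).n_edges
        assert census[("increases", "intra-left")] == 2
        assert census[("increases", "intra-right")] == 0
        assert census[("increases", "inter-hemispheric")] == 5
        assert census[("decreases", "intra-left")] == 3
        assert census[("decreases", "intra-right")] == 5
        assert census[("decreases", "inter-hemispheric")] == 1
        row = changes[(changes.network == "increases")
                      & (changes.stratum == "intra-right")]
        assert bool(row["empty"].iloc[0])
        assert np.isnan(row.percent_change.iloc[0])

    def test_stratum_means_match_brute_force(self, rng):
        sc1 = symmetric_stack(rng, 4, 6) + 0.05
        sc2 = symmetric_stack(rng, 4, 6) + 0.05
        edges = [(1, 2, 0.3), (2, 3, -0.2)]
        pair = make_pair(sc1, sc2)
        per_subject, _ = component_summaries(pair, NetworkComponent(edges=edges))
        sel = per_subject[(per_subject.network == "all")
                          & (per_subject.stratum == "all")]
        expected = sc1[:, [0, 1], [1, 2]].mean(axis=1)
        np.testing.assert_allclose(sel.mean_t1.to_numpy(), expected)
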