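import itertools
import math

import numpy as np
import pandas as pd
import pytest

from rhizonet import cooccurrence_networks as nets
from rhizonet.study_io import OtuTable


def enumeration_tails(N, N1, N2, j_obs):
    """Brute-force oracle: distribution of the joint-occurrence count over all
    C(N,N1) x C(N,N2) incidence placements."""
    sites = range(N)
    counts = {}
    for a in itertools.combinations(sites, N1):
        sa = set(a)
        for b in itertools.combinations(sites, N2):
            j = len(sa.intersection(b))
            counts[j] = counts.get(j, 0) + 1
    total = sum(counts.values())
    p_lt = sum(v for j, v in counts.items() if j <= j_obs) / total
    p_gt = sum(v for j, v in counts.items() if j >= j_obs) / total
    return p_lt, p_gt


def _incidence(matrix, otus=None):
    matrix = np.asarray(matrix)
    otus = otus or [f"o{i}" for i in range(matrix.shape[1])]
    return pd.DataFrame(matrix, index=[f"s{i}" for i in range(matrix.shape[0])],
                        columns=otus)


class TestVeechPairTest:
    def test_small_example(self):
        p_lt, p_gt, ej = nets.veech_pair_test(4, 2, 2, 2)
        assert p_gt == pytest.approx(1 / 6, abs=1e-12)
        assert p_lt == pytest.approx(1.0, abs=1e-12)
        assert ej == pytest.approx(1.0)

    def test_ubiquitous_otu_degenerate(self):
        p_lt, p_gt, _ = nets.veech_pair_test(10, 10, 4, 4)
        assert p_lt == 1.0 and p_gt == 1.0

    def test_balanced_extreme_tail(self):
        _, p_gt, _ = nets.veech_pair_test(20, 10, 10, 10)
        assert p_gt == pytest.approx(1 / math.comb(20, 10), rel=1e-9)

    def test_out_of_support_rejected(self):
        with pytest.raises(ValueError, match="support"):
            nets.veech_pair_test(10, 3, 3, 4)

    @pytest.mark.parametrize("N", [2, 4, 6])
    def test_matches_enumeration(self, N):
        for N1 in range(N + 1):
            for N2 in range(N + 1):
                lo, hi = max(0, N1 + N2 - N), min(N1, N2)
                for j in range(lo, hi + 1):
                    p_lt, p_gt, _ = nets.veech_pair_test(N, N1, N2, j)
                    e_lt, e_gt = enumeration_tails(N, N1, N2, j)
                    assert p_lt == pytest.approx(e_lt, abs=1e-12)
                    assert p_gt == pytest.approx(e_gt, abs=1e-12)

    def test_tail_identity(self, rng):
        from scipy.stats import hypergeom

        for _ in range(100):
            N = int(rng.integers(2, 60))
            N1 = int(rng.integers(0, N + 1))
            N2 = int(rng.integers(0, N + 1))
            lo, hi = max(0, N1 + N2 - N), min(N1, N2)
            j = int(rng.integers(lo, hi + 1))
            p_lt, p_gt, _ = nets.veech_pair_test(N, N1, N2, j)
            pmf = hypergeom.pmf(j, N, N1, N2)
            assert p_lt + p_gt - pmf == pytest.approx(1.0, abs=1e-12)


class TestIncidenceAndFilter:
    def test_incidence(self):
        table = OtuTable(["a", "b"], ["s1", "s2"], np.array([[0, 3], [5, 0]]),
                         ["", ""], "16S")
        inc = nets.incidence_matrix(table)
        np.testing.assert_array_equal(inc.to_numpy(), [[0, 1], [1, 0]])

    def test_column_sums_are_prevalence(self, rng):
        counts = rng.integers(0, 3, size=(10, 6))
        table = OtuTable([f"o{i}" for i in range(6)], [f"s{i}" for i in range(10)],
                         counts, [""] * 6, "16S")
        inc = nets.incidence_matrix(table)
        np.testing.assert_array_equal(inc.sum(axis=0).to_numpy(),
                                      (counts > 0).sum(axis=0))

    def test_prevalence_threshold(self):
        m = np.zeros((10, 2), dtype=int)
        m[:3, 0] = 1  # 3/10 -> kept at 0.30
        m[:2, 1] = 1  # 2/10 -> dropped
        kept = nets.filter_otus(_incidence(m), 0.30)
        assert kept == ["o0"]

    def test_max_otus_cap(self, rng):
        m = (rng.random((20, 50)) < 0.8).astype(int)
        kept = nets.filter_otus(_incidence(m), 0.05, max_otus=10)
        assert len(kept) == 10

    def test_max_pairs_lowers_cap(self, rng):
        m = np.ones((10, 30), dtype=int)
        kept = nets.filter_otus(_incidence(m), 0.5, max_otus=30, max_pairs=45)
        assert len(kept) * (len(kept) - 1) // 2 <= 45

    def test_threshold_monotonicity(self, tiny_study):
        _, tits, _, _ = tiny_study
        inc = nets.incidence_matrix(tits)
        low = set(nets.filter_otus(inc, 0.10))
        high = set(nets.filter_otus(inc, 0.30))
        assert high <= low

    def test_empty_survivors(self):
        m = np.zeros((10, 3), dtype=int)
        m[0, :] = 1
        with pytest.raises(ValueError, match="threshold"):
            nets.filter_otus(_incidence(m), 0.5)


class TestBuildMetacommunity:
    def test_identical_vectors_cooccur(self):
        col = np.zeros(10, dtype=int)
        col[:5] = 1
        inc = _incidence(np.column_stack([col, col]))
        net = nets.build_metacommunity(inc, ["o0", "o1"], alpha=0.05)
        assert len(net.cooccurrence_edges) == 1
        assert net.cooccurrence_edges[0].p_gt == pytest.approx(1 / 252, rel=1e-9)

    def test_mutually_exclusive_coexclude(self):
        a = np.zeros(10, dtype=int)
        a[:5] = 1
        inc = _incidence(np.column_stack([a, 1 - a]))
        net = nets.build_metacommunity(inc, ["o0", "o1"], alpha=0.05)
        assert len(net.coexclusion_edges) == 1
        assert net.coexclusion_edges[0].p_lt == pytest.approx(1 / 252, rel=1e-9)

    def test_alpha_zero_empty(self, rng):
        inc = _incidence((rng.random((20, 8)) < 0.5).astype(int))
        net = nets.build_metacommunity(inc, list(inc.columns), alpha=0.0)
        assert not net.cooccurrence_edges and not net.coexclusion_edges

    def test_edge_sets_disjoint_and_within_nodes(self, default_networks_props):
        networks, _ = default_networks_props
        for net in networks.values():
            cooc = {frozenset((p.otu_a, p.otu_b)) for p in net.cooccurrence_edges}
            coex = {frozenset((p.otu_a, p.otu_b)) for p in net.coexclusion_edges}
            assert not cooc & coex
            node_set = set(net.nodes)
            for pair in net.cooccurrence_edges + net.coexclusion_edges:
                assert {pair.otu_a, pair.otu_b} <= node_set

    def test_null_calibration(self):
        # independent OTUs: rejection rate matches the exact attainable rate
        rng = np.random.default_rng(42)
        N, n_pairs = 100, 200
        prev = rng.uniform(0.2, 0.8, size=2 * n_pairs)
        inc = (rng.random((N, 2 * n_pairs)) < prev).astype(int)
        from scipy.stats import hypergeom

        rejected, expected_rate = 0, 0.0
        for k in range(n_pairs):
            a, b = inc[:, 2 * k], inc[:, 2 * k + 1]
            N1, N2, j = int(a.sum()), int(b.sum()), int((a & b).sum())
            p_lt, p_gt, ej = nets.veech_pair_test(N, N1, N2, j)
            rejected += (p_gt < 0.05) and (j > ej)
            # exact null probability of rejection given margins
            support = np.arange(max(0, N1 + N2 - N), min(N1, N2) + 1)
            pmf = hypergeom.pmf(support, N, N1, N2)
            sf = hypergeom.sf(support - 1, N, N1, N2)
            mask = (sf < 0.05) & (support > N1 * N2 / N)
            expected_rate += float(pmf[mask].sum())
        expected_rate /= n_pairs
        rate = rejected / n_pairs
        se = np.sqrt(max(expected_rate * (1 - expected_rate), 1e-4) / n_pairs)
        assert expected_rate <= 0.05
        assert abs(rate - expected_rate) <= 3 * se

    def test_planted_recovery(self):
        # paired OTUs share a latent factor: strength 0.9 when on, 0.2 off
        rng = np.random.default_rng(7)
        N, n_pairs = 100, 200
        inc = np.zeros((N, 2 * n_pairs), dtype=int)
        for k in range(n_pairs):
            active = rng.random(N) < 0.5
            prob = np.where(active, 0.9, 0.2)
            inc[:, 2 * k] = rng.random(N) < prob
            inc[:, 2 * k + 1] = rng.random(N) < prob
        detected = 0
        for k in range(n_pairs):
            a, b = inc[:, 2 * k], inc[:, 2 * k + 1]
            p_lt, p_gt, ej = nets.veech_pair_test(
                N, int(a.sum()), int(b.sum()), int((a & b).sum())
            )
            detected += (p_gt < 0.05) and ((a & b).sum() > ej)
        assert detected / n_pairs >= 0.90


class TestLocalProperties:
    def _net(self, nodes, cooc=(), coex=()):
        def pair(a, b, cls):
            return nets.PairTest(a, b, N=10, N1=5, N2=5, j_obs=4, expected_j=2.5,
                                 p_lt=1.0, p_gt=0.01, classification=cls)

        return nets.MetacommunityNetwork(
            nodes=list(nodes),
            cooccurrence_edges=[pair(a, b, "cooccurrence") for a, b in cooc],
            coexclusion_edges=[pair(a, b, "coexclusion") for a, b in coex],
        )

    def test_triangle(self):
        net = self._net("abcd", cooc=[("a", "b"), ("b", "c"), ("a", "c")])
        props = nets.local_properties(net, {"a", "b", "c", "d"}, S=4)
        assert props.cooccurrence_transitivity == 1.0
        assert props.cooccurrence_proportion == pytest.approx(0.5)

    def test_path_no_triangles(self):
        net = self._net("abc", cooc=[("a", "b"), ("b", "c")])
        props = nets.local_properties(net, {"a", "b", "c"}, S=3)
        assert props.cooccurrence_transitivity == 0.0

    def test_two_disjoint_triangles_modularity(self):
        net = self._net(
            "abcdef",
            cooc=[("a", "b"), ("b", "c"), ("a", "c"),
                  ("d", "e"), ("e", "f"), ("d", "f")],
        )
        props = nets.local_properties(net, set("abcdef"), S=6)
        # Q = 2 * (3/6 - (6/12)^2) with the component partition
        assert props.cooccurrence_modularity == pytest.approx(0.5, abs=1e-10)

    def test_degenerate_single_otu(self):
        net = self._net("ab", cooc=[("a", "b")])
        props = nets.local_properties(net, {"a"}, S=1)
        assert props.cooccurrence_proportion == 0.0
        assert props.cooccurrence_modularity == 0.0
        assert props.cooccurrence_transitivity == 0.0

    def test_full_presence_equals_metacommunity(self, default_networks_props):
        networks, _ = default_networks_props
        net = networks["ITS"]
        full = nets.local_properties(net, set(net.nodes), S=len(net.nodes))
        import igraph as ig

        g = ig.Graph(
            n=len(net.nodes),
            edges=[
                (net.nodes.index(p.otu_a), net.nodes.index(p.otu_b))
                for p in net.cooccurrence_edges
            ],
        )
        assert full.cooccurrence_transitivity == pytest.approx(
            g.transitivity_undirected(mode="zero"), abs=1e-12
        )

    def test_subgraph_monotonicity(self):
        net = self._net("abcd", cooc=[("a", "b"), ("b", "c"), ("c", "d")])
        full = nets.local_properties(net, set("abcd"), S=4)
        reduced = nets.local_properties(net, set("abd"), S=3)
        n_full = full.cooccurrence_proportion * 6
        n_red = reduced.cooccurrence_proportion * 3
        assert n_red <= n_full

    def test_properties_in_range(self, default_networks_props):
        _, props = default_networks_props
        for tag in ("bac", "fun"):
            for etype in ("cooccurrence", "coexclusion"):
                assert props[f"{tag}_{etype}_proportion"].between(0, 1).all()
                assert props[f"{tag}_{etype}_transitivity"].between(0, 1).all()
                assert props[f"{tag}_{etype}_modularity"].between(-0.5, 1).all()


class TestPlantedStructure:
    def test_planted_pairs_recovered_in_default_study(
        self, default_study, default_networks_props
    ):
        _, _, _, truth = default_study
        networks, _ = default_networks_props
        net = networks["ITS"]
        cooc = {frozenset((p.otu_a, p.otu_b)) for p in net.cooccurrence_edges}
        planted = [frozenset(p) for p in truth.planted_cooccurrence_pairs["ITS"]]
        assert sum(p in cooc for p in planted) / len(planted) >= 0.90
        # co-exclusion recovery is weaker: the shared block-quality signal adds
        # positive correlation that partially offsets the anti-association
        coex = {frozenset((p.otu_a, p.otu_b)) for p in net.coexclusion_edges}
        planted_x = [frozenset(p) for p in truth.planted_coexclusion_pairs["ITS"]]
        assert sum(p in coex for p in planted_x) / len(planted_x) >= 0.75

    def test_local_edges_subset_of_metacommunity(self, default_networks_props):
        networks, _ = default_networks_props
        net = networks["ITS"]
        all_edges = {frozenset((p.otu_a, p.otu_b)) for p in net.cooccurrence_edges}
        some_nodes = set(net.nodes[: len(net.nodes) // 2])
        local = [
            frozenset((p.otu_a, p.otu_b))
            for p in net.cooccurrence_edges
            if p.otu_a in some_nodes and p.otu_b in some_nodes
        ]
        assert set(local) <= all_edges
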