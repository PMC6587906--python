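import numpy as np
import pytest
from scipy import stats

from tfnetprop import (
    PropagationConfig,
    build_transition_matrix,
    coverage,
    extract_mtfnet,
    rwr,
    score_selection,
    select_major_tfs,
    simulate,
)
from tfnetprop.model import TFNetworkModel, time_point_seed
from tfnetprop.synthetic import SimulationSpec

from conftest import make_time_network, random_time_network


class TestTransitionMatrix:
    def test_out_degree_normalization(self):
        tn = make_time_network({("A", "B"): 1.0, ("A", "C"): 1.0}, {"A"}, {}, set())
        W = build_transition_matrix(tn).toarray()
        a = tn.node_index("A")
        col = W[:, a]
        assert sorted(col) == [0.0, 0.5, 0.5]
        assert W.sum(axis=0)[a] == pytest.approx(1.0)

    def test_negative_weights_clamped(self):
        tn = make_time_network({("A", "B"): 1.0, ("A", "C"): -0.5}, {"A"}, {}, set())
        W = build_transition_matrix(tn).toarray()
        assert W[tn.node_index("B"), tn.node_index("A")] == pytest.approx(1.0)
        assert W[tn.node_index("C"), tn.node_index("A")] == 0.0

    def test_dangling_column_is_zero(self):
        tn = make_time_network({("A", "B"): 1.0}, {"A"}, {}, set())
        W = build_transition_matrix(tn).toarray()
        assert np.all(W[:, tn.node_index("B")] == 0.0)

    def test_empty_graph(self):
        tn = make_time_network({}, set(), {}, set())
        assert build_transition_matrix(tn).shape == (0, 0)


class TestRwr:
    def test_alpha_one_returns_seed(self):
        tn = make_time_network({("A", "B"): 1.0}, {"A"}, {}, set())
        W = build_transition_matrix(tn)
        p0 = np.array([2.0, 0.0])
        p = rwr(W, p0, PropagationConfig(alpha=1.0))
        assert np.allclose(p, [1.0, 0.0])

    def test_isolated_seed_keeps_mass(self):
        tn = make_time_network({("A", "B"): 1.0}, {"A"}, {"C": 1.0}, set())
        W = build_transition_matrix(tn)
        p0 = np.zeros(tn.n_nodes)
        p0[tn.node_index("C")] = 1.0
        p = rwr(W, p0, PropagationConfig(alpha=0.4))
        # no mass ever reaches other nodes; the dangling column leaks the
        # walk portion, so the seed retains exactly the restart mass
        assert p[tn.node_index("C")] == pytest.approx(0.4)
        mask = np.ones(tn.n_nodes, bool)
        mask[tn.node_index("C")] = False
        assert np.all(p[mask] == 0.0)

    def test_chain_matches_linear_solve(self):
        """Oracle: direct inversion of the fixed-point equation."""
        tn = make_time_network({("A", "B"): 1.0, ("B", "C"): 1.0}, {"A", "B"}, {}, set())
        cfg = PropagationConfig(alpha=0.3)
        W = build_transition_matrix(tn)
        p0 = np.zeros(3)
        p0[tn.node_index("A")] = 1.0
        p = rwr(W, p0, cfg)
        closed = 0.3 * np.linalg.solve(np.eye(3) - 0.7 * W.toarray(), p0)
        assert np.abs(p - closed).sum() < 10 * cfg.tol

    @pytest.mark.parametrize("alpha", [0.1, 0.5, 0.9])
    def test_random_graphs_match_closed_form(self, alpha, rng):
        for _ in range(5):
            tn = random_time_network(rng, n_tf=5, n_tg=20, n_edges=40)
            cfg = PropagationConfig(alpha=alpha)
            W = build_transition_matrix(tn, cfg)
            p0 = rng.random(tn.n_nodes)
            p = rwr(W, p0, cfg)
            n = tn.n_nodes
            closed = alpha * np.linalg.solve(
                np.eye(n) - (1 - alpha) * W.toarray(), p0 / p0.sum()
            )
            assert np.abs(p - closed).sum() < 10 * cfg.tol

    def test_mass_bounded_and_nonnegative(self, rng):
        tn = random_time_network(rng, n_tf=4, n_tg=10, n_edges=25)
        W = build_transition_matrix(tn)
        p = rwr(W, rng.random(tn.n_nodes), PropagationConfig(alpha=0.2))
        assert np.all(p >= 0)
        assert p.sum() <= 1.0 + 1e-9

    def test_mass_conserved_without_dangling(self):
        # A -> B -> A cycle: every node has out-weight
        tn = make_time_network({("A", "B"): 1.0, ("B", "A"): 1.0}, {"A", "B"}, {}, set())
        W = build_transition_matrix(tn)
        p = rwr(W, np.array([1.0, 0.0]), PropagationConfig(alpha=0.3))
        assert p.sum() == pytest.approx(1.0, abs=1e-8)

    def test_rejects_bad_seed(self):
        tn = make_time_network({("A", "B"): 1.0}, {"A"}, {}, set())
        W = build_transition_matrix(tn)
        with pytest.raises(ValueError):
            rwr(W, np.array([0.0, 0.0]))
        with pytest.raises(ValueError):
            rwr(W, np.array([-1.0, 2.0]))


class TestScoreSelection:
    def test_identical_ordering(self):
        tn = make_time_network({}, set(), {"a": 1.0, "b": 2.0, "c": 3.0}, set())
        ip = [tn.node_de[v] * 10 for v in tn.nodes]
        assert score_selection(ip, tn) == pytest.approx(1.0)

    def test_reversed_ordering(self):
        tn = make_time_network({}, set(), {"a": 1.0, "b": 2.0, "c": 3.0}, set())
        ip = [-tn.node_de[v] for v in tn.nodes]
        assert score_selection(ip, tn) == pytest.approx(-1.0)

    def test_ties_use_average_ranks(self):
        """Oracle: rank both vectors (average ranks) then Pearson."""
        tn = make_time_network(
            {}, set(), {"a": 1.0, "b": 2.0, "c": 2.0, "d": 3.0, "e": 5.0}, set()
        )
        ip = np.array([0.1, 0.4, 0.2, 0.2, 0.9])
        de = tn.de_array()
        expected = np.corrcoef(stats.rankdata(ip), stats.rankdata(de))[0, 1]
        assert score_selection(ip, tn) == pytest.approx(expected, abs=1e-12)

    def test_constant_vector_returns_zero(self):
        tn = make_time_network({}, set(), {"a": 1.0, "b": 2.0}, set())
        assert score_selection([3.0, 3.0], tn) == 0.0


class TestCoverage:
    def test_empty_set(self):
        tn = make_time_network({("A", "B"): 1.0}, {"A"}, {}, {"B"})
        assert coverage(set(), tn) == 0

    def test_direct_targets(self):
        tn = make_time_network({("A", "B"): 1.0, ("A", "C"): 1.0}, {"A"}, {}, {"B", "C"})
        assert coverage({"A"}, tn) == 2

    def test_overlapping_targets_counted_once(self):
        tn = make_time_network(
            {("A", "B"): 1.0, ("X", "B"): 1.0}, {"A", "X"}, {}, {"B"}
        )
        assert coverage({"A", "X"}, tn) == 1

    def test_reachable_mode_follows_paths(self):
        tn = make_time_network(
            {("A", "X"): 1.0, ("X", "B"): 1.0}, {"A", "X"}, {}, {"B"}
        )
        assert coverage({"A"}, tn, mode="direct") == 0
        assert coverage({"A"}, tn, mode="reachable") == 1


class TestSelectMajorTfs:
    def test_immediate_stop_when_coverage_exceeds_half(self):
        tn = make_time_network({("A", "B"): 1.0}, {"A"}, {"A": 1.0, "B": 1.0}, {"B"})
        sel = select_major_tfs(tn, ["A"])
        assert sel.accepted == ["A"]
        assert sel.coverage_trace == [1]

    def test_scc_lowering_candidate_rejected(self):
        """Oracle: exhaustive evaluation of both candidate seed sets."""
        tn = make_time_network(
            {("A", "g1"): 1.0, ("A", "g2"): 1.0, ("A", "g3"): 1.0, ("B", "h1"): 1.0},
            {"A", "B"},
            {"A": 2.0, "B": 1.0, "g1": 3.0, "g2": 3.0, "g3": 3.0, "h1": 0.1,
             "x1": 2.0, "x2": 2.0, "x3": 2.0, "x4": 2.0},
            {"g1", "g2", "g3", "h1", "x1", "x2", "x3", "x4"},
        )
        cfg = PropagationConfig()
        W = build_transition_matrix(tn, cfg)

        def scc_of(seed):
            p0 = np.zeros(tn.n_nodes)
            for t in seed:
                p0[tn.node_index(t)] = tn.node_de[t]
            return score_selection(rwr(W, p0, cfg), tn)

        s_a, s_ab = scc_of(["A"]), scc_of(["A", "B"])
        assert s_ab < s_a  # fixture sanity: B genuinely hurts
        sel = select_major_tfs(tn, ["A", "B"], cfg)
        assert sel.accepted == ["A"]
        rec = sel.scc_trace[1]
        assert rec.candidate == "B" and not rec.accepted
        assert rec.scc_after == pytest.approx(s_ab, abs=1e-9)

    def test_empty_ranking(self):
        tn = make_time_network({("A", "B"): 1.0}, {"A"}, {}, {"B"})
        sel = select_major_tfs(tn, [])
        assert sel.accepted == [] and sel.mtfnet == {}

    def test_empty_deg_set_keeps_first_and_flags(self):
        tn = make_time_network({("A", "B"): 1.0}, {"A"}, {"A": 1.0, "B": 1.0}, set())
        sel = select_major_tfs(tn, ["A"])
        assert sel.accepted == ["A"]
        assert "empty_deg_set" in sel.flags
        assert sel.coverage_trace == [0]

    def test_first_seed_kept_even_with_nonpositive_scc(self):
        # single node pair with anti-ordered DE: SCC <= 0 but A stays
        tn = make_time_network(
            {("A", "b"): 1.0, ("A", "c"): 1.0},
            {"A"},
            {"A": 5.0, "b": 0.1, "c": 0.2, "z1": 3.0, "z2": 3.0, "z3": 3.0},
            {"b", "c", "z1", "z2", "z3"},
        )
        sel = select_major_tfs(tn, ["A"])
        assert sel.accepted == ["A"]

    def test_deterministic(self, rng):
        tn = random_time_network(rng, n_tf=5, n_tg=15, n_edges=30)
        ranking = sorted(tn.tf_set)
        a = select_major_tfs(tn, ranking)
        b = select_major_tfs(tn, ranking)
        assert a.accepted == b.accepted
        assert a.scc_trace == b.scc_trace
        assert a.ip == b.ip

    def test_accepted_scc_strictly_increasing_on_synthetic(self):
        ds = simulate(SimulationSpec(rng_seed=5, n_tf=12, n_tg=80, n_active=2))
        res = TFNetworkModel(ds.template, ds.deg).fit(rounds=200, seed=5)
        for sel in res.selections:
            accepted = [r for r in sel.scc_trace if r.accepted]
            vals = [r.scc_after for r in accepted]
            assert all(b > a for a, b in zip(vals, vals[1:]))
            for r in sel.scc_trace:
                if not r.accepted:
                    assert r.scc_after <= r.scc_before


class TestExtractMtfnet:
    def test_only_deg_targets_kept(self):
        tn = make_time_network(
            {("A", "B"): 1.0, ("A", "X"): 1.0}, {"A"}, {}, {"B"}
        )
        assert extract_mtfnet(["A"], tn) == {("A", "B"): 1.0}

    def test_multi_layer_path_retained(self):
        tn = make_time_network(
            {("A", "B"): 1.0, ("B", "C"): 1.0}, {"A", "B"}, {}, {"C"}
        )
        assert extract_mtfnet(["A", "B"], tn) == {("A", "B"): 1.0, ("B", "C"): 1.0}

    def test_unselected_tf_does_not_relay(self):
        # B is a TF outside S and not a DEG: it neither relays the path to C
        # nor belongs in the result, so nothing is explained
        tn = make_time_network(
            {("A", "B"): 1.0, ("B", "C"): 1.0}, {"A", "B"}, {}, {"C"}
        )
        assert extract_mtfnet(["A"], tn) == {}

    def test_empty_selection(self):
        tn = make_time_network({("A", "B"): 1.0}, {"A"}, {}, {"B"})
        assert extract_mtfnet([], tn) == {}

    def test_non_tf_nodes_are_all_degs(self, rng):
        tn = random_time_network(rng, n_tf=4, n_tg=10, n_edges=25)
        net = extract_mtfnet(sorted(tn.tf_set)[:2], tn)
        for (u, v) in net:
            assert v in tn.tf_set or v in tn.deg_set
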