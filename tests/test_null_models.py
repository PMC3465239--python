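import math

import networkx as nx
import numpy as np
import pytest

from spokenet import (
    AnnealSchedule,
    anneal_to_triangle_count,
    assortativity,
    count_triangles,
    joint_degree_seed,
    metropolis_accept,
    overlapping_null,
    rewire_degree_preserving,
)
from spokenet.null_models import joint_degree_dict
from spokenet.synthetic_data import synth_metabolic_like, synth_modular

from _oracles import joint_degree_tally_brute


class TestRewiring:
    def test_degree_sequence_preserved(self, modular_graph):
        h = rewire_degree_preserving(modular_graph, 5000, seed=1)
        assert dict(h.degree()) == dict(modular_graph.degree())
        assert h.number_of_edges() == modular_graph.number_of_edges()

    def test_rigid_triangle_unchanged(self, caplog):
        g = nx.relabel_nodes(nx.complete_graph(3), str)
        with caplog.at_level("WARNING"):
            h = rewire_degree_preserving(g, 10, seed=0)
        assert {frozenset(e) for e in h.edges} == {frozenset(e) for e in g.edges}

    def test_randomizes_structure(self, modular_graph):
        h = rewire_degree_preserving(modular_graph, 10 * modular_graph.number_of_edges(), seed=2)
        shared = sum(1 for e in modular_graph.edges if h.has_edge(*e))
        assert shared / modular_graph.number_of_edges() < 0.5

    def test_superhub_null_keeps_large_k_ck_shape(self):
        # a degree-preserving null of a super-hub graph keeps its declining
        # large-k clustering: the hubs alone force C ~ 1/k at the top end
        from spokenet import ck_spectrum

        g, hubs = synth_metabolic_like(n=3000, superhub_degrees=(600, 600), seed=5)
        h = rewire_degree_preserving(g, 10 * g.number_of_edges(), seed=6)
        real = ck_spectrum(g).entries
        null = ck_spectrum(h).entries
        k_hubs = [g.degree(v) for v in hubs]
        for k in k_hubs:
            assert null[k][0] == pytest.approx(real[k][0], rel=0.5)


class TestJointDegreeSeed:
    def test_forced_two_regular(self):
        g = nx.relabel_nodes(nx.cycle_graph(4), str)
        h = joint_degree_seed(g, seed=1)
        assert sorted(d for _, d in h.degree()) == [2, 2, 2, 2]
        assert h.number_of_edges() == 4

    def test_joint_matrix_exact(self, modular_graph):
        h = joint_degree_seed(modular_graph, seed=3)
        assert joint_degree_dict(h) == joint_degree_dict(modular_graph)
        assert h.number_of_nodes() == modular_graph.number_of_nodes()

    def test_unordered_tally_matches_brute_force(self, modular_graph):
        h = joint_degree_seed(modular_graph, seed=4)
        assert joint_degree_tally_brute(h) == joint_degree_tally_brute(modular_graph)

    def test_assortativity_reproduced_across_seeds(self):
        # r is a function of the joint degree matrix, so every seed network
        # reproduces it to floating-point accuracy
        g = synth_modular(n_modules=3, module_size=40, p_in=0.2, p_out=0.02, seed=9)
        r_real = assortativity(g)
        for seed in range(20):
            assert assortativity(joint_degree_seed(g, seed)) == pytest.approx(r_real, abs=1e-9)


class TestMetropolis:
    def test_downhill_always_accepted(self):
        rng = np.random.default_rng(0)
        assert all(metropolis_accept(-0.1, 0.01, rng) for _ in range(100))
        assert all(metropolis_accept(0.0, 0.01, rng) for _ in range(100))

    @pytest.mark.parametrize("delta_e,temp", [(0.1, 0.05), (0.02, 0.05), (0.05, 0.1)])
    def test_uphill_frequency_matches_boltzmann(self, delta_e, temp):
        rng = np.random.default_rng(1234)
        n = 20_000
        freq = sum(metropolis_accept(delta_e, temp, rng) for _ in range(n)) / n
        expected = math.exp(-delta_e / temp)
        assert freq == pytest.approx(expected, abs=4 * math.sqrt(expected * (1 - expected) / n))


class TestAnnealing:
    def test_greedy_energy_never_increases(self, modular_graph):
        # in the T -> 0 limit only non-worsening moves are accepted
        schedule = AnnealSchedule(temperature=1e-9, cooling=1.0, max_steps=20_000,
                                  tolerance=0.0, window=1_000_000)
        state = anneal_to_triangle_count(modular_graph, schedule, seed=7)
        energies = [e for _, e in state.trajectory]
        assert all(b <= a + 1e-12 for a, b in zip(energies, energies[1:]))

    def test_joint_matrix_preserved_and_tolerance_reached(self, modular_graph):
        schedule = AnnealSchedule(tolerance=0.1, max_steps=1_500_000)
        state = anneal_to_triangle_count(modular_graph, schedule, seed=8)
        assert state.energy <= 0.1
        assert joint_degree_dict(state.graph) == joint_degree_dict(modular_graph)
        assert abs(state.n_triangles - state.n_target) / state.n_target == pytest.approx(state.energy)

    def test_triangle_free_reference_rejected(self):
        g = nx.relabel_nodes(nx.cycle_graph(6), str)
        with pytest.raises(ValueError, match="no triangles"):
            anneal_to_triangle_count(g, seed=0)

    def test_hot_chain_stays_near_ensemble_mean(self):
        # detailed-balance smoke test: at very high T every proposal is
        # accepted, so a long chain should wander around the triangle level
        # of independent joint-degree-preserving draws, far below the
        # modular target
        g = synth_modular(n_modules=3, module_size=30, p_in=0.25, p_out=0.03, seed=1)
        ens = [count_triangles(joint_degree_seed(g, s)) for s in range(12)]
        schedule = AnnealSchedule(temperature=50.0, cooling=1.0, max_steps=60_000,
                                  tolerance=0.0, window=1_000_000)
        state = anneal_to_triangle_count(g, schedule, seed=3)
        assert state.n_triangles < state.n_target
        assert min(ens) * 0.5 <= state.n_triangles <= max(ens) * 1.5


class TestOverlappingNull:
    def test_full_overlap_is_identity(self, modular_graph):
        h, realized = overlapping_null(modular_graph, 1.0, 1000, seed=0)
        assert realized == 1.0
        assert {frozenset(e) for e in h.edges} == {frozenset(e) for e in modular_graph.edges}

    def test_realized_overlap_at_least_requested(self, modular_graph):
        h, realized = overlapping_null(modular_graph, 0.3, 10 * modular_graph.number_of_edges(), seed=1)
        assert realized >= 0.3
        assert dict(h.degree()) == dict(modular_graph.degree())

    def test_invalid_fraction_rejected(self, modular_graph):
        with pytest.raises(ValueError):
            overlapping_null(modular_graph, 0.0, 10, seed=0)

    def test_flattens_ck_variation_of_disassortative_graph(self):
        # stringent nulls of a hub-repelled graph lose most of the C(k) decline
        from spokenet import ck_spectrum
        from spokenet.analytics import fit_loglog_slope
        from spokenet.synthetic_data import synth_disassortative

        g = synth_disassortative(n=1500, gamma=2.4, target_r=-0.25, seed=2)
        h, _ = overlapping_null(g, 0.3, 10 * g.number_of_edges(), seed=3)

        def slope(graph):
            pts = [(k, c, n) for k, (c, n) in ck_spectrum(graph).entries.items()]
            return fit_loglog_slope(pts, min_count=2).slope

        # randomizing 70% of edges moves the slope toward 0
        assert abs(slope(h)) < abs(slope(g))
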