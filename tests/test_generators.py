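"""Planted-motif generation and the microcanonical null randomizers."""

import itertools

import numpy as np
import pytest

from mdlmotifs.census import enumerate_graphlets
from mdlmotifs.codes import base_entropy, model_complexity
from mdlmotifs.contraction import ReductionState
from mdlmotifs.generators import (
    PlantedSpec,
    connectome_like,
    plant_motifs,
    planted_motif_benchmark,
    randomize,
)
from mdlmotifs.graphs import (
    DirectedGraph,
    Graphlet,
    Multigraph,
    canonical_form,
    clique_graphlet,
)

from conftest import random_digraph

K5 = clique_graphlet(5)
TRI = Graphlet.from_edges(3, [(0, 1), (1, 2), (2, 0)])


class TestPlantMotifs:
    def test_node_and_edge_counts_are_exact(self, rng):
        spec = PlantedSpec(n_latent=40, e_latent=60, placements=((TRI, 3), (K5, 2)))
        pg = plant_motifs(spec, rng)
        assert pg.graph.n == 40 + 3 * 2 + 2 * 4
        assert pg.graph.n_edges == 60 + 3 * 3 + 2 * 20

    def test_ground_truth_subsets_are_disjoint_and_isomorphic(self, rng):
        pg = planted_motif_benchmark(K5, copies=10, rng=rng)
        seen = set()
        for gl, members, bits in pg.ground_truth:
            assert not seen & set(members)
            seen |= set(members)
            cbits, _ = canonical_form(gl.n, pg.graph.induced_bits(members))
            assert cbits == gl.bits
            # the recorded orientation is the actual induced pattern
            assert pg.graph.induced_bits(members) == bits

    def test_round_trip_reproduces_the_latent_multigraph(self, rng):
        """Contracting the ground truth recovers H with the latent phi and
        the same two-part codelength."""
        pg = planted_motif_benchmark(K5, copies=8, rng=rng, n_total=200)
        state = ReductionState(pg.graph, "ER", 9576)
        for gl, members, _ in pg.ground_truth:
            state.contract(members, gl)
        h, relabel = state.to_multigraph()
        node_of = {}
        members_to_super = {s.members: s.node for s in state.supernodes.values()}
        for v, expanded in pg.expansion.items():
            if len(expanded) == 1:
                node_of[v] = relabel[expanded[0]]
            else:
                node_of[v] = relabel[members_to_super[tuple(sorted(expanded))]]
        lat = pg.latent
        assert h.n == lat.n
        for (i, j), m in lat.items():
            assert h.mult(node_of[i], node_of[j]) == m
        assert h.n_edges == lat.n_edges
        for fam in ("ER", "RER"):
            got = base_entropy(h, fam) + model_complexity(h, fam)
            want = base_entropy(lat, fam) + model_complexity(lat, fam)
            assert got == pytest.approx(want, abs=1e-9)

    def test_orientations_are_sampled_uniformly(self, rng):
        # 3-cycle has two distinguishable orientations; both must appear
        seen = set()
        for seed in range(40):
            spec = PlantedSpec(n_latent=6, e_latent=3, placements=((TRI, 1),))
            pg = plant_motifs(spec, np.random.default_rng(seed))
            seen.add(pg.ground_truth[0][2])
            if len(seen) == 2:
                break
        assert len(seen) == 2

    def test_infeasible_spec_rejected(self):
        with pytest.raises(ValueError):
            PlantedSpec(n_latent=3, e_latent=1, placements=((K5, 4),))

    def test_saturated_latent_graph_raises(self, rng):
        # more latent edges than any feasible wiring can carry
        spec = PlantedSpec(n_latent=2, e_latent=5, placements=())
        with pytest.raises(RuntimeError):
            plant_motifs(spec, rng, max_retries=5)


class TestRandomize:
    @pytest.mark.parametrize("family", ["ER", "CM", "RER", "RCM"])
    def test_constrained_features_preserved_exactly(self, family, rng):
        g = random_digraph(30, 0.12, rng)
        h0 = Multigraph.from_simple(g)
        r = randomize(g, family, rng)
        hr = Multigraph.from_simple(r)
        assert r.n == g.n
        assert r.n_edges == g.n_edges
        if family == "CM":
            assert hr.out_degrees() == h0.out_degrees()
            assert hr.in_degrees() == h0.in_degrees()
        if family in ("RER", "RCM"):
            assert hr.reciprocity_stats() == h0.reciprocity_stats()
        if family == "RCM":
            assert hr.reciprocal_degrees() == h0.reciprocal_degrees()

    @pytest.mark.parametrize("family", ["CM", "RCM"])
    def test_swaps_actually_move_the_graph(self, family, rng):
        g = random_digraph(30, 0.12, rng)
        r = randomize(g, family, rng)
        assert set(r.edges) != set(g.edges)

    def test_cm_swaps_stay_in_the_degree_ensemble(self, rng):
        """On the 3-cycle, degree-preserving swaps can only produce the two
        simple digraphs with all in- and out-degrees equal to one."""
        cycle = DirectedGraph(3, [(0, 1), (1, 2), (2, 0)])
        ensemble = set()
        pairs = [(i, j) for i in range(3) for j in range(3) if i != j]
        for combo in itertools.combinations(pairs, 3):
            g = DirectedGraph(3, combo)
            h = Multigraph.from_simple(g)
            if h.out_degrees() == [1, 1, 1] and h.in_degrees() == [1, 1, 1]:
                ensemble.add(frozenset(g.edges))
        assert len(ensemble) == 2
        for seed in range(10):
            r = randomize(cycle, "CM", np.random.default_rng(seed))
            assert frozenset(r.edges) in ensemble

    def test_swap_chain_visits_the_ensemble_roughly_uniformly(self):
        """Smoke test: on a tiny graph the CM chain's visit frequencies over
        the brute-force ensemble are uniform within Monte-Carlo error."""
        g = DirectedGraph(4, [(0, 1), (1, 0), (2, 3), (3, 2), (0, 2), (1, 3)])
        h0 = Multigraph.from_simple(g)
        pairs = [(i, j) for i in range(4) for j in range(4) if i != j]
        ensemble = set()
        for combo in itertools.combinations(pairs, g.n_edges):
            cand = DirectedGraph(4, combo)
            hc = Multigraph.from_simple(cand)
            if (
                hc.out_degrees() == h0.out_degrees()
                and hc.in_degrees() == h0.in_degrees()
            ):
                ensemble.add(frozenset(cand.edges))
        counts = {e: 0 for e in ensemble}
        n_samples = 600
        for seed in range(n_samples):
            r = randomize(g, "CM", np.random.default_rng(seed), n_swaps=400)
            counts[frozenset(r.edges)] += 1
        assert all(v > 0 for v in counts.values())
        expected = n_samples / len(ensemble)
        assert max(counts.values()) < 3 * expected

    def test_pathological_graph_returned_with_warning(self, caplog):
        # a single edge admits no swap at all
        g = DirectedGraph(2, [(0, 1)])
        r = randomize(g, "CM", np.random.default_rng(0))
        assert set(r.edges) == set(g.edges)


class TestConnectomeLike:
    def test_hits_requested_size_with_substantial_reciprocity(self, rng):
        g = connectome_like(100, 1500, rng, reciprocity=0.35)
        assert (g.n, g.n_edges) == (100, 1500)
        em = g.reciprocal_edge_count()
        assert 0.2 < 2 * em / g.n_edges < 0.6

    def test_degrees_are_heavy_tailed(self, rng):
        g = connectome_like(150, 2000, rng, degree_sigma=1.0)
        h = Multigraph.from_simple(g)
        kout = np.array(h.out_degrees())
        assert kout.max() > 3 * kout.mean()
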