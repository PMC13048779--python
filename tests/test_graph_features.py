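"""Feature battery checks: hand examples, degenerate graphs, and oracle
equivalence against brute-force implementations on small random graphs."""

import numpy as np
import pytest

import oracles
from conftest import make_edagraph, random_edagraph
from edagraph.graph_features import (
    GRAPH_FEATURE_NAMES,
    MANIFEST,
    edagraph_feature_vector,
    edge_level_features,
    graph_level_features,
    manifest_json,
    node_level_features,
    spectrum_stats,
    wl_signature,
)


class TestManifest:
    def test_66_unique_names_in_three_categories(self):
        assert len(GRAPH_FEATURE_NAMES) == 66
        assert len(set(GRAPH_FEATURE_NAMES)) == 66
        cats = {s.category for s in MANIFEST}
        assert cats == {"graph", "node", "edge"}

    def test_json_export_round_trips(self):
        import json

        entries = json.loads(manifest_json())
        assert [e["name"] for e in entries] == list(GRAPH_FEATURE_NAMES)


class TestHandExamples:
    def test_triangle(self, k3):
        f = graph_level_features(k3)
        assert f["total_triangle_number"] == 1
        assert f["transitivity"] == 1.0
        assert f["diameter"] == pytest.approx(1.0)
        assert f["radius"] == pytest.approx(1.0)

    def test_path3(self, p3):
        f = graph_level_features(p3)
        assert f["transitivity"] == 0.0
        assert f["diameter"] == pytest.approx(2.0)
        assert f["radius"] == pytest.approx(1.0)

    def test_k2_energy_closed_form(self):
        w = 7.5
        g = make_edagraph([(0, 1, w)])
        f = graph_level_features(g)
        assert f["graph_energy"] == pytest.approx(2 * w)
        assert f["graph_spectrum_max"] == pytest.approx(w)
        assert f["graph_spectrum_min"] == pytest.approx(-w)

    def test_star_centralities(self, star4):
        f = node_level_features(star4)
        assert f["degree_centrality_max"] == pytest.approx(1.0)
        assert f["betweenness_centrality_max"] == pytest.approx(1.0)

    def test_cycle_eigenvector_uniform(self, c4):
        f = node_level_features(c4)
        assert f["eigenvector_centrality_max"] == pytest.approx(
            f["eigenvector_centrality_min"], abs=1e-9)
        assert f["total_eigenvector_centrality"] == pytest.approx(2.0)  # 4 * 1/2

    def test_k2_flow_betweenness_trivial(self):
        g = make_edagraph([(0, 1, 2.0)])
        f = edge_level_features(g)
        # no interior node exists in a 2-node network, so node throughflow is 0
        assert f["flow_centrality_max"] == pytest.approx(0.0)
        assert f["flow_centrality_min"] == pytest.approx(0.0)

    def test_regular_graph_assortativity_sentinel(self, c4):
        f = edge_level_features(c4)
        assert f["degree_assortativity"] == 0.0

    def test_p4_assortativity_matches_brute_force(self):
        g = make_edagraph([(0, 1, 1.0), (1, 2, 1.0), (2, 3, 1.0)])
        f = edge_level_features(g)
        assert f["degree_assortativity"] == pytest.approx(
            oracles.degree_assortativity(g.A), abs=1e-9)


class TestSpectrumStats:
    def test_adjacency_mean_zero(self, k3):
        s = spectrum_stats(k3.A, "adj")
        assert s["adj_mean"] == pytest.approx(0.0, abs=1e-12)

    def test_laplacian_connected_single_zero_eig(self, star4):
        lam = np.linalg.eigvalsh(star4.L)
        assert np.sum(np.abs(lam) < 1e-9) == 1

    def test_single_node_all_zero(self, single_node):
        s = spectrum_stats(single_node.A, "adj")
        assert all(v == 0.0 for v in s.values())


class TestWlSignature:
    def test_vertex_transitive_cycle(self, c4):
        assert wl_signature(c4) == pytest.approx(0.25)

    def test_star(self, star4):
        assert wl_signature(star4) == pytest.approx(0.5)

    def test_single_node(self, single_node):
        assert wl_signature(single_node) == 1.0


class TestFullVector:
    def test_names_match_manifest_in_order(self, k3):
        vec = edagraph_feature_vector(k3)
        assert tuple(vec) == GRAPH_FEATURE_NAMES

    def test_isomorphic_graphs_same_vector(self):
        edges = [(0, 1, 2.0), (1, 2, 4.0), (0, 3, 8.0)]
        relabeled = [(3, 2, 2.0), (2, 1, 4.0), (3, 0, 8.0)]
        v1 = edagraph_feature_vector(make_edagraph(edges))
        v2 = edagraph_feature_vector(make_edagraph(relabeled))
        for name in GRAPH_FEATURE_NAMES:
            assert v1[name] == pytest.approx(v2[name], abs=1e-9), name

    def test_single_node_graph_full_sentinel_vector(self, single_node):
        vec = edagraph_feature_vector(single_node)
        assert tuple(vec) == GRAPH_FEATURE_NAMES
        assert vec["n_nodes"] == 1.0
        assert vec["wl_signature"] == 1.0
        assert all(np.isfinite(v) for v in vec.values())

    def test_pure_function_bit_identical(self):
        g = random_edagraph(42)
        v1 = edagraph_feature_vector(g)
        v2 = edagraph_feature_vector(g)
        assert v1 == v2

    def test_adding_edge_monotonicity(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            g = random_edagraph(int(rng.integers(1000)))
            A = g.A
            n = A.shape[0]
            free = [(i, j) for i in range(n) for j in range(i + 1, n) if A[i, j] == 0]
            if not free:
                continue
            i, j = free[int(rng.integers(len(free)))]
            edges = [(u, v, d["weight"]) for u, v, d in g.graph.edges(data=True)]
            g2 = make_edagraph(edges + [(i, j, 2.0)], n_nodes=n)
            f1, f2 = graph_level_features(g), graph_level_features(g2)
            assert f2["total_triangle_number"] >= f1["total_triangle_number"]
            assert f2["n_edges"] == f1["n_edges"] + 1


@pytest.mark.parametrize("seed", range(40))
class TestOracleEquivalence:
    """Brute-force agreement on random graphs of at most 8 nodes."""

    TOL = 1e-8

    def test_all_metrics(self, seed):
        g = random_edagraph(seed)
        A = g.A
        lengths = np.zeros_like(A)
        mask = A > 0
        lengths[mask] = 1.0 / A[mask]
        vec = edagraph_feature_vector(g)

        # counting metrics
        assert vec["total_triangle_number"] == oracles.triangle_count(A)
        assert vec["transitivity"] == pytest.approx(oracles.transitivity(A), abs=self.TOL)
        if g.n_nodes > 0:
            assert vec["maximal_clique_count"] == oracles.maximal_clique_count(A)
        assert vec["n_components"] == len(oracles.components(A))

        # spectra via an independent solver route
        adj_spec = oracles.spectrum(A)
        assert vec["graph_energy"] == pytest.approx(
            float(np.sum(np.abs(adj_spec))), abs=1e-6)
        assert vec["graph_spectrum_max"] == pytest.approx(adj_spec[-1], abs=1e-6)
        lap_spec = oracles.spectrum(np.diag(A.sum(1)) - A)
        assert vec["laplacian_spectrum_max"] == pytest.approx(lap_spec[-1], abs=1e-6)

        # centralities
        dc = oracles.degree_centrality(A)
        assert vec["degree_centrality_max"] == pytest.approx(dc.max(), abs=self.TOL)
        assert vec["degree_centrality_median"] == pytest.approx(
            float(np.median(dc)), abs=self.TOL)
        cc = oracles.closeness_centrality(A, lengths)
        assert vec["closeness_centrality_max"] == pytest.approx(cc.max(), abs=self.TOL)
        bc = oracles.betweenness_centrality(A, lengths)
        assert vec["betweenness_centrality_max"] == pytest.approx(bc.max(), abs=self.TOL)
        assert vec["betweenness_centrality_median"] == pytest.approx(
            float(np.median(bc)), abs=self.TOL)
        hc = oracles.harmonic_centrality(A, lengths)
        assert vec["harmonic_centrality_max"] == pytest.approx(hc.max(), abs=self.TOL)

        # eigenvector centrality on the largest component via power iteration
        comps = oracles.components(A)
        lcc = sorted(max(comps, key=lambda c: (len(c), -min(c))))
        if len(lcc) > 1:
            sub = A[np.ix_(lcc, lcc)]
            if sub.sum() > 0:
                ec = oracles.eigenvector_centrality(sub)
                assert vec["eigenvector_centrality_max"] == pytest.approx(
                    ec.max(), abs=1e-6)
            # electrical flow metrics
            cfb = oracles.current_flow_betweenness(sub)
            assert vec["flow_centrality_max"] == pytest.approx(cfb.max(), abs=1e-6)
            assert vec["total_log_flow_centrality"] == pytest.approx(
                float(np.sum(np.log1p(cfb))), abs=1e-6)
            cfc = oracles.current_flow_closeness(sub)
            assert vec["flow_closeness_max"] == pytest.approx(cfc.max(), abs=1e-6)

        # assortativity
        r = oracles.degree_assortativity(A)
        expected = 0.0 if not np.isfinite(r) else r
        assert vec["degree_assortativity"] == pytest.approx(expected, abs=1e-6)
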