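"""Comorbidity network, eigen-embeddings and co-occurrence baselines."""

from collections import Counter

import networkx as nx
import numpy as np
import pytest
import scipy.stats

from dxembed import (
    GeneMap,
    RecordCorpus,
    build_bipartite_graph,
    build_comorbidity_network,
    cooccurrence_neighbors,
    disease_gene_cooccurrence_predictor,
    modularity_embedding,
    most_frequent_gene_predictor,
    spectral_embedding,
)


def random_corpus(rng, n_records=40, pool=12, max_len=6):
    toks = [f"d{i}" for i in range(pool)]
    return RecordCorpus([
        tuple(rng.choice(toks, size=rng.integers(2, max_len)))
        for _ in range(n_records)
    ])


class TestComorbidityNetwork:
    def test_perfectly_correlated_pair_is_kept(self):
        corpus = RecordCorpus([("A", "B"), ("A", "B"), ("C",), ("C",)])
        net = build_comorbidity_network(corpus)
        assert net.graph.has_edge("A", "B")
        assert net.graph["A"]["B"]["r"] == pytest.approx(1.0)

    def test_independent_pair_is_rejected(self):
        # incidence A=(1,1,0,0), B=(1,0,1,0): r = 0
        corpus = RecordCorpus([("A", "B"), ("A",), ("B",), ("X",)])
        net = build_comorbidity_network(corpus)
        assert not net.graph.has_edge("A", "B")

    def test_r_and_t_match_textbook_recomputation(self):
        rng = np.random.default_rng(21)
        n_d, n_r = 20, 120
        X = (rng.random((n_d, n_r)) < rng.uniform(0.2, 0.8, size=(n_d, 1)))
        corpus = RecordCorpus([
            tuple(f"d{i:02d}" for i in range(n_d) if X[i, j]) or ("filler",)
            for j in range(n_r)
        ])
        net = build_comorbidity_network(corpus, alpha=0.05)
        diseases = sorted({t for rec in corpus for t in rec})
        inc = {d: np.array([1.0 if d in set(rec) else 0.0 for rec in corpus])
               for d in diseases}
        n = len(corpus)
        checked = 0
        for a_i, a in enumerate(diseases):
            for b in diseases[a_i + 1:]:
                va, vb = inc[a], inc[b]
                if va.std() == 0 or vb.std() == 0:
                    continue
                r, p = scipy.stats.pearsonr(va, vb)
                t = r * np.sqrt((n - 2) / (1 - r * r))
                if net.graph.has_edge(a, b):
                    assert net.graph[a][b]["r"] == pytest.approx(r, abs=1e-10)
                    assert net.graph[a][b]["t"] == pytest.approx(t, abs=1e-8)
                    assert p < 0.05
                    checked += 1
                else:
                    assert p >= 0.05 * (1 - 1e-12)
        assert checked > 0

    def test_edge_set_shrinks_as_alpha_decreases(self):
        corpus = random_corpus(np.random.default_rng(22), n_records=60)
        edges = {}
        for alpha in (0.2, 0.05, 0.001):
            net = build_comorbidity_network(corpus, alpha=alpha)
            edges[alpha] = set(map(frozenset, net.graph.edges()))
        assert edges[0.001] <= edges[0.05] <= edges[0.2]

    def test_ubiquitous_disease_keeps_node_drops_edges(self):
        corpus = RecordCorpus([("U", "A"), ("U", "B"), ("U", "A", "B")])
        with pytest.warns(UserWarning, match="all or no records"):
            net = build_comorbidity_network(corpus)
        assert "U" in net.graph
        assert net.graph.degree("U") == 0

    def test_neighbor_ranking_by_edge_weight(self):
        corpus = RecordCorpus([("A", "B"), ("A", "B"), ("A", "C"), ("D",)] * 2)
        net = build_comorbidity_network(corpus, alpha=0.5)
        nbrs = [t for t, _ in net.neighbors("A", K=2)]
        assert nbrs[0] == "B"

    def test_too_few_records_is_an_error(self):
        with pytest.raises(ValueError):
            build_comorbidity_network(RecordCorpus([("A",), ("B",)]))


class TestBipartiteGraph:
    def test_single_record_construction(self):
        G = build_bipartite_graph(RecordCorpus([("A", "B")]), GeneMap({"A": {"g"}}))
        assert G["A"]["B"]["weight"] == 1.0
        assert G["A"]["g"]["weight"] == 1.0
        assert G.nodes["g"]["kind"] == "gene"

    def test_disjoint_components_stay_disjoint(self):
        G = build_bipartite_graph(
            RecordCorpus([("A", "B"), ("C", "D")]),
            GeneMap({"A": {"g1"}, "C": {"g2"}}),
        )
        comps = [sorted(c) for c in nx.connected_components(G)]
        assert sorted(comps) == [["A", "B", "g1"], ["C", "D", "g2"]]

    def test_weights_match_brute_force_pair_counting(self):
        rng = np.random.default_rng(23)
        corpus = random_corpus(rng)
        gm = GeneMap({f"d{i}": {f"g{int(g)}" for g in rng.integers(0, 6, size=3)}
                      for i in range(0, 12, 3)})
        G = build_bipartite_graph(corpus, gm)
        brute = Counter()
        for rec in corpus:
            uniq = sorted(set(rec))
            for i in range(len(uniq)):
                for j in range(i + 1, len(uniq)):
                    brute[(uniq[i], uniq[j])] += 1
        for (a, b), w in brute.items():
            assert G[a][b]["weight"] == float(w)
        # gene-gene weight = number of shared host diseases
        genes = sorted(gm.all_genes)
        for i in range(len(genes)):
            for j in range(i + 1, len(genes)):
                shared = sum(1 for d in gm.diseases
                             if {genes[i], genes[j]} <= gm.genes(d))
                if shared:
                    assert G[genes[i]][genes[j]]["weight"] == float(shared)


def eigen_residual(graph, emb, matrix):
    """Max residual ||M x - (x'Mx) x|| over returned unit eigen-directions."""
    nodes = sorted(graph.nodes)
    V = np.array([emb[n] for n in nodes])
    worst = 0.0
    for j in range(V.shape[1]):
        x = V[:, j]
        nrm = np.linalg.norm(x)
        if nrm < 1e-12:
            continue
        x = x / nrm
        lam = x @ matrix @ x
        worst = max(worst, float(np.linalg.norm(matrix @ x - lam * x)))
    return worst


class TestSpectralEmbedding:
    def test_bridged_cliques_separate(self):
        G = nx.Graph()
        for base, nodes in (("a", "abcd"), ("e", "efgh")):
            for x in nodes:
                for y in nodes:
                    if x < y:
                        G.add_edge(x, y, weight=1.0)
        G.add_edge("a", "e", weight=0.1)
        emb = spectral_embedding(G, d=1)
        left = [emb[x][0] for x in "abcd"]
        right = [emb[x][0] for x in "efgh"]
        assert (max(left) < min(right)) or (max(right) < min(left))

    def test_eigen_residual_below_tolerance(self):
        G = nx.erdos_renyi_graph(15, 0.4, seed=3)
        G = nx.relabel_nodes(G, {i: f"n{i:02d}" for i in G.nodes})
        for _u, _v, d in G.edges(data=True):
            d["weight"] = 1.0
        emb = spectral_embedding(G, d=4)
        comp = max(nx.connected_components(G), key=len)
        sub = G.subgraph(sorted(comp))
        L = nx.normalized_laplacian_matrix(
            sub, nodelist=sorted(comp), weight="weight").toarray()
        sub_emb = {n: emb[n] for n in sorted(comp)}
        assert eigen_residual(sub, sub_emb, (L + L.T) / 2) <= 1e-8

    def test_path_graph_fiedler_vector_orders_endpoints(self):
        G = nx.path_graph(3)
        G = nx.relabel_nodes(G, {0: "a", 1: "b", 2: "c"})
        for _u, _v, d in G.edges(data=True):
            d["weight"] = 1.0
        emb = spectral_embedding(G, d=1)
        assert emb["a"][0] * emb["c"][0] < 0
        assert abs(emb["b"][0]) < max(abs(emb["a"][0]), abs(emb["c"][0]))

    def test_sign_convention_is_deterministic(self):
        G = nx.cycle_graph(6)
        G = nx.relabel_nodes(G, {i: f"n{i}" for i in G.nodes})
        e1 = spectral_embedding(G, d=2)
        e2 = spectral_embedding(G, d=2)
        for n in G.nodes:
            assert np.array_equal(e1[n], e2[n])

    def test_d_at_least_node_count_is_an_error(self):
        G = nx.path_graph(3)
        with pytest.raises(ValueError):
            spectral_embedding(G, d=3)


class TestModularityEmbedding:
    def test_planted_blocks_separated_by_leading_eigenvector_sign(self):
        rng = np.random.default_rng(24)
        G = nx.Graph()
        blocks = [[f"a{i}" for i in range(8)], [f"b{i}" for i in range(8)]]
        for block in blocks:
            for i, x in enumerate(block):
                for y in block[i + 1:]:
                    if rng.random() < 0.9:
                        G.add_edge(x, y, weight=1.0)
        for x in blocks[0]:
            for y in blocks[1]:
                if rng.random() < 0.05:
                    G.add_edge(x, y, weight=1.0)
        emb = modularity_embedding(G, d=1)
        signs_a = {np.sign(emb[x][0]) for x in blocks[0] if x in emb}
        signs_b = {np.sign(emb[x][0]) for x in blocks[1] if x in emb}
        assert len(signs_a) == 1 and len(signs_b) == 1 and signs_a != signs_b

    def test_modularity_matrix_rows_sum_to_zero_and_residual(self):
        G = nx.erdos_renyi_graph(12, 0.5, seed=5)
        G = nx.relabel_nodes(G, {i: f"n{i:02d}" for i in G.nodes})
        for _u, _v, d in G.edges(data=True):
            d["weight"] = 1.0
        comp = sorted(max(nx.connected_components(G), key=len))
        A = nx.to_numpy_array(G.subgraph(comp), nodelist=comp)
        k = A.sum(axis=1)
        B = A - np.outer(k, k) / k.sum()
        assert np.abs(B.sum(axis=1)).max() < 1e-12
        emb = modularity_embedding(G, d=3)
        assert eigen_residual(G.subgraph(comp), {n: emb[n] for n in comp}, B) <= 1e-8


class TestCooccurrenceNeighbors:
    def test_counting_example(self):
        corpus = RecordCorpus([("A", "B"), ("A", "B"), ("A", "C")])
        assert cooccurrence_neighbors(corpus, "A", K=2) == [("B", 2), ("C", 1)]

    def test_isolated_query_warns_and_returns_empty(self):
        corpus = RecordCorpus([("A",), ("B", "C")])
        with pytest.warns(UserWarning, match="never co-occurs"):
            assert cooccurrence_neighbors(corpus, "A", K=3) == []

    def test_unknown_query_is_an_error(self):
        with pytest.raises(KeyError):
            cooccurrence_neighbors(RecordCorpus([("A",)]), "Z", K=1)

    def test_matches_brute_force_pair_counting(self):
        rng = np.random.default_rng(25)
        corpus = random_corpus(rng)
        query = "d0"
        brute = Counter()
        for rec in corpus:
            s = set(rec)
            if query in s:
                for t in s - {query}:
                    brute[t] += 1
        got = dict(cooccurrence_neighbors(corpus, query, K=100))
        assert got == dict(brute)


class TestGenePredictors:
    def test_most_frequent_ranking_and_truncation(self):
        gm = GeneMap({"D1": {"g1", "g2"}, "D2": {"g1"}})
        assert most_frequent_gene_predictor(gm, K=2) == ["g1", "g2"]
        assert most_frequent_gene_predictor(gm, K=1) == ["g1"]

    def test_most_frequent_ties_break_lexicographically(self):
        gm = GeneMap({"D1": {"gb", "ga"}})
        assert most_frequent_gene_predictor(gm, K=2) == ["ga", "gb"]

    def test_most_frequent_empty_map_is_an_error(self):
        with pytest.raises(ValueError):
            most_frequent_gene_predictor(GeneMap(), K=1)

    def test_cooccurrence_predictor_construction(self):
        corpus = RecordCorpus([("Q", "D1"), ("Q", "D1"), ("D2", "X")])
        gm = GeneMap({"D1": {"g1"}, "D2": {"g2"}})
        assert disease_gene_cooccurrence_predictor(corpus, gm, "Q", K=3) == ["g1"]

    def test_cooccurrence_predictor_matches_record_scan(self):
        rng = np.random.default_rng(26)
        corpus = random_corpus(rng)
        gm = GeneMap({f"d{i}": {f"g{int(x)}" for x in rng.integers(0, 8, size=2)}
                      for i in range(0, 12, 2)})
        query = "d1"
        brute = Counter()
        for rec in corpus:
            if query in rec:
                for t in rec:
                    if t != query:
                        for g in gm.genes(t):
                            brute[g] += 1
        expected = [g for g, _ in sorted(brute.items(), key=lambda x: (-x[1], x[0]))]
        got = disease_gene_cooccurrence_predictor(corpus, gm, query, K=len(brute))
        assert got == expected

    def test_gene_free_neighborhood_warns_and_returns_empty(self):
        corpus = RecordCorpus([("Q", "X"), ("Y", "Z")])
        with pytest.warns(UserWarning, match="never co-occurs"):
            out = disease_gene_cooccurrence_predictor(
                corpus, GeneMap({"Y": {"g"}}), "Q", K=2)
        assert out == []
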