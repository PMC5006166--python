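"""Comparison methods: comorbidity networks, eigen-embeddings, co-occurrence.

The comorbidity network follows the classical phenotypic-network
construction: diseases are linked when the Pearson correlation of their
binary per-record incidence vectors (the phi coefficient) passes a
t-statistic significance test. Spectral (normalized-Laplacian) and
modularity-matrix eigen-embeddings provide matrix-factorization baselines on
either the comorbidity graph or the disease-gene adjacency graph, and raw
co-occurrence ranking plus two trivial gene predictors complete the set.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass

import networkx as nx
import numpy as np
import scipy.linalg
import scipy.stats

from .corpus import GeneMap, RecordCorpus

__all__ = [
    "ComorbidityNetwork",
    "build_comorbidity_network",
    "build_bipartite_graph",
    "spectral_embedding",
    "modularity_embedding",
    "cooccurrence_neighbors",
    "most_frequent_gene_predictor",
    "disease_gene_cooccurrence_predictor",
]


@dataclass
class ComorbidityNetwork:
    """Significance-filtered disease-disease correlation network.

    ``graph`` carries per-edge attributes ``weight`` (= phi coefficient r),
    ``r``, ``t`` and ``p``; every retained edge passed the two-sided t-test
    at ``alpha`` with ``n_records - 2`` degrees of freedom.
    """

    graph: nx.Graph
    n_records: int
    alpha: float

    def neighbors(self, query: str, K: int) -> list[tuple[str, float]]:
        """Top-K neighbors by edge weight (ties lexicographic)."""
        if query not in self.graph:
            raise KeyError(f"unknown query token {query!r}")
        nbrs = [(n, self.graph[query][n]["weight"]) for n in self.graph[query]]
        nbrs.sort(key=lambda x: (-x[1], x[0]))
        return nbrs[:K]


def _incidence(corpus: RecordCorpus) -> tuple[list[str], np.ndarray]:
    """Binary disease x record incidence matrix with sorted disease order."""
    diseases = sorted({t for rec in corpus for t in rec})
    idx = {d: i for i, d in enumerate(diseases)}
    X = np.zeros((len(diseases), len(corpus)), dtype=np.float64)
    for j, rec in enumerate(corpus):
        for t in rec:
            X[idx[t], j] = 1.0
    return diseases, X


def build_comorbidity_network(
    corpus: RecordCorpus, alpha: float = 0.05
) -> ComorbidityNetwork:
    """Build the phi-correlation comorbidity network over a corpus.

    Edge weight is the Pearson correlation of the two binary incidence
    vectors; the edge survives when t = r*sqrt((n-2)/(1-r^2)) rejects zero
    correlation two-sided at ``alpha`` (n = record count). |r| = 1 edges are
    kept (t -> inf). A disease present in all or in no records has undefined
    correlations: the node is kept, its edges dropped, a warning logged.
    """
    n = len(corpus)
    if n < 3:
        raise ValueError("need >= 3 records to test correlations")
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    diseases, X = _incidence(corpus)
    means = X.mean(axis=1)
    degenerate = (means == 0.0) | (means == 1.0)
    if degenerate.any():
        bad = [d for d, b in zip(diseases, degenerate) if b]
        warnings.warn(
            f"{len(bad)} disease(s) occur in all or no records; their edges "
            f"are dropped: {bad[:5]}"
        )
    G = nx.Graph()
    G.add_nodes_from(diseases)
    Xc = X - means[:, None]
    ss = np.sqrt((Xc**2).sum(axis=1))
    t_crit = scipy.stats.t.ppf(1 - alpha / 2, df=n - 2)
    for a in range(len(diseases)):
        if degenerate[a]:
            continue
        for b in range(a + 1, len(diseases)):
            if degenerate[b]:
                continue
            r = float(Xc[a] @ Xc[b] / (ss[a] * ss[b]))
            r = max(-1.0, min(1.0, r))
            if abs(r) == 1.0:
                t_stat, p = np.inf if r > 0 else -np.inf, 0.0
                keep = True
            else:
                t_stat = r * np.sqrt((n - 2) / (1.0 - r * r))
                p = 2.0 * scipy.stats.t.sf(abs(t_stat), df=n - 2)
                keep = abs(t_stat) > t_crit
            if keep:
                G.add_edge(diseases[a], diseases[b], weight=r, r=r,
                           t=float(t_stat), p=float(p))
    return ComorbidityNetwork(graph=G, n_records=n, alpha=alpha)


def _record_cooccurrence(corpus: RecordCorpus) -> Counter:
    """Unordered disease-pair -> number of records containing both."""
    counts: Counter = Counter()
    for rec in corpus:
        uniq = sorted(set(rec))
        for i in range(len(uniq)):
            for j in range(i + 1, len(uniq)):
                counts[(uniq[i], uniq[j])] += 1
    return counts


def build_bipartite_graph(
    corpus: RecordCorpus,
    gene_map: GeneMap,
    gene_gene_edges: bool = True,
) -> nx.Graph:
    """Disease+gene adjacency graph.

    Disease-disease edges are weighted by record co-occurrence counts;
    disease-gene edges are unit-weighted from the association map; gene-gene
    edges (optional) are weighted by the number of shared host diseases.
    Node attribute ``kind`` is "disease" or "gene".
    """
    G = nx.Graph()
    for rec in corpus:
        for t in rec:
            G.add_node(t, kind="disease")
    for (a, b), w in _record_cooccurrence(corpus).items():
        G.add_edge(a, b, weight=float(w))
    for d in sorted(gene_map.diseases):
        if d not in G:
            G.add_node(d, kind="disease")
        for g in sorted(gene_map.genes(d)):
            if g not in G:
                G.add_node(g, kind="gene")
            G.add_edge(d, g, weight=1.0)
    if gene_gene_edges:
        shared: Counter = Counter()
        for d in gene_map.diseases:
            gs = sorted(gene_map.genes(d))
            for i in range(len(gs)):
                for j in range(i + 1, len(gs)):
                    shared[(gs[i], gs[j])] += 1
        for (a, b), w in shared.items():
            G.add_edge(a, b, weight=float(w))
    return G


def _fix_signs(vectors: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: first nonzero coordinate of each
    eigenvector (column) is positive."""
    for j in range(vectors.shape[1]):
        col = vectors[:, j]
        nz = np.nonzero(np.abs(col) > 1e-12)[0]
        if nz.size and col[nz[0]] < 0:
            vectors[:, j] = -col
    return vectors


def spectral_embedding(graph: nx.Graph, d: int) -> dict[str, np.ndarray]:
    """Rows of the d smallest-nonzero eigenvectors of the normalized Laplacian.

    Each connected component is embedded separately (cross-component
    similarity is meaningless and treated as -inf by ranking callers);
    components with fewer than d+1 nodes are zero-padded. Signs are fixed so
    the first nonzero coordinate of each eigenvector is positive.
    """
    n = graph.number_of_nodes()
    if d >= n:
        raise ValueError(f"d={d} must be smaller than the node count {n}")
    out: dict[str, np.ndarray] = {}
    for comp in nx.connected_components(graph):
        nodes = sorted(comp)
        sub = graph.subgraph(nodes)
        L = nx.normalized_laplacian_matrix(sub, nodelist=nodes, weight="weight").toarray()
        L = (L + L.T) / 2.0
        vals, vecs = scipy.linalg.eigh(L)
        nonzero = np.nonzero(vals > 1e-10)[0]
        take = nonzero[:d]
        V = _fix_signs(vecs[:, take].copy())
        emb = np.zeros((len(nodes), d))
        emb[:, : len(take)] = V
        for i, node in enumerate(nodes):
            out[node] = emb[i]
    return out


def modularity_embedding(graph: nx.Graph, d: int) -> dict[str, np.ndarray]:
    """Rows of the top-d eigenvectors of the modularity matrix B = A - k k^T / 2m.

    Same sign convention and per-component handling as
    :func:`spectral_embedding`.
    """
    n = graph.number_of_nodes()
    if d >= n:
        raise ValueError(f"d={d} must be smaller than the node count {n}")
    out: dict[str, np.ndarray] = {}
    for comp in nx.connected_components(graph):
        nodes = sorted(comp)
        A = nx.to_numpy_array(graph.subgraph(nodes), nodelist=nodes, weight="weight")
        k = A.sum(axis=1)
        two_m = k.sum()
        if two_m == 0:
            for node in nodes:
                out[node] = np.zeros(d)
            continue
        B = A - np.outer(k, k) / two_m
        vals, vecs = scipy.linalg.eigh(B)
        take = np.argsort(vals)[::-1][:d]
        V = _fix_signs(vecs[:, take].copy())
        emb = np.zeros((len(nodes), d))
        emb[:, : V.shape[1]] = V
        for i, node in enumerate(nodes):
            out[node] = emb[i]
    return out


def cooccurrence_neighbors(
    corpus: RecordCorpus, query: str, K: int
) -> list[tuple[str, int]]:
    """Diseases most frequently co-hospitalized with the query.

    Ranks by the number of records containing both diseases; ties break
    lexicographically. A query with no co-occurrences returns an empty list
    with a warning.
    """
    vocab = {t for rec in corpus for t in rec}
    if query not in vocab:
        raise KeyError(f"unknown query token {query!r}")
    counts: Counter = Counter()
    for rec in corpus:
        uniq = set(rec)
        if query in uniq:
            for t in uniq:
                if t != query:
                    counts[t] += 1
    if not counts:
        warnings.warn(f"query {query!r} never co-occurs with another disease")
        return []
    ranked = sorted(counts.items(), key=lambda x: (-x[1], x[0]))
    return ranked[:K]


def most_frequent_gene_predictor(train_map: GeneMap, K: int) -> list[str]:
    """The K genes associated with the most training diseases (query-independent)."""
    if len(train_map) == 0:
        raise ValueError("empty gene map")
    counts: Counter = Counter()
    for _d, genes in train_map.items():
        for g in genes:
            counts[g] += 1
    ranked = sorted(counts.items(), key=lambda x: (-x[1], x[0]))
    return [g for g, _ in ranked[:K]]


def disease_gene_cooccurrence_predictor(
    corpus: RecordCorpus, train_map: GeneMap, query: str, K: int
) -> list[str]:
    """Genes that most often appear, via their training host diseases, in
    records containing the query disease.

    Each occurrence of a gene-bearing disease in a query record contributes
    one count to each of its genes. A query that never co-occurs with a
    gene-bearing disease yields an empty list with a warning.
    """
    vocab = {t for rec in corpus for t in rec}
    if query not in vocab:
        raise KeyError(f"unknown query token {query!r}")
    counts: Counter = Counter()
    for rec in corpus:
        if query not in rec:
            continue
        for t in rec:
            if t == query:
                continue
            for g in train_map.genes(t):
                counts[g] += 1
    if not counts:
        warnings.warn(
            f"query {query!r} never co-occurs with a gene-bearing disease"
        )
        return []
    ranked = sorted(counts.items(), key=lambda x: (-x[1], x[0]))
    return [g for g, _ in ranked[:K]]
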