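"""Cosine nearest-neighbor retrieval and the retrieval-style evaluations.

Trained vectors are queried with cosine similarity. Three evaluations mirror
the phenotyping / gene-discovery protocols:

* ``precision_at_k_phenotype`` — a retrieved disease is positive when it
  shares at least one associated gene with the query disease;
* ``gene_overlap_at_k`` — set similarity (Jaccard by default) of the query's
  and neighbor's gene sets, averaged over the K neighbors and the queries;
* ``precision_at_k_genes`` — gene-discovery under a disease holdout: the
  fraction of the top-K retrieved genes that belong to the query disease's
  held-out gene set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .corpus import DISEASE, GENE, GeneMap
from .embedding import EmbeddingModel

__all__ = [
    "EvalReport",
    "cosine_similarity",
    "nearest_neighbors",
    "precision_at_k_phenotype",
    "gene_overlap_at_k",
    "precision_at_k_genes",
]


@dataclass
class EvalReport:
    """Per-K averages of one retrieval metric plus bookkeeping.

    ``values`` maps K -> average metric over queries (all in [0, 1]);
    ``skipped`` lists queries that could not be evaluated (reported, never
    silently dropped); ``config`` echoes the evaluation parameters.
    """

    metric: str
    values: dict[int, float]
    n_queries: int
    skipped: list[str] = field(default_factory=list)
    config: dict = field(default_factory=dict)

    def __post_init__(self):
        for k, v in self.values.items():
            if not (0.0 <= v <= 1.0 + 1e-12):
                raise ValueError(f"{self.metric}@{k} = {v} outside [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        ks = sorted(self.values)
        return pd.DataFrame(
            {f"@{k}": [self.values[k]] for k in ks}, index=[self.metric]
        )

    def to_dict(self) -> dict:
        return {
            "metric": self.metric,
            "values": {str(k): v for k, v in self.values.items()},
            "n_queries": self.n_queries,
            "skipped": list(self.skipped),
            "config": dict(self.config),
        }


def cosine_similarity(u: np.ndarray, v: np.ndarray, name: str = "vector") -> float:
    """u.v / (|u| |v|); raises on a zero-norm (degenerate) vector."""
    nu, nv = float(np.linalg.norm(u)), float(np.linalg.norm(v))
    if nu == 0.0 or nv == 0.0:
        raise ValueError(f"degenerate vector: {name} has zero norm")
    return float(np.dot(u, v) / (nu * nv))


def _candidate_ids(
    model: EmbeddingModel,
    candidate_kind: str,
    candidate_filter: Iterable[str] | None,
) -> np.ndarray:
    vocab = model.vocab
    if candidate_kind not in (DISEASE, GENE):
        raise ValueError(f"unknown candidate kind {candidate_kind!r}")
    ids = vocab.ids_of_kind(candidate_kind)
    if candidate_filter is not None:
        allowed = {vocab.token_to_id[t] for t in candidate_filter if t in vocab.token_to_id}
        ids = np.array([i for i in ids if int(i) in allowed], dtype=np.int64)
    return ids


def nearest_neighbors(
    model: EmbeddingModel,
    query: str,
    K: int,
    candidate_kind: str = DISEASE,
    candidate_filter: Iterable[str] | None = None,
) -> list[tuple[str, float]]:
    """Top-K tokens of the requested kind by cosine similarity to ``query``.

    The query itself is excluded; ties break by lexicographic token order;
    similarities are returned non-increasing. If K exceeds the candidate
    pool the full pool is returned with a warning.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    vocab = model.vocab
    if query not in vocab:
        raise KeyError(f"unknown query token {query!r}")
    qid = vocab[query]
    qvec = model.vectors[qid]
    qn = float(np.linalg.norm(qvec))
    if qn == 0.0:
        raise ValueError(f"degenerate vector: {query!r} has zero norm")
    ids = _candidate_ids(model, candidate_kind, candidate_filter)
    ids = ids[ids != qid]
    if ids.size == 0:
        warnings.warn(f"no candidates of kind {candidate_kind!r} for query {query!r}")
        return []
    mat = model.vectors[ids]
    norms = np.linalg.norm(mat, axis=1)
    ok = norms > 0.0
    if not ok.all():
        degen = [vocab.tokens[int(i)] for i in ids[~ok]]
        warnings.warn(f"skipping zero-norm candidate(s): {degen[:5]}")
        ids, mat, norms = ids[ok], mat[ok], norms[ok]
    sims = (mat @ qvec) / (norms * qn)
    if K > ids.size:
        warnings.warn(
            f"K={K} exceeds candidate pool of {ids.size}; returning full pool"
        )
        K = ids.size
    order = sorted(range(ids.size), key=lambda j: (-sims[j], vocab.tokens[int(ids[j])]))
    return [(vocab.tokens[int(ids[j])], float(sims[j])) for j in order[:K]]


def _phenotype_queries(model: EmbeddingModel, gene_map: GeneMap) -> list[str]:
    vocab = model.vocab
    return sorted(
        t for t in gene_map.diseases
        if t in vocab.token_to_id and vocab.kind(t) == DISEASE
    )


def _neighbor_lists(
    model: EmbeddingModel,
    queries: Sequence[str],
    K_max: int,
    pool: Iterable[str] | None,
) -> tuple[dict[str, list[str]], list[str]]:
    """Ranked neighbor tokens per query; zero-norm queries are skipped."""
    out: dict[str, list[str]] = {}
    skipped: list[str] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # pool-exhaustion warnings per query
        for q in queries:
            try:
                out[q] = [t for t, _ in nearest_neighbors(
                    model, q, K_max, candidate_kind=DISEASE, candidate_filter=pool)]
            except ValueError:
                skipped.append(q)
    return out, skipped


def precision_at_k_phenotype(
    model: EmbeddingModel,
    gene_map: GeneMap,
    K_list: Sequence[int] = (1, 2, 5, 10),
    candidate_pool: str = "annotated",
) -> EvalReport:
    """Average precision@K for phenotyping, shared genes as positives.

    Queries are the diseases present in both the model and the gene map. A
    retrieved neighbor is positive when it shares >= 1 gene with the query.
    By default the candidate pool is restricted to annotated diseases (a
    neighbor with no annotations could never be positive and would conflate
    model quality with annotation coverage); ``candidate_pool="all"`` ranks
    over every disease instead.
    """
    queries = _phenotype_queries(model, gene_map)
    if not queries:
        raise ValueError("no eligible queries: no annotated disease is in the model")
    pool = queries if candidate_pool == "annotated" else None
    K_max = max(K_list)
    neighbors, skipped = _neighbor_lists(model, queries, K_max, pool)
    values: dict[int, float] = {}
    for K in K_list:
        per_query = []
        for q, neigh in neighbors.items():
            gq = gene_map.genes(q)
            hits = sum(1 for n in neigh[:K] if gene_map.genes(n) & gq)
            per_query.append(hits / K)
        values[K] = float(np.mean(per_query))
    return EvalReport(
        metric="precision_phenotype",
        values=values,
        n_queries=len(neighbors),
        skipped=skipped,
        config={"K_list": list(K_list), "candidate_pool": candidate_pool},
    )


def gene_overlap_at_k(
    model: EmbeddingModel,
    gene_map: GeneMap,
    K_list: Sequence[int] = (1, 2, 5, 10),
    candidate_pool: str = "annotated",
    normalizer: str = "jaccard",
) -> EvalReport:
    """Average percentage of overlapping genes between query and neighbors.

    Per query/neighbor pair the overlap is |Gq n Gn| / |Gq u Gn| (Jaccard,
    default) or |Gq n Gn| / |Gq| (``normalizer="query"``), averaged over the
    K neighbors and then over queries.
    """
    if normalizer not in ("jaccard", "query"):
        raise ValueError(f"unknown overlap normalizer {normalizer!r}")
    queries = _phenotype_queries(model, gene_map)
    if not queries:
        raise ValueError("no eligible queries: no annotated disease is in the model")
    pool = queries if candidate_pool == "annotated" else None
    neighbors, skipped = _neighbor_lists(model, queries, max(K_list), pool)

    def overlap(q: str, n: str) -> float:
        gq, gn = gene_map.genes(q), gene_map.genes(n)
        inter = len(gq & gn)
        denom = len(gq | gn) if normalizer == "jaccard" else len(gq)
        return inter / denom if denom else 0.0

    values: dict[int, float] = {}
    for K in K_list:
        per_query = [
            float(np.mean([overlap(q, n) for n in neigh[:K]])) if neigh[:K] else 0.0
            for q, neigh in neighbors.items()
        ]
        values[K] = float(np.mean(per_query))
    return EvalReport(
        metric="gene_overlap",
        values=values,
        n_queries=len(neighbors),
        skipped=skipped,
        config={"K_list": list(K_list), "candidate_pool": candidate_pool,
                "normalizer": normalizer},
    )


def precision_at_k_genes(
    model: EmbeddingModel,
    test_map: GeneMap,
    K_list: Sequence[int] = (1, 2, 5, 10),
) -> EvalReport:
    """Gene-discovery precision@K under the disease-holdout protocol.

    The model must have been trained with the train split only. For each
    held-out disease the top-K gene tokens by cosine are retrieved;
    precision@K = |retrieved n held-out gene set| / K. Test diseases absent
    from the vocabulary are skipped with a warning and reported.
    """
    vocab = model.vocab
    queries = sorted(test_map.diseases)
    if not queries:
        raise ValueError("empty test map")
    present = [q for q in queries if q in vocab.token_to_id]
    skipped = [q for q in queries if q not in vocab.token_to_id]
    if skipped:
        warnings.warn(
            f"{len(skipped)} test disease(s) absent from the vocabulary; skipped"
        )
    if not present:
        raise ValueError("no test disease is present in the model vocabulary")
    K_max = max(K_list)
    ranked: dict[str, list[str]] = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for q in present:
            try:
                ranked[q] = [t for t, _ in nearest_neighbors(
                    model, q, K_max, candidate_kind=GENE)]
            except ValueError:
                skipped.append(q)
    values: dict[int, float] = {}
    for K in K_list:
        per_query = [
            sum(1 for g in ranked[q][:K] if g in test_map.genes(q)) / K
            for q in ranked
        ]
        values[K] = float(np.mean(per_query)) if per_query else 0.0
    return EvalReport(
        metric="precision_genes",
        values=values,
        n_queries=len(ranked),
        skipped=skipped,
        config={"K_list": list(K_list)},
    )
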