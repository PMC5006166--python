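"""Synthetic discharge corpora and gene maps with planted ground truth.

Real inpatient corpora and curated association catalogs are licensed, so the
package ships a generator that emulates their statistical structure:
diseases belong to latent phenotype clusters, each record draws its
diagnoses (mostly) from one cluster, and same-cluster diseases share genes
drawn from a per-cluster pool. The planted cluster labels act as a ground
truth oracle for every retrieval metric.

Defaults mirror the corpus statistics the models were designed around: mean
record length 7.58 diagnoses (records capped at 25 codes) and gene
annotations covering 23.5% of diseases.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .corpus import GeneMap, RecordCorpus

__all__ = ["SyntheticSpec", "GroundTruth", "generate", "expected_cluster_precision"]

_MAX_RECORD_LEN = 25


@dataclass
class SyntheticSpec:
    """Parameters of the planted-cluster generator.

    noise_rate is the per-token probability of drawing a disease uniformly
    from the *other* clusters instead of the record's own cluster.
    annotation_fraction is the share of each cluster's diseases that receive
    gene annotations. ``zipf_exponent`` (optional) makes within-cluster
    disease frequencies non-uniform, P(j) ~ (j+1)^-s, to exercise
    subsampling and the unigram noise distribution.
    """

    n_clusters: int = 10
    diseases_per_cluster: int = 20
    gene_pool_per_cluster: int = 30
    genes_per_disease: int = 10
    n_records: int = 20000
    record_length_mean: float = 7.58
    noise_rate: float = 0.05
    annotation_fraction: float = 0.235
    zipf_exponent: float | None = None
    seed: int = 0

    def __post_init__(self):
        for name in ("n_clusters", "diseases_per_cluster", "gene_pool_per_cluster",
                     "genes_per_disease", "n_records"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not (0 <= self.noise_rate < 1):
            raise ValueError("noise_rate must be in [0, 1)")
        if not (0 < self.annotation_fraction <= 1):
            raise ValueError("annotation_fraction must be in (0, 1]")
        if self.record_length_mean < 2:
            raise ValueError("record_length_mean must be >= 2")
        if self.genes_per_disease > self.gene_pool_per_cluster:
            raise ValueError(
                "infeasible sampling: genes_per_disease exceeds the cluster gene pool"
            )
        if self.n_clusters < 2 and self.noise_rate > 0:
            raise ValueError("noise_rate > 0 needs >= 2 clusters to draw noise from")

    @property
    def n_diseases(self) -> int:
        return self.n_clusters * self.diseases_per_cluster


@dataclass
class GroundTruth:
    """Planted cluster labels for every generated disease and gene token."""

    disease_cluster: dict[str, int]
    gene_cluster: dict[str, int]
    gene_map: GeneMap = field(repr=False)

    def same_cluster(self, a: str, b: str) -> bool:
        return self.disease_cluster[a] == self.disease_cluster[b]


def _disease_token(cluster: int, j: int) -> str:
    return f"C{cluster:02d}D{j:02d}"

def _gene_token(cluster: int, j: int) -> str:
    return f"C{cluster:02d}G{j:02d}"


def generate(spec: SyntheticSpec) -> tuple[RecordCorpus, GeneMap, GroundTruth]:
    """Generate a corpus, a gene map and the planted ground truth.

    Each record draws a cluster uniformly and a length 2 + Poisson(mean - 2)
    capped at 25; each token comes from the record's cluster with
    probability 1 - noise_rate, otherwise uniformly from the other clusters.
    The first round(annotation_fraction * diseases_per_cluster) diseases of
    each cluster receive genes_per_disease genes sampled without replacement
    from the cluster's gene pool, so same-cluster diseases share genes and
    cross-cluster pairs share none.
    """
    rng = np.random.default_rng(spec.seed)
    nC, nD = spec.n_clusters, spec.diseases_per_cluster

    if spec.zipf_exponent is not None:
        w = (np.arange(nD) + 1.0) ** (-spec.zipf_exponent)
        within_p = w / w.sum()
    else:
        within_p = np.full(nD, 1.0 / nD)

    clusters = rng.integers(0, nC, size=spec.n_records)
    lengths = 2 + rng.poisson(spec.record_length_mean - 2.0, size=spec.n_records)
    lengths = np.minimum(lengths, _MAX_RECORD_LEN)

    records: list[tuple[str, ...]] = []
    for c, M in zip(clusters, lengths):
        toks = []
        for _ in range(int(M)):
            if spec.noise_rate > 0 and rng.random() < spec.noise_rate:
                other = int(rng.integers(0, nC - 1))
                if other >= c:
                    other += 1
                j = int(rng.integers(0, nD))
                toks.append(_disease_token(other, j))
            else:
                j = int(rng.choice(nD, p=within_p))
                toks.append(_disease_token(int(c), j))
        records.append(tuple(toks))

    n_annot = max(1, round(spec.annotation_fraction * nD))
    assoc: dict[str, set[str]] = {}
    pvals: dict[tuple[str, str], float] = {}
    gene_cluster: dict[str, int] = {}
    for c in range(nC):
        for j in range(spec.gene_pool_per_cluster):
            gene_cluster[_gene_token(c, j)] = c
        for j in range(min(n_annot, nD)):
            d = _disease_token(c, j)
            picks = rng.choice(spec.gene_pool_per_cluster,
                               size=spec.genes_per_disease, replace=False)
            genes = {_gene_token(c, int(p)) for p in picks}
            assoc[d] = genes
            for g in genes:
                pvals[(d, g)] = float(10.0 ** (-rng.uniform(6.0, 9.0)))

    disease_cluster = {
        _disease_token(c, j): c for c in range(nC) for j in range(nD)
    }
    gene_map = GeneMap(assoc, pvals)
    truth = GroundTruth(disease_cluster=disease_cluster,
                        gene_cluster=gene_cluster, gene_map=gene_map)
    return RecordCorpus(records), gene_map, truth


def expected_cluster_precision(
    truth: GroundTruth,
    neighbor_lists: Mapping[str, Sequence[str]],
    K_list: Sequence[int] = (1, 2, 5, 10),
) -> dict[int, float]:
    """Cluster-label precision@K: a neighbor is positive when it lies in the
    query's planted cluster. Same averaging as the shared-gene phenotype
    precision, with the labels as oracle positives."""
    if not neighbor_lists:
        raise ValueError("no neighbor lists supplied")
    out: dict[int, float] = {}
    for K in K_list:
        per_query = []
        for q, neigh in neighbor_lists.items():
            cq = truth.disease_cluster[q]
            hits = sum(1 for n in neigh[:K] if truth.disease_cluster[n] == cq)
            per_query.append(hits / K)
        out[K] = float(np.mean(per_query))
    return out
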