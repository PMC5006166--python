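"""Model/Results front-end over the embedding trainers.

Follows the fit-then-results convention of statistical modelling packages:
construct a model object from data, call :meth:`fit`, and work with the
returned :class:`EmbeddingResults`, which carries the trained vectors, the
per-epoch objective trace and the retrieval-style evaluations.

    >>> corpus, gene_map, truth = generate(SyntheticSpec(seed=1))
    >>> res = D2D(corpus, config=TrainConfig(dim=50, seed=1)).fit()
    >>> res.nearest_neighbors("C00D00", K=5)
"""

from __future__ import annotations

from typing import Iterable, Sequence

import pandas as pd

from .corpus import DISEASE, GeneMap, RecordCorpus, Vocabulary, build_vocabulary
from .embedding import EmbeddingModel, TrainConfig, train_d2d, train_dag2d
from . import retrieval as _retrieval

__all__ = ["D2D", "DAG2D", "EmbeddingResults"]


class _SkipGramModel:
    """Shared scaffolding of the two embedding models."""

    def __init__(
        self,
        corpus: RecordCorpus,
        gene_map: GeneMap | None = None,
        config: TrainConfig | None = None,
        vocab: Vocabulary | None = None,
        min_count: int = 5,
    ):
        if len(corpus) == 0:
            raise ValueError("empty corpus")
        self.corpus = corpus
        self.gene_map = gene_map
        self.config = config or TrainConfig()
        self.min_count = min_count
        self.vocab = vocab or build_vocabulary(corpus, gene_map, min_count=min_count)

    def fit(self) -> "EmbeddingResults":
        raise NotImplementedError


class D2D(_SkipGramModel):
    """Disease-only skip-gram model over discharge records."""

    def __init__(self, corpus, config=None, vocab=None, min_count: int = 5):
        super().__init__(corpus, None, config, vocab, min_count)

    def fit(self) -> "EmbeddingResults":
        model = train_d2d(self.corpus, self.config, vocab=self.vocab,
                          min_count=self.min_count)
        return EmbeddingResults(self, model)


class DAG2D(_SkipGramModel):
    """Joint disease+gene skip-gram model; genes of the central disease also
    predict its context diseases, embedding genes in the disease space."""

    def __init__(self, corpus, gene_map: GeneMap, config=None, vocab=None,
                 min_count: int = 5):
        super().__init__(corpus, gene_map, config, vocab, min_count)

    def fit(self) -> "EmbeddingResults":
        model = train_dag2d(self.corpus, self.gene_map, self.config,
                            vocab=self.vocab, min_count=self.min_count)
        return EmbeddingResults(self, model)


class EmbeddingResults:
    """Fitted embedding: vectors, objective diagnostics and evaluations."""

    def __init__(self, model_spec: _SkipGramModel, model: EmbeddingModel):
        self.model_spec = model_spec
        self.model = model
        self.vocab = model.vocab
        self.config = model.config
        self.loss_trace = model.loss_per_epoch

    @property
    def vectors(self):
        return self.model.vectors

    def vector(self, token: str):
        return self.model.vector(token)

    def nearest_neighbors(self, query: str, K: int = 10,
                          candidate_kind: str = DISEASE,
                          candidate_filter: Iterable[str] | None = None):
        return _retrieval.nearest_neighbors(self.model, query, K,
                                            candidate_kind, candidate_filter)

    def phenotype_precision(self, gene_map: GeneMap,
                            K_list: Sequence[int] = (1, 2, 5, 10),
                            candidate_pool: str = "annotated"):
        return _retrieval.precision_at_k_phenotype(self.model, gene_map,
                                                   K_list, candidate_pool)

    def gene_overlap(self, gene_map: GeneMap,
                     K_list: Sequence[int] = (1, 2, 5, 10),
                     candidate_pool: str = "annotated",
                     normalizer: str = "jaccard"):
        return _retrieval.gene_overlap_at_k(self.model, gene_map, K_list,
                                            candidate_pool, normalizer)

    def gene_precision(self, test_map: GeneMap,
                       K_list: Sequence[int] = (1, 2, 5, 10)):
        return _retrieval.precision_at_k_genes(self.model, test_map, K_list)

    def save(self, path) -> None:
        self.model.save(path)

    def summary(self) -> str:
        kind = type(self.model_spec).__name__
        cfg = self.config
        rows = [
            ("model", kind),
            ("records", len(self.model_spec.corpus)),
            ("vocabulary (W)", len(self.vocab)),
            ("diseases", self.vocab.n_diseases),
            ("genes", len(self.vocab) - self.vocab.n_diseases),
            ("dimension (D)", cfg.dim),
            ("half-window (b)", cfg.window),
            ("negatives", cfg.negatives),
            ("epochs", cfg.epochs),
            ("subsample t", cfg.subsample_t),
            ("seed", cfg.seed),
        ]
        if self.loss_trace is not None and len(self.loss_trace):
            rows.append(("objective (first epoch)", f"{self.loss_trace[0]:.4f}"))
            rows.append(("objective (last epoch)", f"{self.loss_trace[-1]:.4f}"))
        df = pd.DataFrame(rows, columns=["", "value"]).set_index("")
        title = f"{kind} skip-gram embedding results"
        return f"{title}\n{'=' * len(title)}\n{df.to_string()}"

    def __repr__(self) -> str:
        return (f"<EmbeddingResults {type(self.model_spec).__name__} "
                f"W={len(self.vocab)} D={self.config.dim}>")
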