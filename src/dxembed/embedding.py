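"""Skip-gram embeddings of diseases (D2D) and diseases+genes (DAG2D).

Both models read each discharge record as a "sentence": the central disease
d_m predicts the diseases up to b positions before and after it. The exact
objective is the average log soft-max probability of each in-window context
disease given the center; training replaces the soft-max with the standard
negative-sampling surrogate,

    log sigma(v'_c . v) + sum_neg log sigma(-v'_n . v),

optimised by stochastic gradient ascent. DAG2D additionally lets every gene
associated with the central disease predict the same context diseases, which
places gene vectors in the disease space. Predicted (output) tokens are
always diseases, so the noise distribution is over disease tokens only.

The SGD inner loop is compiled with numba; ``exact_log_likelihood`` and
``full_softmax_ascent`` provide dense-softmax oracles for small instances.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from numba import njit
from scipy.special import logsumexp

from .corpus import DISEASE, GeneMap, RecordCorpus, Vocabulary, build_vocabulary

__all__ = [
    "TrainConfig",
    "EmbeddingModel",
    "subsample_keep_probability",
    "noise_distribution",
    "pair_update",
    "train_d2d",
    "train_dag2d",
    "exact_log_likelihood",
    "full_softmax_ascent",
    "save_embeddings",
    "load_embeddings",
]

_MAX_ORACLE_VOCAB = 5000
_SIGMOID_CLAMP = 50.0


@dataclass
class TrainConfig:
    """Hyperparameters of the skip-gram models.

    dim
        Embedding dimensionality D (default 200, the saturation point of the
        precision-vs-dimension sweep).
    window
        Context half-window b in record positions (default 8, close to the
        mean discharge-record length of 7.58 diagnoses).
    negatives
        Noise samples per positive pair (default 25).
    epochs
        Full passes over the corpus (default 5).
    lr_initial, lr_final
        Endpoints of the linear learning-rate decay over all scheduled
        center-context pairs.
    subsample_t
        Frequency threshold t of the keep probability min(1, sqrt(t/f));
        applied per center occurrence to diseases and genes alike.
    noise_power
        Exponent of the unigram noise distribution (count^power, default 0.75).
    seed
        Seeds both initialization and the training RNG stream.
    """

    dim: int = 200
    window: int = 8
    negatives: int = 25
    epochs: int = 5
    lr_initial: float = 0.025
    lr_final: float = 1e-4
    subsample_t: float = 1e-3
    noise_power: float = 0.75
    seed: int = 1

    def __post_init__(self):
        if self.dim < 1:
            raise ValueError("dim must be >= 1")
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if self.negatives < 1:
            raise ValueError("negatives must be >= 1")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not (self.lr_initial > self.lr_final > 0):
            raise ValueError("need lr_initial > lr_final > 0")
        if self.subsample_t <= 0:
            raise ValueError("subsample_t must be > 0")


class EmbeddingModel:
    """Paired input/output vector matrices over a vocabulary.

    ``vectors`` (input matrix, W x D) holds v_d and v_g for every token and
    is the released representation used at query time; ``output_vectors``
    (W x D) holds v'_d used inside the soft-max. Only disease rows of the
    output matrix are ever trained, since predicted tokens are diseases.
    """

    def __init__(
        self,
        vocab: Vocabulary,
        vectors: np.ndarray,
        output_vectors: np.ndarray,
        config: TrainConfig,
        loss_per_epoch: np.ndarray | None = None,
    ):
        W, D = vectors.shape
        if W != len(vocab) or output_vectors.shape != (W, D):
            raise ValueError("matrix shapes inconsistent with vocabulary")
        self.vocab = vocab
        self.vectors = vectors
        self.output_vectors = output_vectors
        self.config = config
        self.loss_per_epoch = loss_per_epoch

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]

    def vector(self, token: str) -> np.ndarray:
        return self.vectors[self.vocab[token]]

    def check_finite(self) -> None:
        if not (np.isfinite(self.vectors).all() and np.isfinite(self.output_vectors).all()):
            raise FloatingPointError("numerical divergence: non-finite embedding matrix")

    def save(self, path: str | Path) -> None:
        save_embeddings(self, path)

    def __repr__(self) -> str:
        return (f"EmbeddingModel(W={len(self.vocab)}, D={self.dim}, "
                f"n_diseases={self.vocab.n_diseases})")


def subsample_keep_probability(token_frequency: float, t: float) -> float:
    """Keep probability min(1, sqrt(t/f)) for a token of corpus frequency f.

    Tokens are discarded per center occurrence with probability 1 - keep,
    rebalancing updates away from very frequent diagnoses.
    """
    if token_frequency <= 0:
        raise ValueError("token frequency must be > 0 (token absent from corpus?)")
    if token_frequency > 1:
        raise ValueError("token frequency is a proportion in (0, 1]")
    if t <= 0:
        raise ValueError("threshold t must be > 0")
    return min(1.0, math.sqrt(t / token_frequency))


def noise_distribution(vocab: Vocabulary, power: float = 0.75) -> np.ndarray:
    """Unigram noise distribution over the vocabulary: P(d) ~ count(d)^power.

    Genes get probability exactly 0 — negative-sampling targets are always
    diseases. Returned vector sums to 1 (within 1e-12).
    """
    disease_ids = vocab.ids_of_kind(DISEASE)
    if disease_ids.size == 0:
        raise ValueError("vocabulary has no disease tokens")
    p = np.zeros(len(vocab), dtype=np.float64)
    w = vocab.counts[disease_ids].astype(np.float64) ** power
    p[disease_ids] = w / w.sum()
    return p


def _sigmoid(x: np.ndarray | float) -> np.ndarray | float:
    x = np.clip(x, -_SIGMOID_CLAMP, _SIGMOID_CLAMP)
    return 1.0 / (1.0 + np.exp(-x))


def pair_update(
    center_vec: np.ndarray,
    context_token: int,
    negatives: Sequence[int],
    lr: float,
    model: EmbeddingModel,
) -> float:
    """One gradient-ascent step of the negative-sampling objective for one pair.

    Updates the context output vector, each negative's output vector, and
    ``center_vec`` in place; returns the objective value at the pre-update
    point. All sigmoids are evaluated before any update is applied, so the
    step is an exact gradient of the pair objective.
    """
    negatives = np.asarray(negatives, dtype=np.int64)
    if np.any(negatives == context_token):
        raise ValueError("a negative sample equals the positive context token")
    syn1 = model.output_vectors
    s_pos = float(_sigmoid(syn1[context_token] @ center_vec))
    s_neg = _sigmoid(syn1[negatives] @ center_vec)
    loss = math.log(max(s_pos, 1e-300)) + float(np.log(np.maximum(1.0 - s_neg, 1e-300)).sum())
    if not math.isfinite(loss):
        raise FloatingPointError("numerical divergence in pair_update loss")
    # gradient wrt center uses pre-update output vectors
    grad_center = (1.0 - s_pos) * syn1[context_token] - (s_neg[:, None] * syn1[negatives]).sum(axis=0)
    syn1[context_token] += lr * (1.0 - s_pos) * center_vec
    np.add.at(syn1, negatives, lr * (-s_neg)[:, None] * center_vec)
    center_vec += lr * grad_center
    if not (np.isfinite(center_vec).all() and np.isfinite(syn1[context_token]).all()):
        raise FloatingPointError("numerical divergence in pair_update step")
    return loss


@njit(cache=True)
def _train_kernel(
    tokens,          # int64[:] flattened disease ids of the corpus
    offsets,         # int64[:] record start offsets, len = n_records + 1
    gene_indptr,     # int64[:] per-disease-id gene slice into gene_ids (len W+1)
    gene_ids,        # int64[:] gene vocabulary ids
    syn0,            # float64[W, D] input vectors (updated in place)
    syn1,            # float64[W, D] output vectors (updated in place)
    noise_cdf,       # float64[:] cumulative noise distribution over vocab ids
    keep_prob,       # float64[W] subsampling keep probability per token id
    epochs, window, n_neg, lr0, lr1, seed,
):
    """SGD inner loop shared by D2D and DAG2D.

    With an empty gene table the random stream and the update stream are
    exactly those of the plain disease model, so DAG2D with no gene map is
    bit-identical to D2D. Returns (objective sum per epoch, pair count per
    epoch, skipped-pair count).
    """
    np.random.seed(seed)
    n_records = offsets.shape[0] - 1
    D = syn0.shape[1]

    # total scheduled center-context pairs (subsampling does not change the
    # schedule, only whether a scheduled pair performs updates)
    pairs_per_pass = 0
    for r in range(n_records):
        M = offsets[r + 1] - offsets[r]
        for m in range(M):
            lo = m - window if m - window > 0 else 0
            hi = m + window + 1 if m + window + 1 < M else M
            pairs_per_pass += (hi - lo) - 1
    total_pairs = pairs_per_pass * epochs
    if total_pairs == 0:
        return np.zeros(epochs), np.zeros(epochs, dtype=np.int64), 0

    max_genes = 0
    for w in range(gene_indptr.shape[0] - 1):
        ng = gene_indptr[w + 1] - gene_indptr[w]
        if ng > max_genes:
            max_genes = ng
    gene_buf = np.empty(max_genes, dtype=np.int64)
    centers = np.empty(max_genes + 1, dtype=np.int64)
    negs = np.empty(n_neg, dtype=np.int64)
    scores = np.empty(n_neg + 1, dtype=np.float64)
    grad_center = np.empty(D, dtype=np.float64)

    loss_sum = np.zeros(epochs, dtype=np.float64)
    loss_n = np.zeros(epochs, dtype=np.int64)
    pairs_done = 0
    skipped = 0

    for epoch in range(epochs):
        for r in range(n_records):
            start = offsets[r]
            M = offsets[r + 1] - start
            for m in range(M):
                center = tokens[start + m]
                lo = m - window if m - window > 0 else 0
                hi = m + window + 1 if m + window + 1 < M else M
                n_ctx = (hi - lo) - 1
                # one survival draw per center occurrence
                survive = np.random.random() < keep_prob[center]
                n_centers = 0
                if survive:
                    centers[0] = center
                    n_centers = 1
                    g0, g1 = gene_indptr[center], gene_indptr[center + 1]
                    ng = g1 - g0
                    if ng > 0:
                        for j in range(ng):
                            gene_buf[j] = gene_ids[g0 + j]
                        if ng > 1:
                            # Fisher-Yates shuffle: fresh gene order per occurrence
                            for j in range(ng - 1, 0, -1):
                                k = np.random.randint(0, j + 1)
                                tmp = gene_buf[j]
                                gene_buf[j] = gene_buf[k]
                                gene_buf[k] = tmp
                        for j in range(ng):
                            g = gene_buf[j]
                            if np.random.random() < keep_prob[g]:
                                centers[n_centers] = g
                                n_centers += 1
                if n_ctx == 0:
                    continue
                for i in range(lo, hi):
                    if i == m:
                        continue
                    ctx = tokens[start + i]
                    lr = lr0 + (lr1 - lr0) * (pairs_done / total_pairs)
                    pairs_done += 1
                    if n_centers == 0:
                        continue
                    # draw negatives once per pair, shared by disease and
                    # gene centers (resample on collision with the target)
                    bad = False
                    for q in range(n_neg):
                        neg = -1
                        for _attempt in range(100):
                            u = np.random.random()
                            cand = np.searchsorted(noise_cdf, u)
                            if cand != ctx:
                                neg = cand
                                break
                        if neg < 0:
                            bad = True
                            break
                        negs[q] = neg
                    if bad:
                        skipped += 1
                        continue
                    for ci in range(n_centers):
                        cvec = syn0[centers[ci]]
                        # all scores at the pre-update point
                        for q in range(n_neg + 1):
                            row = ctx if q == 0 else negs[q - 1]
                            dot = 0.0
                            for k in range(D):
                                dot += syn1[row, k] * cvec[k]
                            if dot > _SIGMOID_CLAMP:
                                dot = _SIGMOID_CLAMP
                            elif dot < -_SIGMOID_CLAMP:
                                dot = -_SIGMOID_CLAMP
                            scores[q] = 1.0 / (1.0 + math.exp(-dot))
                        obj = math.log(scores[0] if scores[0] > 1e-300 else 1e-300)
                        for q in range(1, n_neg + 1):
                            om = 1.0 - scores[q]
                            obj += math.log(om if om > 1e-300 else 1e-300)
                        loss_sum[epoch] += obj
                        loss_n[epoch] += 1
                        g_pos = 1.0 - scores[0]
                        for k in range(D):
                            grad_center[k] = g_pos * syn1[ctx, k]
                        for q in range(1, n_neg + 1):
                            row = negs[q - 1]
                            s = scores[q]
                            for k in range(D):
                                grad_center[k] -= s * syn1[row, k]
                        for k in range(D):
                            syn1[ctx, k] += lr * g_pos * cvec[k]
                        for q in range(1, n_neg + 1):
                            row = negs[q - 1]
                            s = scores[q]
                            for k in range(D):
                                syn1[row, k] -= lr * s * cvec[k]
                        for k in range(D):
                            cvec[k] += lr * grad_center[k]
    return loss_sum / np.maximum(loss_n, 1), loss_n, skipped


def _corpus_arrays(corpus: RecordCorpus, vocab: Vocabulary):
    """Flatten the corpus into (token id array, record offsets), dropping
    tokens absent from the vocabulary (below min_count)."""
    toks: list[int] = []
    offsets = [0]
    for rec in corpus:
        for t in rec:
            i = vocab.token_to_id.get(t)
            if i is not None:
                toks.append(i)
        offsets.append(len(toks))
    return np.array(toks, dtype=np.int64), np.array(offsets, dtype=np.int64)


def _gene_table(vocab: Vocabulary, gene_map: GeneMap | None):
    """Per-disease-id CSR table of gene vocabulary ids (sorted for determinism)."""
    W = len(vocab)
    indptr = np.zeros(W + 1, dtype=np.int64)
    ids: list[int] = []
    if gene_map is not None:
        for w in range(W):
            if vocab.kinds[w] == DISEASE:
                for g in sorted(gene_map.genes(vocab.tokens[w])):
                    if g not in vocab.token_to_id:
                        raise ValueError(
                            f"gene {g!r} from the gene map is absent from the vocabulary"
                        )
                    ids.append(vocab.token_to_id[g])
            indptr[w + 1] = len(ids)
    return indptr, np.array(ids, dtype=np.int64)


def _keep_probabilities(vocab: Vocabulary, t: float) -> np.ndarray:
    total = int(vocab.counts[vocab.ids_of_kind(DISEASE)].sum())
    freqs = vocab.counts.astype(np.float64) / total
    return np.array([subsample_keep_probability(f, t) for f in freqs])


def _init_matrices(vocab: Vocabulary, config: TrainConfig):
    rng = np.random.default_rng(config.seed)
    W, D = len(vocab), config.dim
    syn0 = rng.uniform(-0.5 / D, 0.5 / D, size=(W, D))
    syn1 = np.zeros((W, D))
    return syn0, syn1


def _train(
    corpus: RecordCorpus,
    gene_map: GeneMap | None,
    config: TrainConfig,
    vocab: Vocabulary | None,
    min_count: int,
) -> EmbeddingModel:
    if vocab is None:
        vocab = build_vocabulary(corpus, gene_map, min_count=min_count)
    if len(vocab) == 0:
        raise ValueError("empty vocabulary")
    tokens, offsets = _corpus_arrays(corpus, vocab)
    gene_indptr, gene_ids = _gene_table(vocab, gene_map)
    noise_cdf = np.cumsum(noise_distribution(vocab, config.noise_power))
    keep = _keep_probabilities(vocab, config.subsample_t)
    syn0, syn1 = _init_matrices(vocab, config)
    kernel_seed = (config.seed * 2654435761 + 12345) % (2**31)
    loss, _n, skipped = _train_kernel(
        tokens, offsets, gene_indptr, gene_ids, syn0, syn1,
        noise_cdf, keep, config.epochs, config.window, config.negatives,
        config.lr_initial, config.lr_final, kernel_seed,
    )
    if skipped:
        import warnings

        warnings.warn(f"skipped {skipped} pair update(s): negative sampling "
                      "could not avoid the positive target")
    model = EmbeddingModel(vocab, syn0, syn1, config, loss_per_epoch=loss)
    model.check_finite()
    return model


def train_d2d(
    corpus: RecordCorpus,
    config: TrainConfig | None = None,
    vocab: Vocabulary | None = None,
    min_count: int = 5,
) -> EmbeddingModel:
    """Train the disease-only skip-gram model on a discharge corpus."""
    if len(corpus) == 0:
        raise ValueError("empty corpus")
    return _train(corpus, None, config or TrainConfig(), vocab, min_count)


def train_dag2d(
    corpus: RecordCorpus,
    gene_map: GeneMap,
    config: TrainConfig | None = None,
    vocab: Vocabulary | None = None,
    min_count: int = 5,
) -> EmbeddingModel:
    """Train the joint disease+gene model.

    Per center disease with attached genes, each in-window context disease is
    predicted once from the disease's input vector and once from each gene's,
    so gene vectors land in the same space. With an empty gene map the update
    and random streams reduce exactly to :func:`train_d2d`.
    """
    if len(corpus) == 0:
        raise ValueError("empty corpus")
    return _train(corpus, gene_map, config or TrainConfig(), vocab, min_count)


def _iter_pairs(corpus, vocab, window):
    """Yield (center position ids, context id) over all records."""
    for rec in corpus:
        ids = [vocab.token_to_id[t] for t in rec if t in vocab.token_to_id]
        M = len(ids)
        for m in range(M):
            lo, hi = max(0, m - window), min(M, m + window + 1)
            for i in range(lo, hi):
                if i != m:
                    yield ids[m], ids[i]


def exact_log_likelihood(
    model: EmbeddingModel,
    corpus: RecordCorpus,
    gene_map: GeneMap | None = None,
    window: int | None = None,
) -> float:
    """Exact average log-likelihood of the skip-gram objective (dense softmax).

    Oracle for small instances only (vocabulary guarded at 5,000 tokens).
    Soft-max normalisation runs over disease tokens; when a gene map is
    given, each gene of the central disease contributes its own conditional
    log-probability for every context disease, so the value is invariant to
    gene-list order.
    """
    if len(model.vocab) > _MAX_ORACLE_VOCAB:
        raise ValueError("oracle is for small instances (vocabulary > 5000 tokens)")
    window = model.config.window if window is None else window
    vocab = model.vocab
    disease_ids = vocab.ids_of_kind(DISEASE)
    syn1_d = model.output_vectors[disease_ids]  # Wd x D
    # position of each vocab id within the disease block
    pos = {int(w): i for i, w in enumerate(disease_ids)}
    gene_lists = {}
    if gene_map is not None:
        for w in disease_ids:
            gl = [vocab.token_to_id[g] for g in sorted(gene_map.genes(vocab.tokens[w]))]
            if gl:
                gene_lists[int(w)] = gl
    total = 0.0
    n_terms = 0
    for center, ctx in _iter_pairs(corpus, vocab, window):
        cs = [center] + gene_lists.get(center, [])
        for c in cs:
            logits = syn1_d @ model.vectors[c]
            lz = logsumexp(logits)
            p = np.exp(logits - lz)
            if abs(p.sum() - 1.0) > 1e-9:
                raise FloatingPointError("softmax normalisation check failed")
            total += logits[pos[ctx]] - lz
            n_terms += 1
    if n_terms == 0:
        raise ValueError("corpus yields no center-context pairs")
    return total / n_terms


def full_softmax_ascent(
    model: EmbeddingModel,
    corpus: RecordCorpus,
    gene_map: GeneMap | None = None,
    window: int | None = None,
    lr: float = 0.1,
    steps: int = 50,
) -> np.ndarray:
    """Batch gradient ascent on the exact soft-max objective (tiny instances).

    Optimisation oracle: returns the objective trace (length steps + 1)
    including the starting value. Updates model matrices in place.
    """
    if len(model.vocab) > _MAX_ORACLE_VOCAB:
        raise ValueError("oracle is for small instances (vocabulary > 5000 tokens)")
    window = model.config.window if window is None else window
    vocab = model.vocab
    disease_ids = vocab.ids_of_kind(DISEASE)
    pos = {int(w): i for i, w in enumerate(disease_ids)}
    gene_lists: dict[int, list[int]] = {}
    if gene_map is not None:
        for w in disease_ids:
            gl = [vocab.token_to_id[g] for g in sorted(gene_map.genes(vocab.tokens[w]))]
            if gl:
                gene_lists[int(w)] = gl
    pairs = []
    for center, ctx in _iter_pairs(corpus, vocab, window):
        for c in [center] + gene_lists.get(center, []):
            pairs.append((c, pos[ctx]))
    if not pairs:
        raise ValueError("corpus yields no center-context pairs")
    centers = np.array([p[0] for p in pairs])
    ctx_pos = np.array([p[1] for p in pairs])
    P = len(pairs)
    trace = np.empty(steps + 1)
    for s in range(steps + 1):
        syn1_d = model.output_vectors[disease_ids]
        logits = model.vectors[centers] @ syn1_d.T  # P x Wd
        lz = logsumexp(logits, axis=1)
        trace[s] = float(np.mean(logits[np.arange(P), ctx_pos] - lz))
        if s == steps:
            break
        probs = np.exp(logits - lz[:, None])
        dlogits = -probs
        dlogits[np.arange(P), ctx_pos] += 1.0
        dlogits /= P
        grad0 = dlogits @ syn1_d
        grad1 = dlogits.T @ model.vectors[centers]
        np.add.at(model.vectors, centers, lr * grad0)
        model.output_vectors[disease_ids] += lr * grad1
    return trace


def save_embeddings(model: EmbeddingModel, path: str | Path) -> None:
    """Write input vectors in word2vec text format plus a JSON sidecar manifest.

    Header "W D", then one line per token: the token followed by D decimal
    floats. The manifest ``<path>.manifest.json`` records token kinds,
    counts, output vectors and the training configuration.
    """
    path = Path(path)
    W, D = model.vectors.shape
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{W} {D}\n")
        for i in range(W):
            coords = " ".join(f"{x:.8e}" for x in model.vectors[i])
            fh.write(f"{model.vocab.tokens[i]} {coords}\n")
    manifest = {
        "kinds": model.vocab.kinds,
        "counts": [int(c) for c in model.vocab.counts],
        "config": asdict(model.config),
        "output_vectors": [[f"{x:.8e}" for x in row] for row in model.output_vectors],
    }
    Path(str(path) + ".manifest.json").write_text(
        json.dumps(manifest) + "\n", encoding="utf-8"
    )


def load_embeddings(path: str | Path) -> EmbeddingModel:
    """Read a model written by :func:`save_embeddings` (<=1e-6 round-trip error)."""
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    if not lines:
        raise ValueError(f"{path}:1: empty embeddings file")
    try:
        W, D = (int(x) for x in lines[0].split())
    except ValueError as e:
        raise ValueError(f"{path}:1: malformed header {lines[0]!r}") from e
    body = [ln for ln in lines[1:] if ln.strip()]
    if len(body) != W:
        raise ValueError(
            f"{path}:{len(lines)}: header declares {W} rows, found {len(body)}"
        )
    tokens: list[str] = []
    vecs = np.empty((W, D))
    for i, ln in enumerate(body):
        parts = ln.split()
        if len(parts) != D + 1:
            raise ValueError(f"{path}:{i + 2}: expected token + {D} floats")
        tokens.append(parts[0])
        vecs[i] = [float(x) for x in parts[1:]]
    man_path = Path(str(path) + ".manifest.json")
    if man_path.exists():
        man = json.loads(man_path.read_text(encoding="utf-8"))
        kinds = man["kinds"]
        counts = np.array(man["counts"], dtype=np.int64)
        config = TrainConfig(**man["config"])
        syn1 = np.array([[float(x) for x in row] for row in man["output_vectors"]])
    else:
        kinds = [DISEASE] * W
        counts = np.ones(W, dtype=np.int64)
        config = TrainConfig(dim=D)
        syn1 = np.zeros((W, D))
    vocab = Vocabulary(tokens=tokens, counts=counts, kinds=kinds)
    return EmbeddingModel(vocab, vecs, syn1, config)
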