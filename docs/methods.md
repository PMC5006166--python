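# Methods

## Model

Discharge records are token sequences ordered by diagnosis priority; the
package never reorders them. D2D is a skip-gram model over these
sequences: for a record of length M, every position m is a center and every
offset i ∈ [−b, b] \ {0} with 1 ≤ m+i ≤ M yields one (center, context)
pair. The window is fixed at ±b — there is no random window shrinking, and
truncation happens only at record boundaries — because the half-window
b = 8 is already matched to the mean record length (7.58 diagnoses), so
most records fit entirely inside one window. The conditional probability of
a context disease given a center token is a soft-max over *disease* output
vectors only.

DAG2D augments each center disease with its associated gene bag. Genes are
attached per position as bags, never inlined as sequence tokens: inlining
would shift window offsets between diseases and corrupt the disease
context structure. For every (center, context) pair, one update is made
with the disease's input vector and one with each attached gene's input
vector, against the same context output vector. Consequences that the test
suite pins down:

* genes live in the same D-dimensional space as diseases;
* the objective is invariant to the order of a disease's gene list (the
  update multiset is order-independent, and the exact objective sums over
  genes);
* an empty gene map reduces DAG2D to D2D *bit-for-bit* — both run the same
  compiled kernel with an empty gene table, so even the random streams
  coincide.

Gene lists are freshly shuffled per center occurrence. Association
catalogs order genes by study p-values, and those orderings carry
population biases between studies; shuffling removes the bias and the
objective is order-invariant anyway, so the shuffle only affects the
(irrelevant) sequential update order.

## Training

Negative sampling replaces the soft-max: each positive pair contributes
log σ(v′_c·v) + Σ over 25 noise draws of log σ(−v′_n·v). Noise diseases are
drawn ∝ count^0.75; genes have probability zero because genes are never
prediction targets in either objective. A noise draw colliding with the
positive target is redrawn (at most 100 attempts, then the pair is skipped
with a warning — in practice unreachable for vocabularies with ≥ 2
diseases).

Parameters, defaults and rationale:

| parameter | default | meaning / rationale |
|---|---|---|
| `dim` (D) | 200 | saturation point of retrieval precision vs dimension; tests and the acceptance experiments use 50 (and 12–24 for unit fixtures) to keep runs desk-scale |
| `window` (b) | 8 | half-window in positions, chosen near the 7.58 mean record length |
| `negatives` | 25 | noise samples per positive pair |
| `epochs` | 5 | corpus passes |
| `lr_initial`→`lr_final` | 0.025 → 1e-4 | linear decay over all *scheduled* pairs (epochs × pair count); subsampling skips a pair's updates but not its schedule slot, keeping the decay deterministic |
| `subsample_t` | 1e-3 | keep probability min(1, √(t/f)) per center occurrence; a gene's frequency is its host-disease occurrence frequency |
| `noise_power` | 0.75 | unigram exponent |
| `min_count` | 5 | vocabulary floor, the convention for this model family; synthetic fixtures pass 1 because every generated disease is frequent by construction |

Input vectors initialize uniform in (−0.5/D, +0.5/D), output vectors at
zero — standard for this model family. Update order is records in file
order, positions left to right, disease center first then its genes in
shuffled order; the order is fixed purely for reproducibility.

`pair_update` evaluates all sigmoids at the pre-update point and then
applies the updates, so one call is an exact gradient-ascent step of that
pair's objective (the classical sequential in-place variant differs only
when one negative is drawn twice in the same update). This is what makes
the central-difference gradient check exact to ~1e-9 relative error. Dot
products are clamped to ±50 before the sigmoid; beyond that range the
sigmoid is 1 to within double precision, and the clamp prevents overflow
in exp.

The inner loop is compiled with numba (single-threaded, no fastmath), with
its own seeded Mersenne–Twister stream, giving bit-identical matrices for
identical seeds across runs. The kernel seed is derived from the config
seed by a fixed affine map mod 2³¹ so that initialization (NumPy PCG64)
and training (kernel MT) use independent streams from one user-facing
seed.

## Exact-softmax oracles

`exact_log_likelihood` computes the dense soft-max objective (normalizer
summed over all disease tokens, checked to 1e-9) and is guarded at 5,000
tokens — it is an oracle for small instances, not a training path.
`full_softmax_ascent` performs batch gradient ascent on the same exact
objective; its non-decreasing trace on toy corpora certifies the gradient
direction independently of the negative-sampling code.

## Retrieval and evaluation

Query-time representations are input vectors; similarity is cosine.
Neighbor ties break lexicographically for determinism. Zero-norm vectors
raise on the query side and are skipped with a warning on the candidate
side; evaluation reports carry the skipped queries rather than silently
dropping them.

Phenotyping precision@K takes as queries the diseases present in both the
model and the gene map, and by default restricts the candidate pool to the
same annotated set: an unannotated neighbor could never count as positive,
so ranking over all diseases would conflate embedding quality with
annotation coverage ("all" mode is available). Gene overlap uses Jaccard
|G_q ∩ G_n| / |G_q ∪ G_n| by default — symmetric and bounded — with the
asymmetric |∩|/|G_q| variant behind a flag. Gene-discovery precision@K
retrieves gene tokens for held-out diseases; the denominator is always K,
even when the gene pool is smaller.

The comorbidity-network baseline uses the Pearson correlation of binary
per-record incidence vectors (the phi coefficient) with n = record count as
the unit of observation; edges survive a two-sided t-test
t = r√((n−2)/(1−r²)) at α = 0.05 (configurable; |r| = 1 edges are kept as
t → ∞). Rejected edges are removed rather than negated, and network
retrieval ranks by remaining edge weight. Eigen-embeddings fix signs by
making each eigenvector's first nonzero coordinate positive and embed each
connected component separately (cross-component similarity is meaningless;
ranking callers treat it as −∞); components smaller than d+1 nodes are
zero-padded. These conventions are not forced by the methods themselves —
they were chosen once for determinism.

## Synthetic generator

The generator emulates the two statistical features the models rely on:
records are cluster-pure up to a noise rate ε (each token is drawn from
the record's cluster with probability 1−ε), and same-cluster diseases
share genes drawn from a per-cluster pool while cross-cluster pairs share
none. Record lengths are 2 + Poisson(mean − 2) capped at 25, so every
record contributes at least one context pair and respects the 25-code cap
of discharge databases; the default mean is 7.58 and the default
annotation fraction 0.235, matching large inpatient corpora. Cluster sizes
and within-cluster frequencies are uniform by default; a Zipf option
skews within-cluster frequencies to exercise subsampling and the noise
distribution.

What the generator does *not* emulate — and hence what passing tests do
not show about real data: diagnosis-priority ordering effects (tokens are
exchangeable within a record), the heavy-tailed disease frequency
distribution of real corpora (unless the Zipf option is used), hierarchical
code structure, gene sets with cross-disease-group sharing, and
annotation biases of curated catalogs. One consequence is measurable: with
uniform frequencies and purely cluster-determined structure, the raw
co-occurrence baseline saturates at the same ceiling as the embeddings on
cluster retrieval (both reach precision@10 = 1.0 at the default
conditions), and in the gene-holdout task no predictor can beat the
base-rate genes_per_disease/pool in expectation, because held-out gene
sets are uniform draws independent of anything observable. The ordering
gaps reported on real corpora arise from sparsity and heterogeneity that
this planted model deliberately lacks; the corresponding comparative
assertions in the acceptance tests document this and fail honestly at the
default conditions.

## Problem sizes

Unit tests run on corpora of 10²–10³ records with D ≤ 24. The acceptance
experiments use the generator's default study conditions — 10 clusters ×
20 diseases, ε = 0.05, 20,000 records of mean length 7.58, D = 50, b = 8,
25 negatives, 5 epochs — chosen as the smallest configuration at which the
planted structure is recovered essentially perfectly and the evaluation
averages stabilise. The full suite and the acceptance script each complete
in well under five minutes on one CPU.

## Known limitations

* One vector per disease: a code used in distinct clinical contexts (e.g.
  sepsis from pneumonia vs from injury) gets a single averaged
  representation.
* D and b are not selected automatically.
* The exact-likelihood oracle is dense and deliberately capped at 5,000
  tokens.
* Evaluation treats shared-gene status as the positive label; this is a
  proxy for phenotype identity, inherited from the retrieval protocol, not
  a clinical ground truth.
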