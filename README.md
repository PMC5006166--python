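# dxembed

Disease and disease–gene embeddings from inpatient discharge records.

Hospital discharge summaries list the diagnoses (ICD-9 codes) of one
inpatient stay in priority order. Treating each discharge record as a
"sentence" of disease tokens, `dxembed` learns low-dimensional disease
representations with a skip-gram model, so that diseases occurring in
similar comorbidity contexts end up nearby in the vector space — even when
they never co-occur in the same patient. A joint extension embeds genes
from disease–gene association catalogs into the *same* space, which turns
disease phenotyping and gene discovery into plain cosine nearest-neighbor
queries. The package is aimed at computational-phenotyping and
systems-biology researchers who want these models, their evaluation
protocols, and the classical comorbidity-network baselines in one place,
runnable end to end on synthetic data with known ground truth.

## Models

**D2D (Disease2Diseases).** For each record d⁽ⁱ⁾ = (d₁ … d_M) the central
disease d_m predicts its neighbors up to b positions away; the objective is
the average log-probability

    L = mean over records, centers m, offsets −b ≤ i ≤ b (i ≠ 0) of
        log P(d_{m+i} | d_m),
    P(c | d) = exp(v′_c · v_d) / Σ_w exp(v′_w · v_d),

with separate input (v) and output (v′) vectors per disease. Training uses
the standard negative-sampling surrogate — log σ(v′_c·v_d) plus 25 noise
diseases drawn from the unigram^0.75 distribution — by stochastic gradient
ascent with a linearly decaying learning rate, and frequent-token
subsampling with keep probability min(1, √(t/f)).

**DAG2D (DiseaseAndGenes2Diseases).** When the central disease d_m carries
associated genes {g₁…g_N} (catalog associations filtered at p < 10⁻⁵), each
gene also predicts the same context diseases: the objective adds
log P(d_{m+i} | g_j) terms, placing gene vectors in the disease space.
Genes never occupy sequence positions and are never prediction targets;
with an empty gene map DAG2D is exactly D2D.

**Retrieval & evaluation.** Cosine-KNN queries over the trained input
vectors; precision@K for phenotyping (a retrieved disease is positive when
it shares a gene with the query), Jaccard gene-overlap@K, and gene-holdout
precision@K for discovery (hold out all gene associations of 20% of
annotated diseases, retrain, and count how many held-out genes are
retrieved). Baselines: the phi-coefficient comorbidity network with
t-statistic edge filtering, normalized-Laplacian and modularity-matrix
eigen-embeddings, raw co-occurrence ranking, and two trivial gene
predictors.

## Worked example

```python
import dxembed as dx

# synthetic EHR corpus: 10 phenotype clusters x 20 diseases, 20,000 records
corpus, gene_map, truth = dx.generate(dx.SyntheticSpec(seed=7))

res = dx.D2D(corpus, config=dx.TrainConfig(dim=50, seed=7), min_count=1).fit()
print(res.summary())
for token, sim in res.nearest_neighbors("C00D00", K=3):
    print(f"{token}\t{sim:.4f}")
```

prints (abridged):

```
D2D skip-gram embedding results
...
vocabulary (W)                      200
dimension (D)                        50
objective (first epoch)         -2.7860
objective (last epoch)          -2.5591
C00D01	0.9827
C00D12	0.9820
C00D19	0.9817
```

The three nearest neighbors of disease `C00D00` are all from its planted
cluster `C00`, with cosine similarity ≈ 0.98; across all 200 diseases the
cluster precision@10 is 1.00 on this corpus. The same pipeline runs from
the shell:

```bash
dxembed simulate --out data --seed 7
dxembed train d2d --records data/records.txt --dim 50 --min-count 1 \
        --out emb.txt --seed 7
dxembed nearest --embeddings emb.txt --query C00D00 --k 3
dxembed eval-phenotype --embeddings emb.txt --gene-map data/gene_map.tsv \
        --out pheno
dxembed eval-genes --records data/records.txt --gene-map data/gene_map.tsv \
        --dim 50 --min-count 1 --out genes --seed 7
```

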