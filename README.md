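# scitopic

Topic-model-based cell-type discovery for single-cell ATAC-seq.

Single-cell combinatorial-indexing ATAC-seq (sci-ATAC-seq) measures chromatin
accessibility in thousands of individual nuclei, but each cell yields only a
few hundred unique fragments — far too sparse to cluster cells from raw
profiles. `scitopic` implements the analysis strategy that made
cell-type-resolved accessibility maps possible for small, shallow libraries
(such as whole larval nematodes): model the binary cells-by-peaks matrix with
latent Dirichlet allocation (cells = documents, peaks = words), cluster cells
by their dominant topics, pool each cluster's Tn5 cut sites, and call peaks
again per cluster — recovering cell-type-specific regulatory sites whose
signal is drowned out by other cell types in bulk data. The loop is iterated
so that the improved peak set yields an improved model.

It is intended for computational biologists analysing sparse binary
single-cell accessibility matrices, and for methods work that needs a
transparent, fully testable collapsed-Gibbs LDA stack with planted-truth
simulators.

## The model

Each cell *d* draws a topic mixture θ_d ~ Dirichlet(α/K, …, α/K) over K
topics; each topic *k* has a peak distribution φ_k ~ Dirichlet(β/V, …, β/V)
over the V peaks. Every detected (cell, peak) entry is a token whose topic
assignment z is sampled by a collapsed Gibbs sampler with the conditional

    p(z_i = k | z_-i, w)  ∝  (n_dk + α/K) · (n_wk + β/V) / (n_k + β)

where the counts exclude token *i*. α and β are the *total* weights of the
symmetric priors (defaults α = 3, β = 2000 for a ~30k-peak vocabulary); a
higher value pushes the corresponding distribution toward uniform. Point
estimates of θ (cells × topics) and φ (topics × peaks) are averaged over
post-burn-in samples taken every `sample_stride` sweeps, with topic labels
aligned across samples.

The number of topics is chosen by five-fold cross-validation: peak-topic
distributions are trained on four folds, each held-out cell's marginal
likelihood is estimated with a Chib-style estimator (fit the cell's topic
vector with φ fixed, pick a high-probability pivot assignment z\*, and return
log p(w, z\*) − log p̂(z\* | w) from the transition kernel), and converted to
perplexity exp(−L/N). The K with the lowest mean held-out perplexity is
recommended, and the final model is trained with ⌈1.5 × K⌉ topics, since the
sampler tolerates surplus topics but not missing ones.

Downstream, the package computes the interpretation statistics used to tie
topics to tissues: per-peak topic specificity, nearest-downstream-gene
assignment (within 1200 bp, stranded), tissue-expression enrichment with
percentile confidence intervals, TF-ChIP and stage overlap enrichment with
size-matched nulls, base-pair Fisher overlap tests, signal enrichment over
shuffled peaks, tissue entropy, and per-gene peak-diversity scores.

## Worked example

Recover five planted cell types from a synthetic 600-cell binary matrix:

```python
from scitopic import LDAConfig, fit_lda, assign_cells, select_cluster_topics
from scitopic.synthetic import simulate_matrix, DESK_PRESET

matrix, truth = simulate_matrix(seed=7, **DESK_PRESET)
print(f"corpus: {matrix.shape[0]} cells x {matrix.shape[1]} peaks, "
      f"{matrix.matrix.nnz} tokens")

model = fit_lda(matrix, LDAConfig(n_topics=8, seed=1))
topics = select_cluster_topics(model.theta)          # centroid score > 0.2
labels = assign_cells(model.theta, topics)           # strict >50% rule

from sklearn.metrics import adjusted_rand_score
print(f"cell-type topics: {topics}")
print(f"assigned cells: {(labels >= 0).sum()} / {len(labels)}")
print(f"ARI vs planted types: {adjusted_rand_score(truth.cell_types, labels):.3f}")
```

Output:

```
corpus: 600 cells x 500 peaks, 39587 tokens
cell-type topics: [2, 4, 3, 6, 5]
assigned cells: 600 / 600
ARI vs planted types: 1.000
```

The model spends five of its eight topics on the five planted cell types
(the surplus topics absorb almost no probability), every cell puts >50% of
its topic weight on its own type's topic, and the resulting clustering
matches the planted labels exactly (adjusted Rand index 1.0).

The same analysis is available from the shell:

```bash
scitopic simulate fragments --seed 3 -o sim/
scitopic cutsites --fragments sim/fragments.tsv --chrom-sizes sim/chrom.sizes -o cut.bed
scitopic matrix --cutsites cut.bed --peaks sim/planted_peaks.bed -o M/
scitopic fit --matrix M/ -K 3 --beta 10 --iters 1000 -o model/
scitopic cluster --model model/ --seed 1 -o clusters/
```

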