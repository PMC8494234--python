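# Methods

This note documents the models, estimators, numerical choices, and known
limitations of `scitopic`, module by module.

## Preprocessing (fragments → cut sites)

A Tn5 insertion leaves a 9-bp staggered duplication, so the canonical
correction shifts plus-strand insertion points by +4 bp and minus-strand
points by −5 bp. Fragment records are BED-style half-open intervals; the
left insertion center is `start + 4` and the right one is `(end − 1) − 5`,
i.e. the −5 shift is applied to the last covered base, not to the exclusive
end coordinate. This is one self-consistent reading of a convention usually
stated for reads rather than fragment records, and it is applied uniformly.
Each center becomes a 60-bp window `[c − 30, c + 30)`, clipped at chromosome
bounds; windows emptied by clipping are dropped and counted.

Barcode correction accepts an observed barcode iff exactly one whitelist
entry lies within 3 edits and no other entry lies within 5. Barcodes are
fixed-length within a run, so Hamming distance is the default metric;
Levenshtein (via edlib) is available behind a flag. PCR duplicates are
collapsed on (barcode, chrom, start, end), and cells with fewer than 150
unique fragments are removed — with so few fragments a cell contributes
almost no usable signal and mostly noise.

## The binary matrix and the change-point filter

The corpus is strictly binary: a cell either shows evidence for a peak
(≥ 1 bp overlap between any of its cut-site windows and the peak) or it
does not. Multiplicities are deliberately discarded — at a few hundred
fragments per cell the count signal is negligible and binarization makes
the Dirichlet-multinomial model appropriate.

Outliers are removed by a change-point rule on the sorted per-item
detection fractions: sort, mean-center, and correlate with a zero-centered
logistic ramp (width 101 samples on [−6, 6] by default; the kernel is a
smoothed local-slope estimator). The flagging threshold is the mean plus
four interquartile ranges of the convolution output, with strict
inequality, so a constant vector removes nothing. Two details are design
choices the rule itself does not determine:

* **Localization.** A width-101 window cannot place a jump more precisely
  than ~50 items when the jump sits near the sorted order's edge — every
  window near the extreme straddles it. The convolution therefore only
  *detects* that a change point exists on a side (any window on that half
  exceeding the threshold); the removal boundary is then placed at the
  largest adjacent gap in the sorted values on that side, which is exactly
  what a direct slope-jump oracle computes. This keeps the flagged set
  tight (in the calibration scenario of 990 inliers and 10 planted
  outliers, all 10 and only those 10 are flagged).
* **Sides.** Cells are filtered on the low side only (sparse cells are
  noise); peaks on both sides (near-empty peaks are noise, near-ubiquitous
  peaks carry no discriminative information). Rows or columns left empty
  afterwards are dropped.

The filter operates in the regime where per-item fractions concentrate
tightly (hundreds of peaks or more); with very small vocabularies a lone
straggler may legitimately stay within the curve.

## Collapsed Gibbs LDA

Priors are symmetric Dirichlets parameterized by their **total** weights:
per-component hyperparameters are α/K and β/V. This convention reconciles a
β of 2000 with a ~30,000-peak vocabulary (per-peak weight ≈ 0.07) and
matches the reading that larger α or β give more weight to the uniform
prior. A `prior_style="per_component"` switch treats α and β as
per-component values directly. Defaults: α = 3.0, β = 2000.0, 4000 sweeps,
burn-in = half the sweeps, one posterior sample every 40 sweeps.

θ and φ are estimated by averaging the sampled count matrices and adding
the prior:

    θ_dk = (mean n_dk + α/K) / (N_d + α),   φ_kw = (mean n_wk + β/V) / (n_k + β).

**Label alignment.** On small corpora the chain visits topic relabelings of
the same mode within a single run; averaging raw samples would smear θ
across topics. Each sample's topic columns are therefore aligned to the
first sample by Hungarian matching on the cosine similarity of word-topic
count columns before accumulation. Per-token assignment frequencies
(`assignment_freq_`) are deliberately **not** aligned: they estimate the
exchangeable posterior, which is what exhaustive enumeration of p(z | w)
computes, and the two are compared directly in the tests (total variation
≤ 0.05 on a 4-token corpus, and co-assignment probabilities P(z_i = z_j),
which are label-invariant, agree with enumeration to ~0.01).

An alternative "mode" estimator takes each token's most frequently sampled
assignment and rebuilds the count matrices from it, mirroring the original
Java implementation's option. It is appropriate in the deep-data regime
where the chain stays in one labeling; with label switching it can produce
inconsistent assignments, which is why "mean" (with alignment) is the
default.

With `n_workers > 1`, documents are partitioned into contiguous shards;
each shard sweeps against a snapshot of the global word-topic counts and
the deltas are merged after every sweep (an approximate-distributed
factorization). Held-out perplexity of parallel and serial runs on the same
synthetic corpus agrees within 0.1% in the test suite. Single-worker runs
are bit-reproducible given the seed.

`transform`/`predict_theta` holds φ fixed and runs an independent chain per
cell, seeded from the master seed and the cell identifier — so permuting
the input cells permutes the output rows identically. (The analogous
exchangeability cannot hold for training: serial collapsed Gibbs couples
documents through the shared word-topic counts and the scan order.) Cells
with no in-vocabulary peaks receive the prior-mean row with a warning.

## Held-out likelihood and topic-count selection

The marginal likelihood of a held-out cell given φ uses a Chib-style
identity: for any pivot assignment z\*,
`log p(w) = log p(w, z*) − log p(z* | w)`, with p(w, z\*) available in
closed form (Dirichlet-multinomial document term × φ factors) and
p̂(z\* | w) estimated as the average probability that one systematic-scan
Gibbs sweep moves a stationary state to z\*. Two variance/bias controls
matter in practice:

* The chain is split into burn-in, a **pivot-selection phase** (z\* is the
  highest-joint-probability state visited), and a **collection phase** for
  the kernel average. Selecting the pivot from the same states used in the
  kernel average couples the two and biases p̂ upward (≈ +1.5% perplexity
  in the uniform-φ calibration); the phase split removes this.
* Several independent chains (default 4) are pooled: the globally best
  pivot is shared and all collected states enter one log-mean-exp kernel
  average.

Calibrations: at K = 1 the estimator reproduces the closed-form log
likelihood to 1e−6 (the identity is exact, every term is analytic); with
uniform φ over V = 100 peaks, single estimates land within 0.5% of the
analytic perplexity of exactly V (20,000 sweeps, 8 chains); on 3-token
documents it matches full enumeration to ~2%.

Model selection runs five-fold CV (cells split evenly and randomly; fold
and per-cell seeds derived from the master seed so per-K scores are
independent of the grid composition). The recommendation is the K with the
lowest mean per-cell held-out perplexity, ties toward smaller K; the final
model uses ⌈1.5 × K⌉ topics. On well-separated 3-type synthetic corpora
(150 cells, 40 peaks/type) the search recommends K = 3 in 5/5 seeded
repeats. CV-internal chains are short (400 training sweeps, 600 estimator
sweeps) because only the ranking across K matters, not absolute likelihood
accuracy.

## Topic clustering

A topic is a candidate cell type when its top-50 cells are cohesive: rank
cells by θ[:, k], average the dot products of those rows with their mean
row, and keep topics scoring above 0.2 (identical one-hot rows score 1;
fully diffuse rows score 1/K). Cells join a cluster by the strict >50% rule
(θ rows sum to one, so at most one topic can qualify). Clusters below 150
cells are grown in a 10-dimensional embedding of the L2-normalized θ: the
cluster centroid is the mean of 200 draws from a Gaussian KDE (Scott's
bandwidth) of the member coordinates, the nearest ⌈1.25 × size⌉ cells are
ranked by distance, the ranked distances are correlated with a ±1 step
kernel (half-width 10) to expose distance jumps, and the closest unassigned
cell whose convolution value does not exceed 1.5 × IQR is admitted — one
cell per iteration, existing labels immutable, small clusters processed in
ascending size order. When the member covariance is singular (e.g. an
embedding padded with constant dimensions) the plain member mean replaces
the KDE centroid. Clusters still below 50 cells are dissolved, since pooled
peak calling needs that much coverage. Embeddings default to UMAP
(deterministic given seed); a PCA reducer and arbitrary callables are
injectable, and the tests use PCA for speed and exact determinism.

## Peak calling and splitting

The MACS2 adapter invokes the external binary with the flag set appropriate
for 60-bp cut-site BED input on a ~9e7-bp genome (`--format BED -g 9e7
--nomodel --qvalue 0.05 --SPMR --tsize 60 --bdg --keep-dup all
--call-summits`), optionally with a naked-DNA control, and parses
narrowPeak/bedGraph output. When the binary is absent, the built-in caller
stands in at desk scale. It is intentionally simple and is **not** a MACS2
reimplementation: cut-site midpoints are counted in 150-bp windows stepped
75 bp; each window is tested against a Poisson rate equal to the maximum of
the genome-wide rate, the local rate in ±10-kb flanks, and the depth-scaled
control rate; Benjamini–Hochberg is applied across all windows at q = 0.05;
and surviving windows are merged, with the summit at the per-base coverage
maximum. Under the null (treatment = control, or uniform treatment) the
fraction of falsely significant windows stays below q in 30-replicate
simulations.

Multi-summit peaks are split into contiguous single-summit segments: the
per-base signal is smoothed with a 50-bp moving average, local maxima with
prominence ≥ 10% of the smoothed maximum are summits, and the boundary
between adjacent summits is the minimum-signal position, ties resolved
toward the midpoint. Segments exactly tile the original interval (verified
on 1000 random signals), and the `[1, 5, 1, 1, 6, 1]` toy signal splits
into `[0, 3)` and `[3, 6)`.

## The iterative pipeline and its synthetic test bed

`run_iteration` performs one full round: matrix → filter → LDA → topic
clustering → per-cluster pooled peak calling → merge. The fragment
generator plants two tiers of type-specific peaks on a 200-kb toy genome
(3 types × 100 cells × 120 fragments by default): *strong* peaks (45% of a
cell's fragments) that bulk calling finds and that drive the clustering,
and *weak* peaks (3%) designed from the Poisson detection arithmetic to sit
below the bulk detection line — where the background pools all three types
plus the depth-scaled control — but about √3 z-score units above the
per-cluster line. In this regime bulk calling misses ~90% of weak peaks
while one clustering round recovers ≥ 90% of those missed, and a second
round reproduces the first's peak set with base-pair Jaccard ≥ 0.97: the
loop is a near fixed point once the clusters are right. The pipeline
scenario trains at K = 3 (the number of planted groups, and what the CV
search itself recommends on such corpora): with a small per-type vocabulary
(~10 informative peaks), surplus topics fragment a type across two topics
and cells fall under the 50% assignment bar — unlike the deep desk-preset
matrix (80 peaks/type), where K = 8 leaves the three surplus topics empty.
The scenario also uses β = 10 for its ~40-peak vocabulary; the default
β = 2000 is a total prior mass calibrated to ~30k peaks and would swamp a
small vocabulary.

## Interpretation statistics

* **Topic specificity** of a peak = fraction of its carrying cells in the
  topic's cluster; per-topic peak lists take the top 250 by specificity or
  all above 0.5, whichever is larger, ties broken by coordinate.
* **Gene assignment**: nearest downstream exon within 1200 bp in the gene's
  orientation (on the minus strand, downstream is the lower-coordinate
  side). Peak–exon overlaps are excluded for topic→gene mapping and
  included for the entropy analyses, matching the two analyses' different
  conventions; the flag records which was used.
* **Enrichment statistics** report the mean log2 ratio of observed to null
  profiles and a 2.5/97.5 percentile interval over 100 null draws (draw
  count configurable; doubling it shrinks the interval in expectation).
  Nulls: random gene sets of 250 for tissue expression; multinomial draws
  proportional to per-topic peak counts for ChIP overlap; random peak sets
  of equal size from the peak universe for stage overlap. Zero cells get a
  0.5 pseudo-count and are flagged. HOT ChIP sites (occupancy ≥ 41
  experiments) are removed before TF-specific analyses. Stage assignment
  uses per-peak z-scores across stages with threshold 1.5 — note a one-hot
  profile over n stages caps at z = √(n−1), so with fewer than ~4 stages
  the threshold is unreachable by design.
* **Fisher overlap** builds the 2×2 table over base pairs (in A∩B, A only,
  B only, neither) and reports the right tail; it agrees with the direct
  hypergeometric tail to machine precision. An element-count variant is
  available behind the base-pair default.
* **Entropy** is Shannon entropy base 2 (configurable, recorded in
  outputs); **peak diversity** counts distinct tissue-set signatures among
  the connected components (≥ 1 bp overlap) of a gene's linked peaks. A
  flag counts components instead of deduplicated signatures; the worked
  example (isolated neuron peak + overlapping intestine/pharynx peaks)
  scores 2 under both readings.

## What the synthetic generators do and do not emulate

The generators reproduce the *structure* the method exploits — planted
cell-type-specific binary accessibility, two-tier fragment enrichment over
a toy genome, tissue-block expression, truth-linked ChIP intervals with HOT
contamination — with every artifact a pure function of parameters and seed.
They do not emulate Tn5 sequence bias, barcode-collision chemistry,
fragment-length periodicity from nucleosomes, doublets, or batch effects.
Passing tests therefore demonstrate that the implementation performs the
stated inference correctly in regimes where its assumptions hold, not that
those assumptions hold in any particular real library.

## Problem sizes

Test and acceptance runs use desk-scale problems chosen to exercise every
code path with stable statistics: 600-cell/500-peak matrices for recovery,
150-cell corpora for cross-validation, a 200-kb genome with 300 cells for
the end-to-end pipeline, 50,000-sweep chains for the enumeration oracle.
The implementation itself is vectorized/numba-compiled and handles
tens of thousands of cells and peaks; only the brute-force test oracles are
exponential.
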