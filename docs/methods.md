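# Methods

## Model

`duogate` integrates paired transcriptome and proteome measurements on the
same cells into a joint low-dimensional representation using a dual-path
graph-attention auto-encoder. Each modality runs through its own
auto-encoder over its own cell-neighborhood graph; the two embeddings are
concatenated and the whole system is trained self-supervised.

### Preprocessing

- **RNA**: counts are depth-scaled per cell to a common total (default
  10,000) and log1p-transformed; the top highly variable genes (default
  2,000) are kept, ranked by Seurat-flavor dispersion (variance/mean on the
  linear scale) standardized within quantile bins of mean expression. We
  use quantile bins sized to hold at least ~10 features each rather than a
  fixed count of 20 bins: fixed binning degenerates into singleton bins on
  matrices with few features, where a z-score is meaningless. Constant
  features are never selected.
- **Protein (ADT)**: Seurat-style centered log-ratio across features within
  each cell, `y_ij = log1p(x_ij / exp(mean_j log1p(x_ij)))`. The classical
  CLR (exact zero-sum with a pseudocount) is intentionally not the default;
  ADT pipelines in this field use the log1p form.
- Cells with zero total counts in either modality are dropped from both to
  preserve pairing.
- A PCA projection of the HVG matrix to 200 components (sign-fixed,
  deterministic) is used **only** for transcriptome neighbor search. The
  auto-encoder consumes the HVG-restricted normalized expression itself.

### Neighborhood graphs

For each modality, all pairwise Euclidean distances are computed (from the
PCA projection for RNA, the CLR matrix for protein, or the tissue
coordinates in spatial mode). Each cell keeps its `n` nearest neighbors
(default 15; exact ties broken by ascending cell index for determinism).
The neighbor sets are then pruned: cells are clustered with Leiden
(resolution 1.0 by default) per modality, and only neighbors sharing the
cell's community survive. The graph is **directed**, exactly as the
set-based definition implies — `j` being among `i`'s nearest neighbors does
not make `i` one of `j`'s. A union-symmetrization flag exists but is off by
default. The weighted adjacency `W = D ∘ B` (distance times indicator) is
kept for inspection and export; message passing in the model uses the
binary structure `B` plus one self-loop per cell, so cells whose pruned set
is empty are never dropped.

In spatial mode both modalities share the coordinate-derived kNN structure
and spatial edge weights, while pruning labels still come from each
modality's expression profile (`prune="none"` disables pruning entirely).

### Architecture

Per path: encoder layer 1 maps input → hidden (default 256) with
single-head additive graph attention and ReLU; encoder layer 2 maps hidden
→ embedding (default 30) with uniform neighbor averaging (attention
deliberately off) and Tanh, so embeddings lie in [−1, 1]. The decoder
mirrors this: embedding → hidden with uniform aggregation and ReLU, then
hidden → input with attention and a linear output. Decoder weights are
independent parameters (mirrored architecture, not tied weights; a tied
mode exists behind a flag). Attention scores are
`LeakyReLU(a_src·Wh_i + a_dst·Wh_j)` with slope 0.2, softmax-normalized
over each cell's retained neighbors plus its self-loop; distance weights
are not fed to the attention — scores are learned from features alone.

The joint representation is the column-wise concatenation
`Z = [T_emb | P_emb]` (60 columns at defaults). "Embedding dimension 30" is
read as per-path; the alternative (15+15) is a config change.

### Objective and training

```
L = (L_recon^t + L_recon^p) + λ (L_super^t + L_super^p),   λ = 0.1
```

Reconstruction is mean-squared error per modality. Self-supervision is a
triplet hinge on Z, `mean max(0, ‖z_a−z_p‖ − ‖z_a−z_n‖ + margin)` with
margin 1.0: both supervision terms are evaluated on the same joint Z and
differ only in which modality's graph supplies the triplets. Triplets are
resampled every epoch (one per anchor by default) from a dedicated seeded
stream: the positive is drawn uniformly from the anchor's pruned neighbors,
the negative uniformly from cells in a different pruning community; anchors
without neighbors are skipped, and a single-community labelling yields an
empty set with a warning (the supervision term is then zero).

Optimization is full-batch Adam (default betas, lr 0.001) for exactly 300
epochs — no early stopping. All forward and backward passes are written
directly in NumPy over a fixed edge structure with analytically derived
gradients (softmax attention, uniform aggregation, MSE, triplet hinge),
verified against central finite differences in the test suite. This keeps
the model dependency-light and bitwise-reproducible on one CPU: two runs
with the same seed produce identical loss histories and embeddings.
Separate RNG streams for initialization and triplet sampling mean a λ = 0
run reproduces a reconstruction-only run exactly.

Non-finite losses abort training with the epoch index; embeddings are
checked finite after every encoder pass.

## Evaluation protocol

The joint embedding is clustered with Leiden at resolutions 0.1, 0.2, …,
1.0 (seeded, deterministic) and each labelling is scored against ground
truth with Purity, Homogeneity, ARI and NMI; the report carries the
per-resolution table and mean ± sd. Homogeneity/ARI/NMI are delegated to
scikit-learn (NMI normalized by the arithmetic mean of entropies; other
normalizations selectable); purity is computed from the contingency table
directly. Degenerate single-class cases follow the conventional limits
(homogeneity 1, NMI 0). All four metrics are cross-checked in the tests
against independent brute-force contingency/entropy/all-pairs oracles.

Robust Rank Aggregation: for a methods × lists rank matrix, each method's
normalized ranks `r(1) ≤ … ≤ r(K)` give exact Beta order-statistic tail
probabilities `β_k = P(Beta(k, K−k+1) ≤ r(k))`; the score `ρ = min_k β_k`
is Bonferroni-corrected, `p = min(1, ρK)`. No Monte-Carlo is used in the
production path; the test suite verifies the closed-form single-list case
and super-uniformity of the p-values under a simulated null.

"x% Gaussian noise" is implemented as additive noise with per-feature
standard deviation equal to x% of that feature's standard deviation,
applied to the **normalized** matrices before graph construction; the
definition is recorded in every run manifest because other readings
(fraction of total signal, noise on raw counts) exist.

## Synthetic data

The generator emulates the CITE-seq regime: cells draw a latent position
(cluster center + unit Gaussian) in a shared 10-dimensional space; cluster
centers have scale 3 (between/within ratio ≈ 3 per latent dimension —
clearly separated populations, as in sorted-cell benchmarks). RNA counts
are negative binomial (dispersion 0.5) around softmax-normalized per-gene
rates times a uniform library size (1,000–5,000), followed by 30% Bernoulli
dropout; protein counts are Poisson around a high baseline (mean ≈ 30), so
RNA is sparse and high-dimensional while ADT is dense and low-dimensional.
The default desk-scale fixture is 600 cells × 200 genes × 30 proteins × 3
clusters, which the full 300-epoch pipeline processes in well under a
minute on one CPU; tests and the acceptance script use this scale so the
whole protocol (three seeds × four noise levels plus a spatial run) stays
within a few minutes.

The spatial variant places cells on a jittered integer lattice and assigns
labels by Voronoi regions of k random seed points (re-drawn until all
regions are populated), giving spatially contiguous ground-truth regions.

What the generator does **not** emulate: batch effects, doublets, ambient
RNA, cell-type hierarchies, count overdispersion heterogeneity across
genes, or realistic gene–gene correlation. Passing tests therefore
demonstrate correctness of the machinery and recoverability of planted
structure, not performance on real tissue atlases.

## Recovery measurement

For recovery experiments the generating number of clusters k is known, so
the sweep's model-selection step picks the resolution whose predicted
cluster count is closest to k (ties toward the lower resolution) and
reports ARI there. At higher resolutions Leiden deliberately over-partitions
(purity and homogeneity stay at 1 while ARI falls), which is granularity
mismatch rather than integration failure; matching granularity first makes
ARI measure what the experiment asks.

## Numerical choices and edge cases

- float64 throughout; full (not truncated) SVD for PCA at desk scale.
- PCA component signs fixed by making each component's largest-magnitude
  loading positive.
- `n_components` and `n_neighbors` are clipped to feasible values with a
  logged warning rather than erroring.
- Triplet distance gradients use an ε = 1e-12 guard against zero norms.
- Leiden runs on an undirected union kNN graph with the same neighbor
  budget as the method (n_iterations = 2, seeded).
- Known limitation: dense m × m distance matrices bound the practical size
  to a few tens of thousands of cells; no approximate-kNN backend is
  provided.
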