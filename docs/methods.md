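# Methods

`chromocnv` infers per-bin copy-number classes from intra-chromosomal Hi-C
contact matrices. This note documents the generative model behind the
synthetic data, the two classifiers, the numerical choices, and what the
passing tests do and do not establish about real data.

## The synthetic contact model

A chromosome is `n` bins of fixed size (default 40 kb). Ground truth is a
set of non-overlapping CNV segments; bins outside segments are diploid
(copy number 2). Classes: deletion (cn ≤ 1), normal (2), duplication (3),
high duplication (≥ 4). Copy numbers 0 and 1 share the deletion class
because the label vocabulary has a single deletion category.

Expected counts follow a distance-decay background with a multiplicative
copy-number effect:

```
E[c_ij] = base_depth · (|i−j|+1)^(−α) · (cn_i · cn_j) / 4
```

with a `diagonal_boost` multiplier on `|i−j| ≤ 1`. The `/4` puts diploid
pairs exactly at the background level, so a bin's off-diagonal row entries
scale as `cn_i/2` against a diploid background — the linear read-count ↔
copy-number relationship the classifiers exploit. Under `noise_model =
"poisson"` each upper-triangle entry is an independent Poisson draw with
this mean, mirrored to keep the matrix exactly symmetric.

Parameter defaults and why:

| parameter | default | rationale |
| --- | --- | --- |
| `bin_size` | 40,000 bp | standard resolution for CNV-scale analysis |
| `decay_exponent` α | 1.0 | canonical contact-probability decay within a chromosome |
| `base_depth` | 100 counts at distance 1 | deep enough that Poisson noise does not drown the cn signal, shallow enough that long-range cells are sparse, as in real maps |
| `diagonal_boost` | 5 | mimics short-range dominance of real Hi-C; a knob, not a claim |
| standard fixture | 1,000 bins, 12 segments of 25–50 bins, copies {1,3,4} | a 40-Mb chromosome where ~45% of bins sit in 1–2 Mb CNV segments, the regime a rearranged cancer genome presents |

The generator does **not** emulate: TADs, compartments, loops,
translocations, inter-chromosomal contacts, mappability/GC bias, or
segment-boundary uncertainty in the labels. Consequences: the synthetic
matrices are smoother and more homogeneous than real data, so absolute
accuracies here say little about accuracy on real cell lines; what the
tests do establish is that each component recovers a known signal of the
stated form, and how that recovery degrades under controlled perturbation.

## Linear model

Each bin is its raw matrix row `x_i ∈ R^n`; the model is 4-class
multinomial logistic regression `y = softmax(x_i W + b)`, trained by
full-batch gradient descent on the mean cross-entropy (lr 0.1, 2,000
epochs, zero init — the loss is convex, so runs are bit-reproducible given
the split seed).

Two numerical choices matter:

- **Global (scalar) feature scaling, not per-feature z-scores.** The
  discriminative signal is the *magnitude profile* of the row — every
  entry scales with `cn_i`. Per-feature standardization equalizes near-
  and far-diagonal columns and erases exactly that profile; a single
  scalar mean/std preserves it and is folded back into `(W, b)` after
  training, so prediction is a plain `softmax(xW + b)` on raw rows.
- **A small fixed ridge penalty (`weight_decay = 0.01`).** With `n`
  features and `0.6·n` training rows the unpenalized fit memorizes
  bin-specific columns; the ridge biases the fit toward the row-magnitude
  direction that generalizes. This is a single fixed constant, not a tuned
  regularization path.

Small-sample limitation: at a 10% training fraction on a 500-bin
chromosome (50 rows, 500 features) the fit collapses toward the majority
class (~61% held-out) even though the signal itself is intact — per-class
row-sum ranges are disjoint, and a row-sum-only classifier reaches ~89%.
The failure is sample complexity, not information: reference multinomial
fits (scikit-learn, any regularization strength) cap at ~70% in this
regime. On chromosomes with thousands of bins, where a 10% split still
provides hundreds of rows, the degradation is far milder.

**Dimension reduction** (for the weight-shared model across chromosomes):
PCA, factor analysis with varimax rotation (an orthogonal rotation), and
locally linear embedding, all via scikit-learn, fitted on the full matrix
before the split — the transform itself sees held-out rows, a leakage the
single-chromosome protocol shares by construction. LLE requires a
connected k-NN graph and `n_neighbors > d` (default `d+1`). The shared
model pools the per-chromosome 60% training splits. Caveat: PCA bases are
fitted per chromosome, so component order and sign follow each
chromosome's segment structure; shared-model accuracy is only comparable
to per-chromosome models when the chromosomes are structurally similar
(e.g. noise replicates of the same layout). Across genuinely different
chromosomes the shared model scores well below the per-chromosome models —
the same collapse motivates treating each chromosome's linear pattern as
specific.

## Graph pipeline

**Graph.** Bins are nodes; every off-diagonal cell `c_ij > min_weight`
(default 0: all positive contacts) is an undirected edge of weight
`c_ij`. An optional `top_k` union sparsifier exists for very large
chromosomes but defaults off.

**node2vec.** Second-order biased walks (return bias `p`, in-out bias `q`;
score of neighbor `x` from `cur` given `prev` is `w(cur,x)` times `1/p`
if `x = prev`, 1 if `x` adjacent to `prev`, else `1/q`), walk length 100,
10 walks per node, window 10, `d = 64`. Defaults `p = q = 1` reduce to
weight-proportional walks. The skip-gram trainer is SGNS with 5 negative
samples from the unigram^0.75 distribution, dynamic window, linearly
decaying learning rate (0.025), single-threaded and seeded, hence
deterministic. Three passes over the corpus are the default: with 10
walks × 100 steps per node the corpus already visits each node ~1,000
times per pass, and embeddings are stable after three. Isolated bins get
zero vectors and are excluded from training/evaluation splits.

**GCN.** Four graph-convolution layers over the symmetric-normalized
operator with unit self-loops, `Â = D̃^(−1/2)(W+I)D̃^(−1/2)`:

```
H1 = tanh(Â X W1),  H2 = tanh(Â H1 W2),  H3 = tanh(Â H2 W3),
H4 = tanh(Â (H1+H3) W4),  O = sigmoid(dropout(H4) W5 + b)
```

The residual re-injects `H1` additively into the last layer's input
(shapes force a sum; element-wise addition is the standard residual).
The head is a per-class sigmoid scored with per-class cross-entropy
against one-hot labels; classes are mutually exclusive, so a softmax head
would be the conventional choice, but the sigmoid head is retained as the
architecture's defining form and the gradient at the logits is identical
(`O − Y`). Training: full-batch Adam (lr 0.01, betas 0.9/0.999, 200
epochs), hidden width 64, dropout 0.5 on `H4` only, random 60/40 node
split. Forward/backward are hand-derived in numpy (float32 matmuls);
graphs are single chromosomes of at most a few thousand nodes, so
full-batch is cheap and mini-batching is unnecessary.

**Transfer.** A model trained on one chromosome is applied to another
after retraining node2vec on the target graph. Zero-shot accuracy is
volatile because independently trained skip-gram embeddings agree only up
to rotation; a shared seed aligns them approximately, not exactly.
Fine-tuning uses a random 2% of target labels for at most 5 full-batch
Adam steps at lr 0.05 (the largest step that does not destabilize the
trained weights in so few updates); with that budget it mainly
recalibrates the output layer toward the target's class priors, which is
sufficient for a double-digit accuracy gain on average but varies by seed.

**Metrics.** Accuracy is the fraction of correctly argmax-classified bins
(ties to the lowest class index). Macro F1 and macro one-vs-rest AUC
average over classes present in the truth; a class with no positives has
no ROC curve and is skipped, renormalizing the average. Both fraction and
percent are reported.

## Perturbation suite

Five operators, each a pure function of (input, seed), each reporting the
fraction of data it left unchanged: label reconstruction (i.i.d. uniform
class draws), label shuffling (permutation; preserves the class multiset,
so ~Σp² of labels keep their value by chance), row shuffling, value
shuffling (permutes all n² cells), and Gaussian value noise (N(0,1) added
to every cell). Row- and value-shuffled matrices are generally asymmetric;
since the chromosomal graph is undirected they are symmetrized as
`(M+Mᵀ)/2` at graph construction, and noise-induced negatives are floored
at 0 there (the stored perturbed matrix keeps them, so the operator remains
the exact arithmetic perturbation).

Measured pattern on the standard fixture: value noise is harmless (unit
noise on counts of order 10–500); value shuffling destroys the structure
and costs tens of points; label reconstruction pins held-out accuracy at
4-class chance. Row shuffling is **not** harmless here (~25-point drop):
after a row permutation the symmetrized matrix blends each bin's true
neighborhood with an unrelated bin's, and the retrained embeddings lose
their positional meaning. On sparse real matrices, where a large share of
cells are zeros mapping onto zeros, the same operator can leave the
effective graph largely intact — the harmlessness of row shuffling is a
property of the dataset, not of the model.

## Degenerate inputs and tie-breaks

Single-class training splits, all-zero matrices (for ICE), non-square or
asymmetric dense input, dimension mismatches, infeasible segment packings,
and fine-tuning samples covering one class all raise `ValueError` before
any compute. Argmax ties break to the lowest class index everywhere. ICE
masks all-zero bins (sentinel NaN bias) rather than adding pseudocounts,
keeping homozygous deletions visible downstream; convergence is max
relative row-sum deviation < 1e−5 within 200 iterations by default.

## Problem sizes

Default experiment sizes — 500-bin chromosomes for linear-model studies,
1,000-bin for the graph pipeline, 3–5 seeds per quantity — are the
package's standard desk-scale configuration; all headline behaviors
(linear-law recovery, ICE invariance, perturbation ordering, transfer
gains) are computed at these sizes by the test suite and
`scripts/acceptance.py`.
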