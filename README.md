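# chromocnv

Copy-number variation (CNV) inference from Hi-C contact maps.

Hi-C measures the contact frequency between pairs of genomic bins. Because a
segment present in `c` copies contributes proportionally more ligation
products, the expected contact count between bins *i* and *j* scales with
`cn_i · cn_j` on top of the usual genomic-distance decay — so a chromosome's
contact matrix carries its copy-number profile. `chromocnv` implements two
machine-learning routes from an intra-chromosomal contact matrix to per-bin
CNV classes (deletion ≤1, normal 2, duplication 3, high duplication ≥4),
for people studying how structural variation expresses itself in chromatin
contact data:

- **Linear model** — each bin's matrix row `x_i` is mapped through
  `y = softmax(x_i W + b)`; trained per chromosome by full-batch gradient
  descent on the cross-entropy, it exploits the linear read-count ↔
  copy-number relationship. A dimension-reduction harness (PCA / factor
  analysis / locally linear embedding, via scikit-learn) unifies feature
  dimensions so a single weight-shared model can be trained across
  chromosomes.
- **Graph model** — the matrix is treated as a weighted undirected graph
  (bins = nodes, counts = edge weights). node2vec (biased random walks +
  skip-gram with negative sampling) pretrains 64-dim node features, which a
  four-layer graph convolutional network with a residual connection
  classifies per bin:

  ```
  H1 = tanh(Â X W1)        Â = D̃^(-1/2) (W + I) D̃^(-1/2)
  H2 = tanh(Â H1 W2)
  H3 = tanh(Â H2 W3)
  H4 = tanh(Â (H1 + H3) W4)
  O  = sigmoid(dropout(H4) W5 + b)
  ```

  Training is full-batch Adam on a random 60% of bins; a transfer mode
  fine-tunes a trained model on a new chromosome from as little as 2% of
  its labels.

Around the models sit: a synthetic Hi-C generator with known CNV truth
(distance-decay background, multiplicative `cn_i·cn_j/4` effect, Poisson
noise), ICE matrix balancing and resolution coarsening, a five-operator
perturbation suite (label reconstruction / label shuffle / row shuffle /
value shuffle / Gaussian value noise) for probing what the models actually
learn, and metrics (accuracy, macro F1, macro one-vs-rest AUC, confusion).

## Worked example

```python
import numpy as np
from chromocnv import simulate_chromosome, fit_linear_model, run_gcn_pipeline
from chromocnv.linear import SplitSpec

# 500 x 40-kb bins, CNV segments with copies {1, 3, 4}, no noise
sim = simulate_chromosome(n_bins=500, n_segments=8, min_len=15, max_len=35,
                          noise_model="none", seed=0)
params, report = fit_linear_model(sim.matrix, sim.labels, SplitSpec(0.6, 0))
print(f"linear held-out accuracy: {report.accuracy_percent:.1f}%")

# 1,000-bin Poisson-noise chromosome through node2vec + GCN
noisy = simulate_chromosome(seed=0)
result = run_gcn_pipeline(noisy.matrix, noisy.labels, seed=0)
print(f"GCN held-out accuracy:    {result.report.accuracy_percent:.1f}%")
```

prints

```
linear held-out accuracy: 96.5%
GCN held-out accuracy:    96.2%
```

96.5% of the 200 held-out bins of the noise-free chromosome get the correct
CNV class from the linear row model; the graph pipeline reaches a similar
accuracy on the Poisson-noise fixture because the GCN aggregates each bin's
neighborhood and the node2vec features encode the chromosomal structure.

The same operations are available from the shell:

```bash
chromocnv simulate --n-bins 1000 --seed 0 --out-prefix demo
chromocnv train-gcn --matrix demo.matrix.tsv --labels demo.labels.bed \
    --out-model model.npz --metrics-json metrics.json
chromocnv perturb --kind value_shuffle --matrix demo.matrix.tsv \
    --labels demo.labels.bed --seed 0 --out-prefix shuffled
```

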