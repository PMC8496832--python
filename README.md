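# phenoreads

Attention-based **read-level phenotype prediction** for 16S rRNA amplicon
data.

Conventional microbiome classifiers first collapse reads into OTU/ASV
abundance tables and then classify samples. `phenoreads` inverts this:
a neural network classifies *each read* by the phenotype of the sample it
came from (body site, disease status, or a taxonomic label), and the
sample-level call is an aggregate of millions of read-level calls. Because
the network carries a soft-attention layer, it also *explains* itself: the
attention weights localise the nucleotide positions that drive the
classification, and the attention-weighted read embeddings cluster by
taxon without any taxonomic supervision.

## The model

A read of length `T` is one-hot coded (`T x 4`, channels A,C,G,T) and
passed through

* 1-D convolutional blocks (window `W = 9`, `N_c` channels, batch norm,
  ReLU) -> `T x N_c` local k-mer features,
* a bidirectional LSTM -> hidden states `h_t` (`T x N_h`),
* a soft-attention layer `e_t = w2' tanh(W1 h_t + b1)`,
  `alpha = softmax(e)` -> the read embedding `r = sum_t alpha_t h_t`,
* a dense softmax over the `N_y` phenotype classes.

Training uses Adam (lr 0.001) with binary/categorical cross-entropy,
10 epochs by default. Sample-level predictors built on the read outputs:

* **majority vote** — every read votes for each class whose score beats
  chance (`1/N`); argmax of vote counts;
* **averaged embedding** — mean read embedding per sample + Random Forest;
* **pseudo-OTU table** — k-means (k = 1000) over training read embeddings;
  per-sample cluster counts, row-normalised, + Random Forest;
* **9-mer frequency table** — the classical baseline.

Interpretation: per-position Shannon entropy
`H(l) = -sum_b f(b,l) log2 f(b,l)`, entropy-scaled class logos
`S_c(b,l) = f_c(b,l) H(l)`, class-mean attention profiles `A(c,l)`
(smoothed, window 9), attention re-indexed onto an external MSA, attention
budgets per 16S variable region, and PCA ordination of embeddings.

The network, backpropagation and Adam live in plain NumPy
(`phenoreads/_nn.py`) and are verified against finite differences in the
test suite. See `docs/methods.md` for assumptions, parameter meanings and
limitations.

## Worked example

Simulate a dataset whose 3 classes differ only inside a planted 10-base
window, train a small model, and check what it learned:

```python
import numpy as np
from phenoreads import (SyntheticSpec, generate_samples,
                        ReadPhenotypeModel, Hyperparams)
from phenoreads import sample

spec = SyntheticSpec(n_classes=3, n_genera=2, read_length=60,
                     reads_per_sample=100, samples_per_class=4,
                     substitution_rate=0.01, seed=42)
data = generate_samples(spec)

hp = Hyperparams(conv_channels=32, hidden_units=16, attention_units=8,
                 epochs=5, batch_size=128, learning_rate=0.005, seed=42)
model = ReadPhenotypeModel.from_records(
    data.records_for_split("train"), data.metadata, hp)
results = model.fit()
print(results.summary())
```

```
Read-level phenotype classifier
===============================================
classes               class_0, class_1, class_2
parameters            13,379
conv blocks           2 (window 9, 32 channels)
Bi-LSTM units         16 (8/direction)
attention units       8
dropout               0.0
optimiser             Adam, lr 0.005
loss                  categorical cross-entropy
epochs trained        5
final train loss      0.0065
final train accuracy  1.0000
```

Held-out reads and samples, and where the attention went:

```python
test = data.records_for_split("test")
outputs = results.predict_reads(test)          # attention, embedding, scores
att = np.stack([o.attention for o in outputs])
w = spec.planted_windows[0]
print(att[:, w.start:w.end].sum(axis=1).mean())  # mass in the planted window
```

prints (with the seeds above):

```
test read-level accuracy: 1.000
majority-vote sample accuracy: 1.000
attention mass in planted window 26-35 (uniform expectation 0.167): 0.732
```

The model classifies every held-out read correctly and concentrates 73%
of its attention on the 10 positions (17% of the read would be the
uniform share) that actually distinguish the classes — the attention
layer has rediscovered the planted locus.

The same pipeline is available from the shell:

```bash
phenoreads simulate --outdir data --seed 1
phenoreads train    --data-dir data --model-out model.npz
phenoreads predict  --data-dir data --model model.npz --outdir pred \
                    --strategies vote,embedding,pseudo_otu
phenoreads interpret --data-dir data --predictions pred --outdir interp
```

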