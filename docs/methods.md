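# Methods

## The model

`phenoreads` classifies *individual amplicon reads* by the phenotype of the
sample they were sequenced from, and aggregates the read-level signal into
sample-level predictions. The classifier is a hybrid
convolutional/recurrent network with soft attention:

1. **Input.** A read of length `T` is one-hot coded into a `T x 4` matrix
   on the fixed channel order A, C, G, T. IUPAC ambiguity codes become the
   uniform distribution over their compatible bases (N -> 0.25 on every
   channel); positions beyond a short read's end are all-zero padding rows.
2. **Convolutional blocks.** `n_conv_blocks` (default 2) blocks of
   same-padded 1-D convolution with window `W = 9` and `N_c` output
   channels, each followed by batch normalisation and ReLU. The window of
   9 reflects the k-mer length at which naive-Bayes 16S taxonomy
   classifiers saturate; the output is a `T x N_c` matrix of local k-mer
   features.
3. **Bi-LSTM.** A bidirectional LSTM with `N_h/2` units per direction
   (concatenated to `N_h`) integrates the features along the read, giving
   per-position hidden states `h_t` (`T x N_h`).
4. **Soft attention.** A two-stage scorer
   `e_t = w2' tanh(W1 h_t + b1)` with `N_a` hidden units, normalised by a
   softmax over positions, yields attention weights `alpha_t >= 0`,
   `sum_t alpha_t = 1`. The read embedding is `r = sum_t alpha_t h_t`.
5. **Classifier.** A dense layer with softmax maps `r` to `N_y` class
   scores. Cross-entropy loss (binary for two classes, categorical
   otherwise) is minimised with Adam at learning rate 0.001.

The two intermediate outputs — `alpha` and `r` — are the scientific point:
`alpha` localises the nucleotide positions the model relies on, and `r` is
a dense read representation that clusters by taxon even though training
labels are phenotypes.

The network, backpropagation and Adam are implemented directly in NumPy
(`phenoreads/_nn.py`). Every layer's analytic gradient is checked against
central finite differences in the test suite. Batch normalisation keeps
exponential running statistics (momentum 0.9) that are used at inference,
so predictions are independent of batch composition; duplicate inputs get
identical outputs, and batched vs one-at-a-time prediction agree to float32
round-off.

### Default hyperparameters

| parameter | default | meaning |
|---|---|---|
| `conv_window` (W) | 9 | convolution window, bases |
| `n_conv_blocks` | 2 | conv->batch-norm->ReLU blocks |
| `conv_channels` (N_c) | 256 | conv output channels |
| `hidden_units` (N_h) | 64 | Bi-LSTM width = embedding size |
| `attention_units` (N_a) | 16 | attention hidden nodes |
| `dropout` | 0.0 | after each conv block and on the embedding |
| `learning_rate` | 0.001 | Adam |
| `epochs` | 10 | full passes over the training reads |
| `batch_size` | 512 | reads per gradient step |

The `N_c = 256 / N_h = 64 / dropout 0 / lr 0.001` values are the
cross-validated optimum reported for read-level 16S phenotype prediction;
the batch size is our own choice (not part of that search) picked for
CPU-efficiency. One integer seed drives weight initialisation and epoch
shuffling; reruns on the same platform are bit-identical, but exact
cross-platform reproducibility of trained weights is not promised (BLAS
summation order may differ).

Variable-length inputs (e.g. near-full-length sequences) are right-padded
with zero vectors to the nearest multiple of 100 and grouped into
padded-length buckets; training draws batches within buckets, since the
convolution and LSTM are length-agnostic and share parameters across
buckets.

## Sample-level prediction

* **Majority vote.** Each read votes for every class whose score is
  *strictly* greater than chance `1/N` — a read compatible with several
  phenotypes votes for each. If no class exceeds `1/N` (uniform scores)
  the argmax class receives the single vote; this fallback, and breaking
  tied vote maxima by class-name order, are our own deterministic
  conventions for cases the voting rule leaves open.
* **Averaged embedding.** The arithmetic mean of a sample's read
  embeddings, classified by a Random Forest (100 trees).
* **Pseudo-OTU table.** Training-read embeddings are k-means clustered
  (Euclidean distance, `k = 1000` by default, k-means++ with 10 restarts
  and a fixed seed). Each sample's reads are counted over clusters and
  row-normalised to relative abundances — a learned analogue of an OTU
  table — and classified by a Random Forest. Empty clusters are retained
  as zero-usage columns so the table always has `k` columns.
* **k-mer baseline.** Per-sample relative frequencies of all overlapping
  9-mers (9 matching the convolution window), Random Forest on top.

Zero-read samples yield an all-zero count row, an undefined (NaN)
relative-abundance row, and are dropped from classifier training with a
warning.

## Interpretation

* **Entropy profile.** `H(l) = -sum_b f(b,l) log2 f(b,l)` in bits, with
  `f(b,l)` the observed base frequency at position `l` and `0 log 0 = 0`.
  Positions with gaps or ambiguity codes renormalise over the observed
  A/C/G/T only.
* **Class logo.** `S_c(b,l) = f_c(b,l) * H(l)`: class-conditional
  frequencies scaled by the *pooled* entropy, so letter heights within a
  class stack exactly to `H(l)` and invariant positions vanish.
* **Mean attention.** `A(c,l)` is the arithmetic mean of attention vectors
  grouped by class label — the *predicted* label for phenotype models
  (reads from mixed communities carry no true per-read phenotype), the
  *true* label for taxonomic models. For display the profile is smoothed
  by a centred moving average of window 9 (the convolution window); at the
  read ends the window truncates to the available positions. Smoothing is
  therefore mass-preserving away from the edges but not at them.
* **Alignment.** Given an externally produced MSA of the scored sequences,
  each attention value is re-indexed to the alignment column holding its
  residue; a sequence's gap columns are undefined (NaN) and column means
  average defined entries only (no renormalisation after alignment).
  Deleting gap columns from an aligned row recovers the input vector
  bit-exactly.
* **Region budgets.** Attention mass summed per variable region
  (breakpoints supplied as a 1-based inclusive TSV); non-overlapping
  regions partitioning the read give sums that add to the total attention.
* **Ordination.** Covariance PCA (no unit-variance scaling) onto the top
  two components; component signs are fixed by making each component's
  largest-magnitude loading positive so projections are deterministic.

## Synthetic data

The generator emulates the structure the method exploits: `n_genera`
random backbone references shared across classes except inside planted
windows, where each class has its own base assignment; samples draw reads
from genera by a per-class mixture, with i.i.d. substitutions (uniform
over the 3 alternative bases) and optional single-base indels re-trimmed/
padded to length `T`. Defaults — 3 classes, 5 genera, 100-base reads, 10
samples per class per split, 500 reads per sample, one 10-base centred
window, 1% substitution noise, no indels — are desk-scale study
conditions: large enough that attention localisation and all three
sample-level strategies are exercised end to end, small enough to train on
one CPU in minutes.

What the generator does *not* emulate: real 16S phylogenetic structure,
chimeras, PCR/sequencer error profiles, length variation within a run, or
class imbalance. Passing tests therefore demonstrate that the
implementation recovers planted signal under its stated noise model — not
that the architecture attains any particular accuracy on real microbiome
data.

Because every read's (genus, class) draw and mutated positions are
recorded, the noiseless entropy profile is known exactly, and test
separability can be dialled from perfect (distinct window assignments,
zero noise) to chance (no planted windows).

## Numerical and design choices

* Parameters are float32 by default (float64 available via
  `Hyperparams.dtype`); gradient checks run in float64.
* LSTM initialisation: Glorot-uniform input weights, orthogonal recurrent
  weights, unit forget-gate bias. Conv and dense layers Glorot-uniform.
* The attention scorer reads the Bi-LSTM states only (not the raw conv
  features).
* Nearest-centroid ties go to the lowest cluster index; vote ties to the
  first class in `class_names` order.
* Tests and the worked examples train a reduced network (`N_c = 64`,
  `N_h = 32`, 5 epochs) on 10 training samples per class (200–500 reads
  each): read-level training saturates quickly because reads, not samples,
  are the training unit.
* Model checkpoints are single `.npz` files embedding hyperparameters,
  class order, running statistics and the training log.

## Known limitations

* Training is CPU-bound dense NumPy: fine for thousands to hundreds of
  thousands of short reads, not for GPU-scale corpora.
* No quality filtering, primer trimming or paired-end merging — inputs are
  assumed preprocessed (FASTQ qualities are parsed and ignored).
* The network attends over zero-padding positions of right-padded reads;
  with homogeneous read lengths (the supported study design) this is
  moot, but heavily mixed-length batches within one bucket would let
  padding absorb attention mass.
* Multiple sequence alignment itself is out of scope; the alignment
  utilities consume an externally produced aligned FASTA.
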