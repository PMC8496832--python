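"""Sample-level phenotype prediction from read-level classifier outputs.

Three aggregation strategies are provided, plus a k-mer frequency baseline:

* **majority vote** — every read votes for each class whose likelihood score
  strictly exceeds chance (1/N); the sample prediction is the argmax of the
  vote counts;
* **averaged embedding** — the arithmetic mean of a sample's read embeddings,
  fed to a Random Forest;
* **pseudo-OTU table** — read embeddings of the training data are k-means
  clustered (Euclidean distance, 1000 clusters by default); per-sample read
  counts over clusters, row-normalised, form a relative-abundance feature
  table for a Random Forest, by analogy with conventional OTU tables;
* **k-mer table** — per-sample relative frequencies of all overlapping
  k-mers (default k=9, matching the convolution window).
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.ensemble import RandomForestClassifier

logger = logging.getLogger(__name__)


@dataclass
class VoteTally:
    """Per-sample vote counts over classes and the resulting call."""

    sample_id: str | None
    votes: np.ndarray
    class_names: list[str]
    threshold: float
    predicted_label: str


def majority_vote(
    score_vectors: np.ndarray | Sequence[np.ndarray],
    class_names: Sequence[str],
    sample_id: str | None = None,
) -> VoteTally:
    """Aggregate read class scores into a sample call by thresholded voting.

    Each read casts one vote for *every* class whose score is strictly
    greater than chance, 1/N — a read compatible with several phenotypes
    votes for each of them.  If no class exceeds 1/N (e.g. exactly uniform
    scores) the read's argmax class receives the single vote.  The sample
    prediction is the argmax of the vote counts; ties are broken in
    ``class_names`` order.
    """
    scores = np.atleast_2d(np.asarray(score_vectors, dtype=float))
    if scores.shape[0] == 0:
        raise ValueError("majority_vote requires at least one read")
    n = len(class_names)
    if n < 2:
        raise ValueError("majority_vote requires at least 2 classes")
    if scores.shape[1] != n:
        raise ValueError("score vectors and class_names disagree on class count")
    threshold = 1.0 / n
    above = scores > threshold
    votes = above.sum(axis=0).astype(int)
    # fallback: a read with no class above chance still casts its argmax vote
    none_above = ~above.any(axis=1)
    if none_above.any():
        fallback = scores[none_above].argmax(axis=1)
        votes += np.bincount(fallback, minlength=n)
    predicted = class_names[int(np.argmax(votes))]
    return VoteTally(sample_id, votes, list(class_names), threshold, predicted)


def average_embedding(read_embeddings: np.ndarray | Sequence[np.ndarray]) -> np.ndarray:
    """Sample-level embedding: the arithmetic mean of its read embeddings."""
    emb = np.asarray(read_embeddings, dtype=float)
    if emb.ndim != 2 or emb.shape[0] == 0:
        raise ValueError("need a non-empty list of equal-length read embeddings")
    return emb.mean(axis=0)


@dataclass
class PseudoOtuTable:
    """Samples x clusters abundance table from embedding clustering.

    ``counts`` rows sum to the sample's read count; ``relabund`` rows sum to
    1 for non-empty samples and are NaN for samples with zero reads
    (``empty_samples`` lists them).  Column order is centroid index order
    and the column count always equals k, even when clusters end up empty.
    """

    cluster_centroids: np.ndarray
    counts: pd.DataFrame
    relabund: pd.DataFrame
    empty_samples: list[str]


def pseudo_otu_fit(
    train_embeddings: np.ndarray,
    k: int = 1000,
    seed: int = 0,
) -> np.ndarray:
    """Cluster training read embeddings into ``k`` pseudo-OTU centroids.

    k-means with Euclidean distance, k-means++ initialisation and 10
    restarts; the seed fixes initialisation so refits are identical.
    """
    emb = np.asarray(train_embeddings, dtype=float)
    if emb.ndim != 2:
        raise ValueError("train_embeddings must be a 2-D array")
    if emb.shape[0] < k:
        raise ValueError(
            f"only {emb.shape[0]} embeddings for k={k} clusters; lower k "
            f"(e.g. k <= {emb.shape[0]})"
        )
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    km.fit(emb)
    return km.cluster_centers_


def assign_clusters(embeddings: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    """Nearest centroid (Euclidean) per embedding; ties to the lowest index."""
    emb = np.asarray(embeddings, dtype=float)
    # ||e - c||^2 = ||e||^2 - 2 e.c + ||c||^2 ; the ||e||^2 term is constant per row
    d2 = (centroids * centroids).sum(axis=1) - 2.0 * emb @ centroids.T
    return d2.argmin(axis=1)


def pseudo_otu_table(
    embeddings_by_sample: Mapping[str, np.ndarray],
    centroids: np.ndarray,
) -> PseudoOtuTable:
    """Count each sample's reads over the fitted pseudo-OTU clusters."""
    k = centroids.shape[0]
    sample_ids = list(embeddings_by_sample)
    counts = np.zeros((len(sample_ids), k), dtype=int)
    empty: list[str] = []
    for i, sid in enumerate(sample_ids):
        emb = np.asarray(embeddings_by_sample[sid], dtype=float)
        if emb.shape[0] == 0:
            empty.append(sid)
            continue
        counts[i] = np.bincount(assign_clusters(emb, centroids), minlength=k)
    with np.errstate(invalid="ignore", divide="ignore"):
        relabund = counts / counts.sum(axis=1, keepdims=True)
    cols = [f"pOTU_{j}" for j in range(k)]
    return PseudoOtuTable(
        cluster_centroids=centroids,
        counts=pd.DataFrame(counts, index=sample_ids, columns=cols),
        relabund=pd.DataFrame(relabund, index=sample_ids, columns=cols),
        empty_samples=empty,
    )


def fit_sample_classifier(
    features: np.ndarray | pd.DataFrame,
    labels: Sequence[str],
    seed: int = 0,
) -> RandomForestClassifier:
    """Random Forest (100 trees, library defaults) on sample-level features.

    Works interchangeably on averaged embeddings, pseudo-OTU relative
    abundances or k-mer tables.  Samples whose feature row is all-NaN
    (zero-read samples) are dropped with a warning.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    valid = ~np.isnan(X).any(axis=1)
    if not valid.all():
        warnings.warn(
            f"dropping {int((~valid).sum())} zero-read sample(s) from training",
            stacklevel=2,
        )
        X, y = X[valid], y[valid]
    if len(np.unique(y)) < 2:
        raise ValueError("need at least 2 classes to train the sample classifier")
    clf = RandomForestClassifier(n_estimators=100, random_state=seed)
    clf.fit(X, y)
    return clf


def predict_samples(
    classifier: RandomForestClassifier, features: np.ndarray | pd.DataFrame
) -> np.ndarray:
    X = np.asarray(features, dtype=float)
    if X.shape[1] != classifier.n_features_in_:
        raise ValueError(
            f"feature dimension {X.shape[1]} does not match the classifier's "
            f"{classifier.n_features_in_}"
        )
    return classifier.predict(X)


def kmer_table(
    reads_by_sample: Mapping[str, Sequence[str]], k: int = 9
) -> pd.DataFrame:
    """Per-sample relative frequencies of all overlapping k-mers.

    Only windows consisting purely of A/C/G/T are counted; windows touching
    any other character are skipped.  Columns are all 4^k k-mers in
    lexicographic order.  A sample with no countable window gets an all-zero
    row (flagged with a warning).
    """
    if k < 1:
        raise ValueError("k must be positive")
    base_idx = np.full(256, -1, dtype=np.int64)
    for i, b in enumerate("ACGT"):
        base_idx[ord(b)] = i
    n_cols = 4 ** k
    sample_ids = list(reads_by_sample)
    counts = np.zeros((len(sample_ids), n_cols), dtype=np.int64)
    for row, sid in enumerate(sample_ids):
        for read in reads_by_sample[sid]:
            codes = base_idx[np.frombuffer(read.upper().encode(), dtype=np.uint8)]
            if len(codes) < k:
                continue
            # rolling base-4 encoding over valid (ACGT-only) windows
            powers = 4 ** np.arange(k - 1, -1, -1)
            windows = np.lib.stride_tricks.sliding_window_view(codes, k)
            valid = (windows >= 0).all(axis=1)
            if valid.any():
                keys = windows[valid] @ powers
                counts[row] += np.bincount(keys, minlength=n_cols)
    row_sums = counts.sum(axis=1, keepdims=True)
    zero_rows = row_sums[:, 0] == 0
    if zero_rows.any():
        warnings.warn(
            f"sample(s) with no countable {k}-mer window: "
            f"{[sample_ids[i] for i in np.where(zero_rows)[0]]}",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(row_sums > 0, counts / np.maximum(row_sums, 1), 0.0)
    columns = ["".join(p) for p in itertools.product("ACGT", repeat=k)]
    return pd.DataFrame(freq, index=sample_ids, columns=columns)
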