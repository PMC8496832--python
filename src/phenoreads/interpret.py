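"""Interpretation of trained read classifiers: entropy logos and attention.

The three quantities computed here are

* the per-position Shannon entropy of a read group,
  ``H(l) = -sum_b f(b,l) log2 f(b,l)`` with ``f(b,l)`` the observed base
  frequency at position ``l`` (0 log 0 = 0, so H is in [0, 2] bits);
* the entropy-scaled class logo ``S_c(b,l) = f_c(b,l) * H(l)``, where
  ``f_c`` is the base frequency among reads of class ``c`` and ``H`` is the
  *pooled* entropy — letter heights within a class stack to H(l);
* the class-wise mean attention ``A(c,l)``, the arithmetic mean of the
  attention vectors of reads grouped by predicted (or true) class label,
  optionally smoothed by a centred moving average of window 9 (the
  convolution window, so the smoothing scale matches the features the
  attention is computed from).

Attention vectors can additionally be re-indexed into the column space of
an external multiple sequence alignment, and summed per 16S variable
region to budget where a model spends its attention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .seqio import BASES

_BASE_TO_COL = {b: i for i, b in enumerate(BASES)}


@dataclass
class EntropyProfile:
    """Per-position base frequencies and Shannon entropy (bits)."""

    H: np.ndarray
    freqs: np.ndarray
    n_reads: np.ndarray


@dataclass
class ClassLogo:
    """Entropy-scaled letter heights per class: S_c(b,l) = f_c(b,l) H(l)."""

    S: np.ndarray           # class x L x 4
    class_freqs: np.ndarray  # class x L x 4
    classes: list[str]
    H: np.ndarray


@dataclass
class AttentionSummary:
    """Class-wise mean attention, raw and smoothed."""

    A: np.ndarray           # class x L
    smoothed: np.ndarray    # class x L
    classes: list[str]
    grouping: str
    window: int


@dataclass
class AlignedAttention:
    """Attention vectors re-indexed to alignment columns.

    ``per_sequence`` has one row per input vector in alignment-column
    space; entries at a sequence's gap columns are NaN.  ``column_mean``
    averages the defined entries only, so gaps dilute nothing.
    """

    ids: list[str]
    per_sequence: np.ndarray  # n x L_aln with NaN at gaps
    column_mean: np.ndarray


@dataclass
class RegionTable:
    """Per-group attention mass inside each (variable) region."""

    regions: pd.DataFrame     # name, start, end (1-based inclusive)
    attention_sums: pd.DataFrame  # groups x regions


def _base_counts(sequences: Sequence[str]) -> np.ndarray:
    """L x 4 counts of A/C/G/T; gaps and ambiguity codes are not counted."""
    lengths = {len(s) for s in sequences}
    if len(lengths) != 1:
        raise ValueError(f"sequences have differing lengths: {sorted(lengths)}")
    (length,) = lengths
    counts = np.zeros((length, 4))
    for seq in sequences:
        for i, ch in enumerate(seq.upper()):
            col = _BASE_TO_COL.get(ch)
            if col is not None:
                counts[i, col] += 1
    return counts


def entropy_profile(sequences: Sequence[str]) -> EntropyProfile:
    """Positional base frequencies and Shannon entropy of a read group.

    Frequencies are normalised over the observed A/C/G/T at each position
    (gap or ambiguity characters do not enter the normalisation).
    """
    if len(sequences) == 0:
        raise ValueError("entropy_profile requires at least one sequence")
    counts = _base_counts(sequences)
    n = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        freqs = np.where(n[:, None] > 0, counts / np.maximum(n, 1)[:, None], 0.0)
        plogp = np.where(freqs > 0, freqs * np.log2(freqs), 0.0)
    return EntropyProfile(H=-plogp.sum(axis=1), freqs=freqs, n_reads=n)


def class_logo(
    sequences: Sequence[str],
    class_labels: Sequence[str],
    profile: EntropyProfile | None = None,
    classes: Sequence[str] | None = None,
) -> ClassLogo:
    """Entropy-scaled sequence logo per class.

    Letter heights are the class-conditional base frequencies scaled by the
    pooled (all-class) positional entropy, so positions that are invariant
    across the whole group vanish and class-discriminative positions show
    which base each class prefers.  ``profile`` defaults to the pooled
    entropy of ``sequences`` and must be the pooled one if supplied.
    """
    if len(sequences) != len(class_labels):
        raise ValueError("sequences and class_labels lengths differ")
    if profile is None:
        profile = entropy_profile(sequences)
    if classes is None:
        classes = sorted(set(class_labels))
    labels = np.asarray(class_labels)
    present = set(labels)
    missing = [c for c in classes if c not in present]
    if missing:
        raise ValueError(f"class(es) absent from labels: {missing}")
    class_freqs = np.zeros((len(classes), len(profile.H), 4))
    for ci, c in enumerate(classes):
        sub = [s for s, lab in zip(sequences, labels) if lab == c]
        class_freqs[ci] = entropy_profile(sub).freqs
    S = class_freqs * profile.H[None, :, None]
    return ClassLogo(S=S, class_freqs=class_freqs, classes=list(classes), H=profile.H)


def smooth_attention(vector: np.ndarray, window: int = 9) -> np.ndarray:
    """Centred moving average; the window truncates at the edges.

    Output length equals input length: position ``i`` is the mean over
    positions ``i-(w-1)/2 .. i+(w-1)/2`` intersected with the vector.
    """
    v = np.asarray(vector, dtype=float)
    if window % 2 == 0:
        raise ValueError("smoothing window must be odd")
    if window > v.shape[-1]:
        raise ValueError("smoothing window exceeds the vector length")
    half = window // 2
    csum = np.concatenate([[0.0], np.cumsum(v, axis=-1)])
    length = v.shape[-1]
    lo = np.maximum(np.arange(length) - half, 0)
    hi = np.minimum(np.arange(length) + half + 1, length)
    return (csum[hi] - csum[lo]) / (hi - lo)


def mean_attention(
    attention_vectors: np.ndarray | Sequence[np.ndarray],
    labels: Sequence[str],
    grouping: str = "predicted_label",
    window: int = 9,
    classes: Sequence[str] | None = None,
) -> AttentionSummary:
    """Class-wise arithmetic-mean attention, raw and window-smoothed.

    ``labels`` should already be the grouping key of choice — the predicted
    class label for phenotype models (a read from a mixed community carries
    no true per-read phenotype) or the true label for taxonomic models;
    ``grouping`` records which convention was used.  Classes listed in
    ``classes`` but absent from ``labels`` are omitted with a warning.
    """
    if grouping not in ("predicted_label", "true_label"):
        raise ValueError("grouping must be 'predicted_label' or 'true_label'")
    att = np.asarray(attention_vectors, dtype=float)
    labels = np.asarray(labels)
    if att.shape[0] != labels.shape[0]:
        raise ValueError("attention_vectors and labels lengths differ")
    if classes is None:
        classes = sorted(set(labels))
    kept, rows = [], []
    for c in classes:
        mask = labels == c
        if not mask.any():
            warnings.warn(f"class {c!r} has no reads; omitted", stacklevel=2)
            continue
        kept.append(c)
        rows.append(att[mask].mean(axis=0))
    A = np.asarray(rows)
    smoothed = np.stack([smooth_attention(row, window) for row in A])
    return AttentionSummary(A=A, smoothed=smoothed, classes=kept,
                            grouping=grouping, window=window)


def align_attention(
    aligned_seqs: Mapping[str, str],
    attention_by_id: Mapping[str, np.ndarray],
) -> AlignedAttention:
    """Place per-residue attention values at their alignment columns.

    The attention value of ungapped position ``j`` of a sequence lands at
    the alignment column holding that residue; the sequence's gap columns
    are NaN.  Dropping a row's NaN entries therefore recovers the input
    vector exactly.  ``column_mean`` averages the defined entries per
    column (all-gap columns are NaN).
    """
    ids = [i for i in aligned_seqs if i in attention_by_id]
    if not ids:
        raise ValueError("no shared ids between alignment and attention vectors")
    l_aln = len(next(iter(aligned_seqs.values())))
    rows = np.full((len(ids), l_aln), np.nan)
    for r, sid in enumerate(ids):
        aligned = aligned_seqs[sid]
        att = np.asarray(attention_by_id[sid], dtype=float)
        residue_cols = np.array([i for i, ch in enumerate(aligned) if ch != "-"])
        if len(residue_cols) != len(att):
            raise ValueError(
                f"sequence {sid!r}: ungapped length {len(residue_cols)} != "
                f"attention length {len(att)}"
            )
        rows[r, residue_cols] = att
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        column_mean = np.nanmean(rows, axis=0)
    return AlignedAttention(ids=ids, per_sequence=rows, column_mean=column_mean)


def region_attention(
    attention: np.ndarray | AlignedAttention | AttentionSummary,
    regions: pd.DataFrame,
    group_names: Sequence[str] | None = None,
) -> RegionTable:
    """Sum (mean) attention mass per region, per group.

    ``regions`` uses 1-based inclusive coordinates (name, start, end), the
    convention of published 16S variable-region breakpoint tables; regions
    must not overlap.  ``attention`` may be a single vector, a groups x L
    matrix, an :class:`AttentionSummary` (rows = classes) or an
    :class:`AlignedAttention` (one row, the column mean).
    """
    if isinstance(attention, AttentionSummary):
        mat = attention.A
        group_names = group_names or attention.classes
    elif isinstance(attention, AlignedAttention):
        mat = np.nan_to_num(attention.column_mean)[None, :]
        group_names = group_names or ["mean"]
    else:
        mat = np.atleast_2d(np.asarray(attention, dtype=float))
    if group_names is None:
        group_names = [f"group_{i}" for i in range(mat.shape[0])]
    length = mat.shape[1]
    spans = []
    for _, row in regions.iterrows():
        start, end = int(row["start"]), int(row["end"])
        if not 1 <= start <= end <= length:
            raise ValueError(
                f"region {row['name']!r} [{start}, {end}] outside [1, {length}]"
            )
        spans.append((row["name"], start - 1, end))  # to 0-based half-open
    spans_sorted = sorted(spans, key=lambda s: s[1])
    for (na, sa, ea), (nb, sb, _) in zip(spans_sorted, spans_sorted[1:]):
        if sb < ea:
            raise ValueError(f"regions {na!r} and {nb!r} overlap")
    sums = np.stack([[mat[g, s:e].sum() for _, s, e in spans]
                     for g in range(mat.shape[0])])
    return RegionTable(
        regions=regions.reset_index(drop=True),
        attention_sums=pd.DataFrame(
            sums, index=list(group_names), columns=[n for n, _, _ in spans]
        ),
    )
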