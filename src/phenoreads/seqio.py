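"""Sequence and metadata I/O, one-hot encoding, trimming and length bucketing.

Reads are represented as plain nucleotide strings over the IUPAC alphabet and
encoded as ``T x 4`` float matrices on the fixed channel order ``A, C, G, T``.
A fully specified base maps to a unit vector; an ambiguity code maps to the
uniform distribution over its compatible bases (``N`` -> 0.25 everywhere);
positions beyond the end of a short read are all-zero padding rows, the
convention used for right-padding variable-length amplicons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: fixed channel order for every encoded matrix and every logo downstream
BASES = "ACGT"

#: IUPAC nucleotide codes -> compatible unambiguous bases (RNA ``U`` folded into T)
IUPAC_CODES: Mapping[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

# one row per IUPAC code, precomputed once
_CODE_ROWS: dict[str, np.ndarray] = {}
for _code, _bases in IUPAC_CODES.items():
    _row = np.zeros(4)
    for _b in _bases:
        _row[BASES.index(_b)] = 1.0 / len(_bases)
    _CODE_ROWS[_code] = _row


@dataclass(frozen=True)
class ReadRecord:
    """A single amplicon read with its sample of origin."""

    read_id: str
    sequence: str
    sample_id: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"read {self.read_id!r}: empty sequence")


def one_hot_encode(sequence: str, target_length: int | None = None) -> np.ndarray:
    """Encode ``sequence`` as a ``target_length x 4`` matrix (channels A,C,G,T).

    Positions past the end of the sequence are zero rows (right padding).
    Ambiguity codes become the uniform distribution over their compatible
    bases; lowercase is accepted; ``U`` is treated as ``T``.

    Raises
    ------
    ValueError
        If a character is not an IUPAC nucleotide code (the position is
        reported 1-based) or the sequence is longer than ``target_length``.
    """
    if target_length is None:
        target_length = len(sequence)
    if target_length < 1:
        raise ValueError("target_length must be >= 1")
    if len(sequence) > target_length:
        raise ValueError(
            f"sequence length {len(sequence)} exceeds target_length {target_length}"
        )
    out = np.zeros((target_length, 4))
    for i, ch in enumerate(sequence.upper()):
        row = _CODE_ROWS.get(ch)
        if row is None:
            raise ValueError(
                f"non-IUPAC character {ch!r} at position {i + 1}"
            )
        out[i] = row
    return out


def decode_onehot(matrix: np.ndarray) -> str:
    """Inverse of :func:`one_hot_encode` for unambiguous, unpadded rows."""
    seq = []
    for row in matrix:
        if row.sum() == 0:
            break
        seq.append(BASES[int(np.argmax(row))])
    return "".join(seq)


def trim_read(sequence: str, offset: int, length: int) -> str:
    """Return ``sequence[offset:offset + length]`` (0-based, half-open).

    A remainder shorter than ``length`` is returned as-is; zero padding is
    deferred to :func:`one_hot_encode`.  ``offset`` must leave at least one
    base.
    """
    if offset < 0:
        raise ValueError("offset must be non-negative")
    if length < 1:
        raise ValueError("length must be positive")
    if offset >= len(sequence):
        raise ValueError(
            f"offset {offset} is beyond the sequence end (length {len(sequence)})"
        )
    return sequence[offset: offset + length]


def bucket_length(length: int, bucket_size: int = 100) -> int:
    """Smallest multiple of ``bucket_size`` that is >= ``length``."""
    if bucket_size < 1:
        raise ValueError("bucket_size must be >= 1")
    return -(-length // bucket_size) * bucket_size


def bucket_by_length(
    sequences: Sequence[str], bucket_size: int = 100
) -> dict[int, tuple[list[int], np.ndarray]]:
    """Group sequences into padded-length buckets and encode each bucket.

    Each sequence is assigned to the smallest multiple of ``bucket_size``
    at or above its length and right-padded with zero rows to that length,
    e.g. a 1001-base sequence lands in the 1100 bucket with 99 padding rows.

    Returns a mapping ``bucket_length -> (original indices, n x L x 4 batch)``.
    """
    groups: dict[int, list[int]] = {}
    for i, seq in enumerate(sequences):
        groups.setdefault(bucket_length(len(seq), bucket_size), []).append(i)
    out: dict[int, tuple[list[int], np.ndarray]] = {}
    for blen in sorted(groups):
        idx = groups[blen]
        batch = np.stack([one_hot_encode(sequences[i], blen) for i in idx])
        out[blen] = (idx, batch)
    return out


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Load the sample metadata TSV (``sample_id<TAB>label<TAB>split``)."""
    meta = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "label", "split"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"metadata is missing columns: {sorted(missing)}")
    dup = meta["sample_id"][meta["sample_id"].duplicated()]
    if not dup.empty:
        raise ValueError(f"duplicate sample ids in metadata: {sorted(set(dup))}")
    bad = set(meta["split"]) - {"train", "test"}
    if bad:
        raise ValueError(f"unknown split values: {sorted(bad)}")
    return meta.reset_index(drop=True)


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t", index=False)


def _sniff_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in {".fq", ".fastq"}:
        return "fastq"
    if suffix in {".fa", ".fasta", ".fna"}:
        return "fasta"
    with open(path) as fh:
        first = fh.read(1)
    return "fastq" if first == "@" else "fasta"


def load_dataset(
    read_files: Iterable[str | Path],
    metadata: str | Path | pd.DataFrame,
    sample_ids: Sequence[str] | None = None,
) -> tuple[list[ReadRecord], pd.DataFrame]:
    """Load reads from FASTA/FASTQ files plus the sample metadata table.

    Each file holds the reads of one sample; the sample id defaults to the
    file stem but can be given explicitly via ``sample_ids`` (aligned with
    ``read_files``).  FASTQ qualities are parsed and discarded.  Record order
    is deterministic: files in the given order, reads in file order.
    """
    meta = metadata if isinstance(metadata, pd.DataFrame) else read_metadata(metadata)
    known = set(meta["sample_id"])
    files = [Path(p) for p in read_files]
    if sample_ids is None:
        sample_ids = [p.stem for p in files]
    elif len(sample_ids) != len(files):
        raise ValueError("sample_ids and read_files lengths differ")
    records: list[ReadRecord] = []
    for path, sid in zip(files, sample_ids):
        if sid not in known:
            raise ValueError(f"sample {sid!r} (file {path.name}) not in metadata")
        n = 0
        for rec in SeqIO.parse(str(path), _sniff_format(path)):
            records.append(ReadRecord(rec.id, str(rec.seq).upper(), sid))
            n += 1
        logger.info("loaded %d reads for sample %s from %s", n, sid, path.name)
    return records, meta


def read_regions(path: str | Path) -> pd.DataFrame:
    """Load a variable-region breakpoint table (``name<TAB>start<TAB>end``).

    Coordinates in the file are 1-based inclusive, as in published 16S
    variable-region tables; they are kept that way in the returned frame.
    """
    regions = pd.read_csv(path, sep="\t", dtype={"name": str})
    required = {"name", "start", "end"}
    if missing := required - set(regions.columns):
        raise ValueError(f"region table is missing columns: {sorted(missing)}")
    return regions


def read_alignment(path: str | Path) -> dict[str, str]:
    """Load an aligned FASTA (gap character ``-``) as id -> aligned row."""
    aln = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    lengths = {len(s) for s in aln.values()}
    if len(lengths) > 1:
        raise ValueError("alignment rows have differing lengths")
    return aln
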