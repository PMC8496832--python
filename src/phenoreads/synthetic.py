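"""Synthetic amplicon datasets with known class-discriminative loci.

The generator emulates the statistical structure a read-level phenotype
classifier is asked to exploit: several *genera* (reference clusters) whose
backbone sequences are shared across phenotype classes, except inside
*planted windows* where each class carries its own base assignment; samples
draw reads from genus references according to a per-class genus mixture,
with i.i.d. per-base substitution noise and optional single-base indels.
Because the planted loci, references and per-read genus draws are all
recorded, expected entropy profiles and separability are known exactly,
which makes every downstream module testable without external data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path


import numpy as np
import pandas as pd

from .seqio import BASES, ReadRecord

_BASE_IDX = {b: i for i, b in enumerate(BASES)}


@dataclass(frozen=True)
class PlantedWindow:
    """A class-discriminative locus: [start, end) with per-class bases."""

    start: int
    end: int
    assignments: dict[str, str]  # class name -> bases of length end-start

    def __post_init__(self) -> None:
        width = self.end - self.start
        if width < 1 or self.start < 0:
            raise ValueError("window must satisfy 0 <= start < end")
        for cls, bases in self.assignments.items():
            if len(bases) != width:
                raise ValueError(
                    f"window assignment for class {cls!r} has length "
                    f"{len(bases)}, expected {width}"
                )


@dataclass
class SyntheticSpec:
    """Ground-truth description of a simulated multi-sample dataset.

    Defaults are desk-scale study conditions: 3 classes, 5 genera,
    100-base reads, 10 samples per class per split, 500 reads per sample,
    one 10-base planted window, 1% per-base substitution noise, no indels.
    """

    n_classes: int = 3
    n_genera: int = 5
    read_length: int = 100
    planted_windows: list[PlantedWindow] | None = None
    substitution_rate: float = 0.01
    indel_rate: float = 0.0
    reads_per_sample: int = 500
    samples_per_class: int = 10
    class_genus_mixture: np.ndarray | None = None
    seed: int = 0
    class_names: list[str] = field(default_factory=list)
    genus_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_classes < 2 or self.n_genera < 1:
            raise ValueError("need n_classes >= 2 and n_genera >= 1")
        if not 0.0 <= self.substitution_rate <= 0.5:
            raise ValueError("substitution_rate must be in [0, 0.5]")
        if not 0.0 <= self.indel_rate <= 0.5:
            raise ValueError("indel_rate must be in [0, 0.5]")
        if not self.class_names:
            self.class_names = [f"class_{i}" for i in range(self.n_classes)]
        if not self.genus_names:
            self.genus_names = [f"genus_{i}" for i in range(self.n_genera)]
        if self.class_genus_mixture is None:
            self.class_genus_mixture = np.full(
                (self.n_classes, self.n_genera), 1.0 / self.n_genera
            )
        mix = np.asarray(self.class_genus_mixture, dtype=float)
        if mix.shape != (self.n_classes, self.n_genera):
            raise ValueError("class_genus_mixture must be n_classes x n_genera")
        if not np.allclose(mix.sum(axis=1), 1.0):
            raise ValueError("class_genus_mixture rows must sum to 1")
        self.class_genus_mixture = mix
        if self.planted_windows is None:
            self.planted_windows = [default_window(self)]
        spans = sorted((w.start, w.end) for w in self.planted_windows)
        for (s1, e1), (s2, _) in zip(spans, spans[1:]):
            if s2 < e1:
                raise ValueError("planted windows overlap (conflicting assignments)")
        for w in self.planted_windows:
            if w.end > self.read_length:
                raise ValueError("planted window extends past the read length")
            if set(w.assignments) != set(self.class_names):
                raise ValueError("window assignments must cover every class")


def default_window(spec: SyntheticSpec, start: int | None = None,
                   width: int = 10) -> PlantedWindow:
    """A centred planted window with distinct per-class bases per position.

    For the default 100-base reads this is positions 46–55 (1-based).
    """
    width = min(width, spec.read_length)
    if start is None:
        start = (spec.read_length - width) // 2
    rng = np.random.default_rng(spec.seed + 1)
    assign = {c: [] for c in spec.class_names}
    for _ in range(width):
        perm = rng.permutation(4)
        for i, c in enumerate(spec.class_names):
            assign[c].append(BASES[perm[i % 4]])
    return PlantedWindow(start, start + width,
                         {c: "".join(v) for c, v in assign.items()})


@dataclass
class SyntheticDataset:
    """Generated reads plus the full ground truth."""

    spec: SyntheticSpec
    references: dict[str, dict[str, str]]  # genus -> class -> sequence
    records: list[ReadRecord]
    metadata: pd.DataFrame                 # sample_id, label, split
    truth: pd.DataFrame                    # read_id, sample_id, genus, class, mutations

    def records_for_split(self, split: str) -> list[ReadRecord]:
        keep = set(self.metadata.loc[self.metadata["split"] == split, "sample_id"])
        return [r for r in self.records if r.sample_id in keep]


def generate_references(spec: SyntheticSpec) -> dict[str, dict[str, str]]:
    """Per-genus backbones, shared across classes except at planted windows."""
    rng = np.random.default_rng(spec.seed)
    refs: dict[str, dict[str, str]] = {}
    for genus in spec.genus_names:
        backbone = rng.integers(0, 4, size=spec.read_length)
        refs[genus] = {}
        for cls in spec.class_names:
            seq = backbone.copy()
            for w in spec.planted_windows:
                seq[w.start: w.end] = [_BASE_IDX[b] for b in w.assignments[cls]]
            refs[genus][cls] = "".join(BASES[i] for i in seq)
    return refs


def _mutate(seq: str, spec: SyntheticSpec, rng: np.random.Generator) -> tuple[str, list[int]]:
    """Apply i.i.d. substitutions, then optional single-base indels.

    Substitutions draw uniformly from the 3 alternative bases.  Indels are
    single-base (deletion or insertion with equal odds per event); the read
    is re-trimmed or padded with random bases back to the reference length,
    mimicking a sequencer that keeps reading to a fixed cycle count.
    """
    codes = np.array([_BASE_IDX[b] for b in seq])
    sub_pos = np.where(rng.random(len(codes)) < spec.substitution_rate)[0]
    for p in sub_pos:
        codes[p] = (codes[p] + rng.integers(1, 4)) % 4
    if spec.indel_rate > 0.0:
        out: list[int] = []
        for c in codes:
            r = rng.random()
            if r < spec.indel_rate / 2.0:
                continue  # deletion
            if r < spec.indel_rate:
                out.append(int(rng.integers(0, 4)))  # insertion before the base
            out.append(int(c))
        codes = np.array(out[: len(seq)])
        if len(codes) < len(seq):
            codes = np.concatenate(
                [codes, rng.integers(0, 4, size=len(seq) - len(codes))]
            )
    return "".join(BASES[i] for i in codes), sub_pos.tolist()


def generate_samples(spec: SyntheticSpec, outdir: str | Path | None = None) -> SyntheticDataset:
    """Draw the full dataset: train and test splits, FASTA-ready records.

    Each class gets ``samples_per_class`` samples in each split; each sample
    draws ``reads_per_sample`` reads (genus by the class's mixture row, then
    the class-specific reference with noise).  With ``outdir`` set, one
    FASTA per sample plus ``metadata.tsv`` and ``truth.tsv`` are written.
    """
    refs = generate_references(spec)
    rng = np.random.default_rng(spec.seed + 2)
    records: list[ReadRecord] = []
    meta_rows: list[dict] = []
    truth_rows: list[dict] = []
    for split in ("train", "test"):
        for ci, cls in enumerate(spec.class_names):
            for s in range(spec.samples_per_class):
                sid = f"{split}_{cls}_s{s:02d}"
                meta_rows.append({"sample_id": sid, "label": cls, "split": split})
                genera = rng.choice(
                    spec.n_genera, size=spec.reads_per_sample,
                    p=spec.class_genus_mixture[ci],
                )
                for j, gi in enumerate(genera):
                    genus = spec.genus_names[int(gi)]
                    seq, subs = _mutate(refs[genus][cls], spec, rng)
                    rid = f"{sid}_r{j:04d}"
                    records.append(ReadRecord(rid, seq, sid))
                    truth_rows.append(
                        {"read_id": rid, "sample_id": sid, "genus": genus,
                         "class": cls,
                         "mutations": ";".join(map(str, subs))}
                    )
    metadata = pd.DataFrame(meta_rows)
    truth = pd.DataFrame(truth_rows)
    dataset = SyntheticDataset(spec, refs, records, metadata, truth)
    if outdir is not None:
        write_dataset(dataset, outdir)
    return dataset


def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> list[Path]:
    """Write one FASTA per sample, metadata.tsv, truth.tsv and a manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    by_sample: dict[str, list[ReadRecord]] = {}
    for rec in dataset.records:
        by_sample.setdefault(rec.sample_id, []).append(rec)
    fasta_paths = []
    for sid in dataset.metadata["sample_id"]:
        path = outdir / f"{sid}.fasta"
        with open(path, "w") as fh:
            for rec in by_sample.get(sid, []):
                fh.write(f">{rec.read_id}\n{rec.sequence}\n")
        fasta_paths.append(path)
    dataset.metadata.to_csv(outdir / "metadata.tsv", sep="\t", index=False)
    dataset.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    spec = dataset.spec
    manifest = {
        "n_classes": spec.n_classes,
        "class_names": spec.class_names,
        "n_genera": spec.n_genera,
        "read_length": spec.read_length,
        "planted_windows": [
            {"start": w.start, "end": w.end, "assignments": w.assignments}
            for w in spec.planted_windows
        ],
        "substitution_rate": spec.substitution_rate,
        "indel_rate": spec.indel_rate,
        "reads_per_sample": spec.reads_per_sample,
        "samples_per_class": spec.samples_per_class,
        "seed": spec.seed,
        "n_reads": len(dataset.records),
        "fasta_files": [p.name for p in fasta_paths],
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return fasta_paths


def analytic_entropy(dataset: SyntheticDataset, split: str | None = None) -> np.ndarray:
    """Exact noiseless entropy profile implied by the ground truth.

    Counts each read's reference base per position from the recorded
    (genus, class) draws — valid only at substitution_rate 0, where every
    read equals its reference.
    """
    truth = dataset.truth
    if split is not None:
        keep = set(
            dataset.metadata.loc[dataset.metadata["split"] == split, "sample_id"]
        )
        truth = truth[truth["sample_id"].isin(keep)]
    length = dataset.spec.read_length
    counts = np.zeros((length, 4))
    pair_counts = truth.groupby(["genus", "class"]).size()
    for (genus, cls), n in pair_counts.items():
        ref = dataset.references[genus][cls]
        for i, b in enumerate(ref):
            counts[i, _BASE_IDX[b]] += n
    freqs = counts / counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        plogp = np.where(freqs > 0, freqs * np.log2(freqs), 0.0)
    return -plogp.sum(axis=1)
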