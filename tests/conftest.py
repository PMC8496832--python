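"""Shared fixtures: synthetic datasets and (expensively) trained models.

The planted-signal dataset and the two trained models (normal and
label-shuffled control) are session-scoped because training the network on
the full desk-scale dataset takes minutes; every test that needs a trained
model shares them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

from phenoreads.model import Hyperparams, ReadPhenotypeModel, ReadPhenotypeResults
from phenoreads.seqio import one_hot_encode
from phenoreads.synthetic import SyntheticDataset, SyntheticSpec, generate_samples

SEED = 1


@dataclass
class TrainedRun:
    """A trained model plus its train/test predictions and labels."""

    dataset: SyntheticDataset
    results: ReadPhenotypeResults
    train_records: list
    test_records: list
    train_outputs: list
    test_outputs: list
    y_train_true: list[str]
    y_test_true: list[str]
    y_test_pred: list[str]
    rf_train_labels: dict[str, str]  # sample labels the RF stage should use


def _predict_split(results, records):
    return results.predict_reads(records)


def _run(dataset: SyntheticDataset, hp: Hyperparams, read_labels=None,
         rf_labels=None) -> TrainedRun:
    train_records = dataset.records_for_split("train")
    test_records = dataset.records_for_split("test")
    labels = dict(zip(dataset.metadata["sample_id"], dataset.metadata["label"]))
    model = ReadPhenotypeModel.from_records(train_records, dataset.metadata, hp)
    if read_labels is not None:  # label-shuffled control
        class_index = {c: i for i, c in enumerate(model.class_names)}
        model._y = np.array([class_index[c] for c in read_labels])
    results = model.fit()
    train_outputs = _predict_split(results, train_records)
    test_outputs = _predict_split(results, test_records)
    y_test_true = [labels[r.sample_id] for r in test_records]
    y_test_pred = [results.class_names[o.predicted_index] for o in test_outputs]
    return TrainedRun(
        dataset=dataset,
        results=results,
        train_records=train_records,
        test_records=test_records,
        train_outputs=train_outputs,
        test_outputs=test_outputs,
        y_train_true=[labels[r.sample_id] for r in train_records],
        y_test_true=y_test_true,
        y_test_pred=y_test_pred,
        rf_train_labels=rf_labels or labels,
    )


@pytest.fixture(scope="session")
def planted_dataset() -> SyntheticDataset:
    """Default study conditions: 3 classes x 10 samples x 500 reads per
    split, 100-base reads differing only inside one 10-base window."""
    return generate_samples(SyntheticSpec(seed=SEED))


@pytest.fixture(scope="session")
def small_hp() -> Hyperparams:
    """The small desk-scale architecture: 64 conv channels, 32 hidden units,
    5 epochs."""
    return Hyperparams(conv_channels=64, hidden_units=32, epochs=5, seed=SEED)


@pytest.fixture(scope="session")
def planted_run(planted_dataset, small_hp) -> TrainedRun:
    return _run(planted_dataset, small_hp)


@pytest.fixture(scope="session")
def shuffled_run(planted_dataset, small_hp) -> TrainedRun:
    """Label-shuffled control: i.i.d. random read labels for network
    training and permuted sample labels for the downstream classifiers."""
    rng = np.random.default_rng(SEED + 1000)
    spec = planted_dataset.spec
    train_records = planted_dataset.records_for_split("train")
    read_labels = rng.choice(spec.class_names, size=len(train_records))
    meta = planted_dataset.metadata
    train_meta = meta[meta["split"] == "train"]
    permuted = rng.permutation(train_meta["label"].to_numpy())
    rf_labels = dict(zip(meta["sample_id"], meta["label"]))
    rf_labels.update(dict(zip(train_meta["sample_id"], permuted)))
    return _run(planted_dataset, small_hp, read_labels=read_labels,
                rf_labels=rf_labels)


@pytest.fixture(scope="session")
def tiny_dataset() -> SyntheticDataset:
    """A seconds-scale dataset for unit tests of the training loop."""
    return generate_samples(
        SyntheticSpec(
            n_classes=2, n_genera=2, read_length=30, reads_per_sample=40,
            samples_per_class=3, substitution_rate=0.0, seed=7,
            planted_windows=None,
        )
    )


@pytest.fixture
def tiny_hp() -> Hyperparams:
    # small batches and a higher learning rate so the seconds-scale
    # datasets converge within a few epochs
    return Hyperparams(
        conv_window=5, conv_channels=8, hidden_units=8, attention_units=4,
        epochs=4, batch_size=32, learning_rate=0.01, seed=7,
    )


def encode_records(records, length=None):
    t = length or max(len(r.sequence) for r in records)
    return np.stack([one_hot_encode(r.sequence, t) for r in records])
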