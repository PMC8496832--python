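"""Read-level phenotype classifier: model specification, fitting, results.

The public surface follows the Model/Results convention of statistical
modelling packages: :class:`ReadPhenotypeModel` holds the encoded reads and
hyperparameters, ``fit()`` trains the network and returns a
:class:`ReadPhenotypeResults` carrying the learned weights, the per-epoch
training log and prediction/interpretation accessors.

The classifier itself maps a one-hot read (``T x 4``) through convolutional
blocks, a bidirectional LSTM, a soft-attention layer and a dense softmax.
Its two intermediate outputs — the per-position attention weights and the
attention-weighted read embedding — are first-class results here, since the
interpretation and sample-aggregation machinery is built on them.
"""

from __future__ import annotations

import io
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ._nn import Adam, ReadNet
from . import seqio

logger = logging.getLogger(__name__)


@dataclass
class Hyperparams:
    """Architecture and optimisation settings.

    Defaults follow the configuration selected by cross-validation for
    read-level 16S phenotype prediction: convolution window 9 (the k-mer
    size at which naive-Bayes taxonomic classifiers saturate), 256
    convolution channels, 64 Bi-LSTM hidden units, 16 attention hidden
    units, no dropout, Adam at learning rate 0.001 for 10 epochs.
    """

    conv_window: int = 9
    n_conv_blocks: int = 2
    conv_channels: int = 256
    hidden_units: int = 64
    attention_units: int = 16
    dropout: float = 0.0
    learning_rate: float = 0.001
    epochs: int = 10
    batch_size: int = 512
    seed: int = 0
    dtype: str = "float32"

    def __post_init__(self) -> None:
        if self.conv_window % 2 == 0 or self.conv_window < 1:
            raise ValueError("conv_window must be odd and positive")
        if self.hidden_units % 2:
            raise ValueError("hidden_units must be even")
        for name in ("n_conv_blocks", "conv_channels", "hidden_units",
                     "attention_units", "batch_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")


@dataclass
class AttentionOutput:
    """Per-read network outputs exposed for interpretation.

    ``attention`` is the softmax-normalised positional importance vector
    (length T, sums to 1); ``embedding`` is the attention-weighted sum of
    the Bi-LSTM ``hidden_states`` (T x N_h); ``scores`` are the class
    probabilities (length N_y, sums to 1).
    """

    attention: np.ndarray
    embedding: np.ndarray
    scores: np.ndarray
    hidden_states: np.ndarray
    read_id: str | None = None
    sample_id: str | None = None

    @property
    def predicted_index(self) -> int:
        return int(np.argmax(self.scores))


class ReadPhenotypeModel:
    """Model specification: encoded reads, labels and hyperparameters.

    Parameters
    ----------
    X : B x T x 4 array, or list of per-read one-hot matrices of varying
        length (variable-length mode: reads are grouped into padded-length
        buckets and trained bucket by bucket).
    y : length-B integer label indices into ``class_names``.
    class_names : ordered phenotype labels; the order is fixed here and
        serialised with the fitted results.
    """

    def __init__(
        self,
        X: np.ndarray | Sequence[np.ndarray],
        y: Sequence[int],
        class_names: Sequence[str],
        hyperparams: Hyperparams | None = None,
    ) -> None:
        self.hyperparams = hyperparams or Hyperparams()
        self.class_names = list(class_names)
        y = np.asarray(y, dtype=np.int64)
        if isinstance(X, np.ndarray):
            if X.ndim != 3 or X.shape[2] != 4:
                raise ValueError("X must be B x T x 4")
            buckets = {X.shape[1]: (np.arange(len(X)), X)}
        else:
            lengths = {m.shape[0] for m in X}
            buckets = {}
            for length in sorted(lengths):
                idx = np.array([i for i, m in enumerate(X) if m.shape[0] == length])
                buckets[length] = (idx, np.stack([X[i] for i in idx]))
        self._buckets = buckets
        self._y = y
        self.n_reads = int(y.shape[0])
        self.n_classes = len(self.class_names)
        self.read_length = max(buckets)
        if self.read_length < self.hyperparams.conv_window:
            raise ValueError(
                f"read length {self.read_length} is smaller than the "
                f"convolution window {self.hyperparams.conv_window}"
            )
        if sum(len(i) for i, _ in buckets.values()) != self.n_reads:
            raise ValueError("X and y lengths differ")

    @classmethod
    def from_records(
        cls,
        records: Sequence[seqio.ReadRecord],
        metadata: pd.DataFrame,
        hyperparams: Hyperparams | None = None,
        class_names: Sequence[str] | None = None,
        bucket_size: int | None = None,
    ) -> "ReadPhenotypeModel":
        """Build the model from raw reads plus the sample metadata table.

        Each read inherits the phenotype label of its sample.  With
        ``bucket_size`` set, reads are padded to the nearest multiple
        (variable-length mode); otherwise all reads are padded to the
        longest read.
        """
        labels = dict(zip(metadata["sample_id"], metadata["label"]))
        if class_names is None:
            class_names = sorted(set(labels.values()))
        class_index = {c: i for i, c in enumerate(class_names)}
        y = np.array([class_index[labels[r.sample_id]] for r in records])
        if bucket_size:
            mats = [
                seqio.one_hot_encode(
                    r.sequence, seqio.bucket_length(len(r.sequence), bucket_size)
                )
                for r in records
            ]
            return cls(mats, y, class_names, hyperparams)
        t = max(len(r.sequence) for r in records)
        X = np.stack([seqio.one_hot_encode(r.sequence, t) for r in records])
        return cls(X, y, class_names, hyperparams)

    def _build_net(self, rng: np.random.Generator) -> ReadNet:
        hp = self.hyperparams
        return ReadNet(
            window=hp.conv_window,
            n_conv_blocks=hp.n_conv_blocks,
            conv_channels=hp.conv_channels,
            hidden_units=hp.hidden_units,
            attention_units=hp.attention_units,
            n_classes=self.n_classes,
            dropout=hp.dropout,
            dtype=hp.dtype,
            rng=rng,
        )

    @property
    def loss_name(self) -> str:
        # softmax cross-entropy over two classes coincides with binary
        # cross-entropy; the log records which regime applies
        return "binary cross-entropy" if self.n_classes == 2 else "categorical cross-entropy"

    def fit(self, epochs: int | None = None) -> "ReadPhenotypeResults":
        """Train for ``epochs`` passes (default from hyperparams) with Adam.

        Reads are shuffled each epoch with the configured seed; in
        variable-length mode batches are drawn within length buckets and the
        batch order is shuffled across buckets.  ``epochs=0`` returns an
        untrained (freshly initialised) network with an empty log.
        """
        if len(np.unique(self._y)) < 2:
            raise ValueError("training reads must span at least 2 classes")
        hp = self.hyperparams
        if epochs is None:
            epochs = hp.epochs
        rng = np.random.default_rng(hp.seed)
        net = self._build_net(rng)
        optimiser = Adam(net.params, lr=hp.learning_rate)
        log: list[dict] = []
        for epoch in range(epochs):
            batches = []
            for length, (idx, xb) in self._buckets.items():
                perm = rng.permutation(len(idx))
                for s in range(0, len(idx), hp.batch_size):
                    batches.append((length, perm[s: s + hp.batch_size]))
            order = rng.permutation(len(batches))
            total_loss = 0.0
            total_correct = 0
            for bi in order:
                length, rows = batches[bi]
                idx, xb = self._buckets[length]
                yb = self._y[idx[rows]]
                cache = net.forward(xb[rows], train=True, rng=rng)
                total_loss += net.loss(cache["probs"], yb) * len(rows)
                total_correct += int((cache["probs"].argmax(axis=1) == yb).sum())
                grads = net.backward(cache, yb)
                optimiser.step(net.params, grads)
            log.append(
                {
                    "epoch": epoch + 1,
                    "loss": total_loss / self.n_reads,
                    "accuracy": total_correct / self.n_reads,
                    "loss_name": self.loss_name,
                }
            )
            logger.info(
                "epoch %d/%d: loss %.4f, accuracy %.4f",
                epoch + 1, epochs, log[-1]["loss"], log[-1]["accuracy"],
            )
        return ReadPhenotypeResults(net, self.class_names, hp, pd.DataFrame(
            log, columns=["epoch", "loss", "accuracy", "loss_name"]
        ), model=self)


class ReadPhenotypeResults:
    """Fitted read classifier: learned weights plus prediction accessors."""

    def __init__(
        self,
        net: ReadNet,
        class_names: Sequence[str],
        hyperparams: Hyperparams,
        training_log: pd.DataFrame,
        model: ReadPhenotypeModel | None = None,
    ) -> None:
        self.net = net
        self.class_names = list(class_names)
        self.hyperparams = hyperparams
        self.training_log = training_log
        self.model = model

    # ------------------------------------------------------------- prediction

    def _forward_batches(self, X: np.ndarray) -> dict:
        """Eval-mode forward over ``X`` in batches; concatenated outputs."""
        bs = self.hyperparams.batch_size
        outs = {"alpha": [], "embedding": [], "probs": [], "hidden": []}
        for s in range(0, len(X), bs):
            cache = self.net.forward(X[s: s + bs], train=False)
            outs["alpha"].append(cache["alpha"])
            outs["embedding"].append(cache["embedding"])
            outs["probs"].append(cache["probs"])
            outs["hidden"].append(cache["hidden"])
        return {k: np.concatenate(v) for k, v in outs.items()}

    def predict_reads(
        self,
        X: np.ndarray | Sequence[np.ndarray] | Sequence[seqio.ReadRecord],
        strict_length: bool = True,
    ) -> list[AttentionOutput]:
        """Per-read attention, embedding and class scores, in input order.

        Accepts a ``B x T x 4`` array, a list of per-read matrices, or raw
        :class:`~phenoreads.seqio.ReadRecord` objects (encoded here).  With
        ``strict_length`` (single-length mode), the read length must match
        the length the model was fitted on.
        """
        ids: list[tuple[str | None, str | None]]
        if len(X) and isinstance(X[0], seqio.ReadRecord):
            ids = [(r.read_id, r.sample_id) for r in X]
            t = max(len(r.sequence) for r in X)
            X = np.stack([seqio.one_hot_encode(r.sequence, t) for r in X])
        else:
            ids = [(None, None)] * len(X)
        if isinstance(X, np.ndarray):
            mats_by_len = {X.shape[1]: (np.arange(len(X)), X)}
        else:
            mats_by_len = {}
            for length in sorted({m.shape[0] for m in X}):
                idx = np.array([i for i, m in enumerate(X) if m.shape[0] == length])
                mats_by_len[length] = (idx, np.stack([X[i] for i in idx]))
        if strict_length and self.model is not None and len(self.model._buckets) == 1:
            t_train = self.model.read_length
            bad = [length for length in mats_by_len if length != t_train]
            if bad:
                raise ValueError(
                    f"read length(s) {bad} do not match the fitted length "
                    f"{t_train}; pass strict_length=False for bucketed input"
                )
        results: list[AttentionOutput | None] = [None] * len(ids)
        for _, (idx, xb) in mats_by_len.items():
            out = self._forward_batches(xb)
            for j, i in enumerate(idx):
                results[i] = AttentionOutput(
                    attention=out["alpha"][j],
                    embedding=out["embedding"][j],
                    scores=out["probs"][j],
                    hidden_states=out["hidden"][j],
                    read_id=ids[i][0],
                    sample_id=ids[i][1],
                )
        return results  # type: ignore[return-value]

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Class-score matrix (B x N_y) for a fixed-length batch."""
        return self._forward_batches(np.asarray(X))["probs"]

    def embed(self, X: np.ndarray) -> np.ndarray:
        """Read-embedding matrix (B x N_h) for a fixed-length batch."""
        return self._forward_batches(np.asarray(X))["embedding"]

    # ---------------------------------------------------------------- reporting

    def summary(self) -> str:
        hp = self.hyperparams
        n_params = sum(v.size for v in self.net.params.values())
        buf = io.StringIO()
        buf.write("Read-level phenotype classifier\n")
        buf.write("=" * 47 + "\n")
        rows = [
            ("classes", ", ".join(self.class_names)),
            ("parameters", f"{n_params:,}"),
            ("conv blocks", f"{hp.n_conv_blocks} (window {hp.conv_window}, "
                            f"{hp.conv_channels} channels)"),
            ("Bi-LSTM units", f"{hp.hidden_units} ({hp.hidden_units // 2}/direction)"),
            ("attention units", str(hp.attention_units)),
            ("dropout", str(hp.dropout)),
            ("optimiser", f"Adam, lr {hp.learning_rate}"),
            ("loss", "binary cross-entropy" if len(self.class_names) == 2
                     else "categorical cross-entropy"),
            ("epochs trained", str(len(self.training_log))),
        ]
        if len(self.training_log):
            last = self.training_log.iloc[-1]
            rows.append(("final train loss", f"{last['loss']:.4f}"))
            rows.append(("final train accuracy", f"{last['accuracy']:.4f}"))
        for k, v in rows:
            buf.write(f"{k:<22}{v}\n")
        return buf.getvalue()

    # -------------------------------------------------------------- persistence

    def save(self, path: str | Path) -> None:
        """Write a self-describing checkpoint (weights + config + log)."""
        net = self.net
        meta = {
            "hyperparams": asdict(self.hyperparams),
            "class_names": self.class_names,
            "n_classes": net.n_classes,
            "training_log": self.training_log.to_dict(orient="records"),
        }
        arrays = {f"param_{k}": v for k, v in net.params.items()}
        arrays.update({f"running_{k}": v for k, v in net.running.items()})
        np.savez(path, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "ReadPhenotypeResults":
        with np.load(path) as data:
            meta = json.loads(bytes(data["meta"]).decode())
            hp = Hyperparams(**meta["hyperparams"])
            net = ReadNet(
                window=hp.conv_window,
                n_conv_blocks=hp.n_conv_blocks,
                conv_channels=hp.conv_channels,
                hidden_units=hp.hidden_units,
                attention_units=hp.attention_units,
                n_classes=meta["n_classes"],
                dropout=hp.dropout,
                dtype=hp.dtype,
                rng=np.random.default_rng(0),
            )
            for k in net.params:
                net.params[k] = data[f"param_{k}"]
            for k in net.running:
                net.running[k] = data[f"running_{k}"]
        log = pd.DataFrame(
            meta["training_log"], columns=["epoch", "loss", "accuracy", "loss_name"]
        )
        return cls(net, meta["class_names"], hp, log)
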