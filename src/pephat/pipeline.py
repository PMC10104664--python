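"""Configuration-driven train / predict / evaluate entry points.

Training runs Adam on the mean CRF negative log-likelihood with gradient
accumulation over mini-batches of sequences, a seeded 10% validation split,
gradient clipping, and per-epoch logging.  Checkpoints store every
parameter tensor plus the run configuration and the loss trace, and load
back to bit-identical predictions.
"""

from __future__ import annotations

import json
import sys
import time
from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .metrics import MetricsReport, evaluate_dataset
from .model import ModelConfig, StructurePredictor
from .seqio import EmbeddingTable, LabeledRecord, PeptideRecord

CHECKPOINT_VERSION = 1


@dataclass
class TrainConfig:
    epochs: int = 30
    batch_size: int = 8
    learning_rate: float = 1e-3
    clip_norm: float = 5.0
    validation_fraction: float = 0.1
    seed: int = 0
    # stop once validation accuracy reaches this level (None = never)
    target_val_acc: float | None = None
    verbose: bool = True


@dataclass
class Checkpoint:
    version: int
    model_config: ModelConfig
    arrays: list[np.ndarray]
    loss_trace: list[float] = field(default_factory=list)
    val_acc_trace: list[float] = field(default_factory=list)

    def save(self, path: str) -> None:
        payload = {f"param_{i:04d}": a for i, a in enumerate(self.arrays)}
        meta = json.dumps({
            "version": self.version,
            "model_config": self.model_config.to_dict(),
            "loss_trace": self.loss_trace,
            "val_acc_trace": self.val_acc_trace,
        })
        with open(path, "wb") as fh:   # keep the exact path (no .npz suffix)
            np.savez(fh, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
                     **payload)

    @classmethod
    def load(cls, path: str) -> "Checkpoint":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            if meta["version"] != CHECKPOINT_VERSION:
                raise ValueError(
                    f"checkpoint version {meta['version']} is not supported "
                    f"(expected {CHECKPOINT_VERSION})"
                )
            keys = sorted(k for k in data.files if k.startswith("param_"))
            arrays = [data[k] for k in keys]
        return cls(version=meta["version"],
                   model_config=ModelConfig.from_dict(meta["model_config"]),
                   arrays=arrays,
                   loss_trace=meta["loss_trace"],
                   val_acc_trace=meta["val_acc_trace"])

    def build_model(self, embedding_table: EmbeddingTable | None = None) -> StructurePredictor:
        model = StructurePredictor(self.model_config, seed=0,
                          embedding_table=embedding_table)
        model.load_state_arrays(self.arrays)
        return model


def _log(msg: str, verbose: bool) -> None:
    if verbose:
        print(msg, file=sys.stderr)


def _split(data: list[LabeledRecord], fraction: float,
           rng: np.random.Generator) -> tuple[list[LabeledRecord], list[LabeledRecord]]:
    idx = rng.permutation(len(data))
    n_val = max(1, int(round(fraction * len(data)))) if len(data) > 1 else 0
    val_idx = set(idx[:n_val].tolist())
    train = [data[i] for i in range(len(data)) if i not in val_idx]
    val = [data[i] for i in sorted(val_idx)]
    return train, val


def train(model_config: ModelConfig, data: list[LabeledRecord],
          train_config: TrainConfig | None = None,
          embedding_table: EmbeddingTable | None = None) -> Checkpoint:
    """Fit a fresh model on `data`; returns the final checkpoint."""
    tc = train_config or TrainConfig()
    if not data:
        raise ValueError("training requires a non-empty dataset")
    model = StructurePredictor(model_config, seed=tc.seed, embedding_table=embedding_table)
    for rec in data:
        model.ss.validate(rec.labels, record_id=rec.id)

    rng = np.random.default_rng(tc.seed)
    train_set, val_set = _split(data, tc.validation_fraction, rng)
    params = model.parameters()
    optimizer = ad.Adam(params, lr=tc.learning_rate)
    loss_trace: list[float] = []
    val_acc_trace: list[float] = []

    for epoch in range(tc.epochs):
        t0 = time.time()
        order = rng.permutation(len(train_set))
        epoch_loss = 0.0
        for b0 in range(0, len(order), tc.batch_size):
            batch = [train_set[i] for i in order[b0:b0 + tc.batch_size]]
            optimizer.zero_grad()
            batch_loss = 0.0
            for rec in batch:
                labels = model.ss.encode(rec.labels)
                loss = model.loss(rec, labels)
                value = float(loss)
                if not np.isfinite(value):
                    raise RuntimeError(
                        f"non-finite loss at epoch {epoch}, batch starting at "
                        f"index {b0} (record {rec.id!r})"
                    )
                # average over sequences in the batch
                loss.backward(np.asarray(1.0 / len(batch)))
                batch_loss += value
            ad.clip_grad_norm(params, tc.clip_norm)
            optimizer.step()
            epoch_loss += batch_loss
        mean_loss = epoch_loss / max(1, len(train_set))
        loss_trace.append(mean_loss)
        val_acc = _accuracy(model, val_set) if val_set else float("nan")
        val_acc_trace.append(val_acc)
        _log(f"epoch {epoch + 1}/{tc.epochs}  loss {mean_loss:.4f}  "
             f"val_acc {val_acc:.2f}%  ({time.time() - t0:.1f}s)", tc.verbose)
        if (tc.target_val_acc is not None and val_set
                and val_acc >= tc.target_val_acc):
            _log(f"validation accuracy target reached at epoch {epoch + 1}",
                 tc.verbose)
            break

    return Checkpoint(version=CHECKPOINT_VERSION, model_config=model_config,
                      arrays=model.state_arrays(), loss_trace=loss_trace,
                      val_acc_trace=val_acc_trace)


def _accuracy(model: StructurePredictor, records: list[LabeledRecord]) -> float:
    correct = total = 0
    for rec in records:
        pred = model.predict_labels(PeptideRecord(rec.id, rec.sequence))
        correct += sum(a == b for a, b in zip(rec.labels, pred))
        total += len(rec.labels)
    return 100.0 * correct / total if total else 0.0


def predict(checkpoint: Checkpoint, records: list[PeptideRecord],
            embedding_table: EmbeddingTable | None = None) -> list[LabeledRecord]:
    model = checkpoint.build_model(embedding_table)
    out = []
    for rec in records:
        labels = model.predict_labels(rec)
        out.append(LabeledRecord(id=rec.id, sequence=rec.sequence, labels=labels))
    return out


def evaluate(checkpoint: Checkpoint, data: list[LabeledRecord],
             embedding_table: EmbeddingTable | None = None) -> MetricsReport:
    from .seqio import SSAlphabet

    preds = predict(checkpoint,
                    [PeptideRecord(r.id, r.sequence) for r in data],
                    embedding_table)
    pairs = [(ref.labels, pred.labels) for ref, pred in zip(data, preds)]
    return evaluate_dataset(pairs, SSAlphabet(checkpoint.model_config.ss_mode))
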