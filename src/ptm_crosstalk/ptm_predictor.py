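"""Per-residue multi-label PTM prediction: model wrapper, pretraining,
PR-AUC evaluation and PR-AUC-weighted ensembling.

A :class:`PredictorModel` wraps the NumPy transformer with the sequence
encoding pipeline: tokenize -> per-window forward pass -> sigmoid ->
overlap-mean merge -> optional eligibility masking (probabilities forced to
0 at residues chemically incompatible with a class). Ensembles combine
member probabilities with per-PTM-class weights derived from each base
model's area under the precision-recall curve on held-out data, so the
classes a member predicts well contribute more.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score

from . import encoder_prep as enc
from .nn import Adam, PTMTransformer, masked_bce_with_logits, binary_accuracy
from .schema import PTMLabelSchema, DEFAULT_SCHEMA
from .sequence_io import ProteinRecord
from .synthetic_data import SyntheticCorpus

__all__ = [
    "PredictorConfig",
    "SMALL_CONFIG",
    "PredictorModel",
    "EnsembleSpec",
    "pretrain",
    "predict",
    "compute_pr_auc",
    "ensemble_predict",
    "PredictionMatrix",
]


@dataclass(frozen=True)
class PredictorConfig:
    """Architecture and pretraining hyperparameters.

    The base architecture is not prescribed by the scoring/fine-tuning
    protocol, which is base-model-agnostic; defaults use d_model=128 to
    match the 128-dimensional sinusoidal positional encodings, with 4
    post-norm encoder layers of 4 heads. ``SMALL_CONFIG`` is a reduced
    profile for CPU test runs.
    """

    d_model: int = 128
    n_layers: int = 4
    n_heads: int = 4
    d_ff: int = 256
    n_classes: int = 13
    pretrain_epochs: int = 30
    pretrain_lr: float = 1e-3
    batch_size: int = 16

    def __post_init__(self):
        if self.d_model % 2:
            raise ValueError("d_model must be even (sinusoidal encoding)")


SMALL_CONFIG = PredictorConfig(d_model=64, n_layers=2, n_heads=4, d_ff=128,
                               pretrain_epochs=200, pretrain_lr=3e-3,
                               batch_size=8)


@dataclass(frozen=True)
class PredictionMatrix:
    """Per-residue PTM probabilities for one protein (1-based positions)."""

    protein_id: str
    sequence: str
    values: np.ndarray            # (L, n_classes) in [0, 1]
    classes: tuple[str, ...]
    provenance: str = "model"

    def __post_init__(self):
        v = np.asarray(self.values)
        if v.shape != (len(self.sequence), len(self.classes)):
            raise ValueError("prediction matrix shape mismatch")
        if ((v < 0) | (v > 1)).any():
            raise ValueError("probabilities outside [0, 1]")

    def probability(self, position: int, ptm_type: str) -> float:
        return float(self.values[position - 1, self.classes.index(ptm_type)])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.classes))
        df.insert(0, "residue", list(self.sequence))
        df.insert(0, "position", np.arange(1, len(self.sequence) + 1))
        df.insert(0, "protein_id", self.protein_id)
        return df


class PredictorModel:
    """A transformer PTM predictor plus its encoding/masking conventions."""

    def __init__(self, config: PredictorConfig, schema: PTMLabelSchema = DEFAULT_SCHEMA,
                 seed: int = 0, model_id: str = "model"):
        if schema.n_classes != config.n_classes:
            raise ValueError("schema and config disagree on class count")
        self.config = config
        self.schema = schema
        self.model_id = model_id
        rng = np.random.default_rng(seed)
        self.net = PTMTransformer(enc.VOCAB_SIZE, config.d_model, config.n_layers,
                                  config.n_heads, config.d_ff, config.n_classes, rng)
        self._pe = enc.positional_encoding(enc.WINDOW_LENGTH, config.d_model)

    # -- forward -------------------------------------------------------
    def _forward_windows(self, windows: Sequence[enc.TokenWindow],
                         crop: bool = True):
        """Batched forward over token windows -> logits Tensor (B, L', C).

        Trailing pad columns shared by the whole batch are cropped before
        the forward pass; with padded keys masked out of attention this is
        an exact identity on the real-token outputs.
        """
        ids = np.stack([w.token_ids for w in windows])
        valid = ids != enc.PAD_ID  # start/end participate in attention
        if crop:
            last = int(np.max(valid.sum(axis=1)))
            ids, valid = ids[:, :last], valid[:, :last]
        logits = self.net(ids, self._pe[:ids.shape[1]], key_valid=valid)
        return logits

    def predict(self, record: ProteinRecord, mask_eligibility: bool = True,
                provenance: str | None = None) -> PredictionMatrix:
        """Predict per-residue probabilities for all 13 PTM classes."""
        windows = enc.tokenize(record)
        logits = self._forward_windows(windows).data
        probs = 1.0 / (1.0 + np.exp(-logits))
        per_window = []
        for i, w in enumerate(windows):
            rows = probs[i][w.valid_mask[:probs.shape[1]]]
            per_window.append(rows)
        merged = enc.merge_window_predictions(list(windows), per_window)
        if mask_eligibility:
            merged = merged * self.schema.eligibility_matrix(record.sequence)
        return PredictionMatrix(protein_id=record.id, sequence=record.sequence,
                                values=merged, classes=self.schema.classes,
                                provenance=provenance or self.model_id)

    # -- persistence ----------------------------------------------------
    def save(self, directory: str | Path) -> None:
        """Self-describing checkpoint: config JSON + npz weight blobs."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        meta = {"model_id": self.model_id, "config": asdict(self.config),
                "classes": list(self.schema.classes)}
        (directory / "config.json").write_text(json.dumps(meta, indent=2))
        np.savez(directory / "weights.npz", **self.net.state_dict())

    @classmethod
    def load(cls, directory: str | Path,
             schema: PTMLabelSchema = DEFAULT_SCHEMA) -> "PredictorModel":
        directory = Path(directory)
        meta = json.loads((directory / "config.json").read_text())
        model = cls(PredictorConfig(**meta["config"]), schema=schema,
                    model_id=meta["model_id"])
        with np.load(directory / "weights.npz") as blobs:
            model.net.load_state_dict({k: blobs[k] for k in blobs.files})
        return model

    def clone(self, model_id: str | None = None) -> "PredictorModel":
        other = copy.deepcopy(self)
        if model_id:
            other.model_id = model_id
        return other


# ---------------------------------------------------------------------------
def _corpus_batches(corpus: SyntheticCorpus, schema: PTMLabelSchema):
    """Tokenize every corpus record once; returns per-record window data
    aligned with (L, C) label matrices."""
    items = []
    for rec, labels in corpus.records:
        windows = enc.tokenize(rec)
        for w in windows:
            tgt = np.zeros((enc.WINDOW_LENGTH, schema.n_classes))
            msk = np.zeros((enc.WINDOW_LENGTH, schema.n_classes), dtype=bool)
            rows = slice(w.window_offset, w.window_offset + w.n_residues)
            res_slots = np.flatnonzero(w.valid_mask)
            tgt[res_slots] = labels[rows]
            msk[res_slots] = True
            items.append((w, tgt, msk))
    return items


def pretrain(corpus: SyntheticCorpus, config: PredictorConfig = SMALL_CONFIG,
             seed: int = 0, schema: PTMLabelSchema = DEFAULT_SCHEMA,
             model_id: str | None = None) -> PredictorModel:
    """Train a base PTM predictor from scratch on a labeled corpus.

    Full-matrix binary cross-entropy against the binary label matrices,
    Adam, mini-batches in a seeded shuffle order. Deterministic given
    (corpus, config, seed).
    """
    if not corpus.records:
        raise ValueError("empty pretraining corpus")
    model = PredictorModel(config, schema=schema, seed=seed,
                           model_id=model_id or f"base_seed{seed}")
    items = _corpus_batches(corpus, schema)
    rng = np.random.default_rng(seed + 1)
    opt = Adam(model.net.parameters(), lr=config.pretrain_lr)
    widths = np.array([w.n_residues for w, _t, _m in items])
    for _epoch in range(config.pretrain_epochs):
        # shuffle, then stable-sort by length so batches stay near-uniform
        # in width (pads are masked out, so cropping batches is exact)
        order = rng.permutation(len(items))
        order = order[np.argsort(widths[order], kind="stable")]
        for start in range(0, len(items), config.batch_size):
            batch = [items[i] for i in order[start:start + config.batch_size]]
            windows = [b[0] for b in batch]
            logits = model._forward_windows(windows)
            width = logits.shape[1]
            tgt = np.stack([b[1][:width] for b in batch])
            msk = np.stack([b[2][:width] for b in batch])
            loss = masked_bce_with_logits(logits, tgt, msk)
            opt.zero_grad()
            loss.backward()
            opt.step()
    return model


def predict(model: PredictorModel, record: ProteinRecord,
            mask_eligibility: bool = True) -> PredictionMatrix:
    """Functional alias for :meth:`PredictorModel.predict`."""
    return model.predict(record, mask_eligibility=mask_eligibility)


def compute_pr_auc(model: PredictorModel,
                   validation: SyntheticCorpus) -> dict[str, float | None]:
    """Per-class PR-AUC (average precision) on a labeled validation set.

    Classes without at least one positive and one negative example are
    flagged absent (None) rather than scored 0, and are later excluded
    from ensemble weighting.
    """
    schema = model.schema
    scores, labels = [], []
    for rec, lab in validation.records:
        pm = model.predict(rec, mask_eligibility=False)
        scores.append(pm.values)
        labels.append(np.asarray(lab))
    s = np.concatenate(scores)
    y = np.concatenate(labels)
    out: dict[str, float | None] = {}
    for j, cls in enumerate(schema.classes):
        yj = y[:, j]
        if yj.min() == yj.max():
            out[cls] = None
        else:
            out[cls] = float(average_precision_score(yj, s[:, j]))
    return out


@dataclass
class EnsembleSpec:
    """Fine-tuned members plus per-class combination weights.

    ``weights`` has shape (n_members, n_classes); columns are normalised
    to sum to 1 (a class with zero total weight is an error).
    """

    members: list[PredictorModel]
    weights: np.ndarray
    schema: PTMLabelSchema = field(default_factory=lambda: DEFAULT_SCHEMA)

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if len(self.members) < 1:
            raise ValueError("ensemble needs at least one member")
        if self.weights.shape != (len(self.members), self.schema.n_classes):
            raise ValueError("weights must be (n_members, n_classes)")
        if (self.weights < 0).any():
            raise ValueError("weights must be non-negative")
        totals = self.weights.sum(axis=0)
        if (totals <= 0).any():
            bad = [self.schema.classes[j] for j in np.flatnonzero(totals <= 0)]
            raise ValueError(f"zero total weight for classes {bad}")
        self.weights = self.weights / totals

    @classmethod
    def from_pr_auc(cls, members: list[PredictorModel],
                    pr_auc_per_member: Sequence[dict[str, float | None]],
                    schema: PTMLabelSchema = DEFAULT_SCHEMA) -> "EnsembleSpec":
        """Weights proportional to each base model's PR-AUC per class;
        classes absent from the validation data fall back to equal weights."""
        w = np.zeros((len(members), schema.n_classes))
        for i, aucs in enumerate(pr_auc_per_member):
            for j, cl in enumerate(schema.classes):
                v = aucs.get(cl)
                w[i, j] = 0.0 if v is None else v
        equal = np.full(len(members), 1.0 / len(members))
        for j in range(schema.n_classes):
            if w[:, j].sum() <= 0:
                w[:, j] = equal
        return cls(members=members, weights=w, schema=schema)


def ensemble_predict(spec: EnsembleSpec, record: ProteinRecord,
                     mask_eligibility: bool = True) -> PredictionMatrix:
    """Weighted arithmetic mean of member probabilities, per (residue, class)."""
    stacked = np.stack([m.predict(record, mask_eligibility=mask_eligibility).values
                        for m in spec.members])           # (M, L, C)
    merged = np.einsum("mlc,mc->lc", stacked, spec.weights)
    merged = np.clip(merged, 0.0, 1.0)  # guard rounding at the boundaries
    return PredictionMatrix(protein_id=record.id, sequence=record.sequence,
                            values=merged, classes=spec.schema.classes,
                            provenance="ensemble")
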