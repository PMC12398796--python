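"""Frozen-layer fine-tuning of pretrained PTM predictors.

To adapt a pretrained per-residue predictor to a six-sequence dataset
without catastrophic forgetting, all parameters are frozen except the
final transformer encoder block and the last dense (output) layer. Training
runs binary cross-entropy against the continuous target-score matrices
over the supervised cells only, with Adam at learning rate 1e-4 for 500
epochs by default, and is repeated across an ensemble of base models whose
per-class combination weights come from the bases' held-out PR-AUC.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import encoder_prep as enc
from .nn import Adam, binary_accuracy, masked_bce_with_logits
from .ms_quant import TargetScoreMatrix
from .ptm_predictor import EnsembleSpec, PredictorModel, compute_pr_auc
from .sequence_io import ProteinRecord
from .synthetic_data import SyntheticCorpus

__all__ = [
    "FinetuneConfig",
    "FrozenReport",
    "FREEZE_POLICIES",
    "freeze",
    "finetune_one",
    "finetune_ensemble",
]


@dataclass(frozen=True)
class FinetuneConfig:
    epochs: int = 500
    learning_rate: float = 1e-4
    n_members: int = 15
    seed: int = 0
    freeze_policy: str = "last_block_and_head"
    accuracy_threshold: float = 0.5

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.n_members < 1:
            raise ValueError("n_members must be >= 1")
        if self.freeze_policy not in FREEZE_POLICIES:
            raise ValueError(f"unknown freeze policy {self.freeze_policy!r}")

    def member_seed(self, index: int) -> int:
        # deterministic per-member seed stream, kept below 2**31
        return (self.seed * 100_003 + index * 7919 + 17) % (2 ** 31 - 1)


def _trainable_last_block_and_head(model: PredictorModel) -> set[str]:
    """'Final encoding layer' read as the last transformer encoder block;
    'last dense layer' is the output head."""
    last = len(model.net.layers) - 1
    names = set()
    for name in model.net.named_parameters():
        if name.startswith((f"layers.{last}.", "final_norm.", "head.")):
            names.add(name)
    return names


def _trainable_head_only(model: PredictorModel) -> set[str]:
    """Alternative reading: only a final projection (the head) is tuned."""
    return {n for n in model.net.named_parameters()
            if n.startswith(("final_norm.", "head."))}


FREEZE_POLICIES = {
    "last_block_and_head": _trainable_last_block_and_head,
    "head_only": _trainable_head_only,
}


@dataclass
class FrozenReport:
    """Per-parameter-group freeze status with content checksums."""

    frozen: dict[str, str] = field(default_factory=dict)      # name -> sha256
    trainable: tuple[str, ...] = ()

    @staticmethod
    def checksum(arr: np.ndarray) -> str:
        return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()

    def verify(self, model: PredictorModel) -> bool:
        """True iff every frozen group is bit-identical to its checksum."""
        params = model.net.named_parameters()
        return all(self.checksum(params[n].data) == h
                   for n, h in self.frozen.items())


def freeze(model: PredictorModel,
           policy: str = "last_block_and_head") -> FrozenReport:
    """Mark all parameters untrainable except those selected by `policy`.

    Frozen parameters also stop requiring gradients, so backpropagation
    does not traverse into them; the returned report carries checksums for
    later bit-exactness verification.
    """
    trainable_names = FREEZE_POLICIES[policy](model)
    report = FrozenReport(trainable=tuple(sorted(trainable_names)))
    for name, p in model.net.named_parameters().items():
        is_trainable = name in trainable_names
        p.trainable = is_trainable
        p.requires_grad = is_trainable
        if not is_trainable:
            report.frozen[name] = FrozenReport.checksum(p.data)
    return report


def _window_targets(record: ProteinRecord, matrix: TargetScoreMatrix):
    """Spread a full-length target matrix over the record's token windows."""
    windows = enc.tokenize(record)
    items = []
    for w in windows:
        tgt = np.zeros((enc.WINDOW_LENGTH, matrix.scores.shape[1]))
        msk = np.zeros((enc.WINDOW_LENGTH, matrix.scores.shape[1]), dtype=bool)
        rows = slice(w.window_offset, w.window_offset + w.n_residues)
        slots = np.flatnonzero(w.valid_mask)
        tgt[slots] = matrix.scores[rows]
        msk[slots] = matrix.mask[rows]
        items.append((w, tgt, msk))
    return items


def finetune_one(base: PredictorModel, records: Sequence[ProteinRecord],
                 targets: Mapping[str, TargetScoreMatrix],
                 config: FinetuneConfig, seed: int | None = None,
                 ) -> tuple[PredictorModel, pd.DataFrame, FrozenReport]:
    """Fine-tune one base model on the six-sequence dataset.

    Returns the fine-tuned copy (the base is untouched), a per-epoch
    loss/accuracy log, and the freeze report whose checksums must still
    verify afterwards. Deterministic given (base, dataset, config, seed).
    """
    del seed  # full-batch training is already deterministic; kept for API symmetry
    missing = [r.id for r in records if r.id not in targets]
    if missing:
        raise KeyError(f"no target matrix for records {missing}")
    model = base.clone(model_id=f"{base.model_id}_ft")
    report = freeze(model, config.freeze_policy)

    items = []
    for rec in records:
        items.extend(_window_targets(rec, targets[rec.id]))
    if not any(m.any() for _w, _t, m in items):
        raise ValueError("fully-masked dataset: nothing to supervise")

    # Bucket windows by cropped token width: pads are masked out of
    # attention, so trimming each bucket to its own real length is exact
    # and avoids 514-wide attention maps for short tail windows.
    from ._autograd import Tensor
    n_layers = len(model.net.layers)
    trainable_layers = [int(n.split(".")[1]) for n in report.trainable
                        if n.startswith("layers.")]
    first = min(trainable_layers) if trainable_layers else n_layers

    # When only the tail of the network is trainable (the default freeze
    # policy), its output is needed solely at supervised positions, so the
    # per-epoch pass restricts attention queries to those rows — exact,
    # since keys/values come from the cached frozen prefix.
    row_mode = first >= n_layers - 1

    buckets: dict[int, list[tuple]] = {}
    for item in items:
        w = item[0]
        width = w.n_residues + 2  # start + residues + end
        buckets.setdefault(width, []).append(item)
    groups = []
    total_sup = 0
    for width, members in sorted(buckets.items()):
        ids = np.stack([w.token_ids[:width] for w, _t, _m in members])
        valid = ids != enc.PAD_ID
        tgt = np.stack([t[:width] for _w, t, _m in members])
        msk = np.stack([m[:width] for _w, _t, m in members])
        bias = model.net.attn_bias(valid)
        # Frozen-prefix caching: activations below the first trainable
        # block are constant across epochs; freeze() cleared requires_grad
        # on frozen parameters so this pass builds no graph.
        x = model.net.embed(ids, model._pe[:width])
        for layer in model.net.layers[:first]:
            x = layer(x, bias)
        n_sup = int(msk.sum())
        if n_sup == 0:
            continue  # no supervised cells: zero loss and zero gradient
        g = {"prefix": x.data, "bias": bias, "tgt": tgt, "msk": msk,
             "n_sup": n_sup}
        if row_mode:
            per_window_rows = [np.flatnonzero(m.any(axis=-1)) for m in msk]
            s_max = max(len(r) for r in per_window_rows)
            # pad short row lists with slot 0 (the start token), which is
            # never supervised, so its gathered mask is all-False
            rows = np.zeros((len(members), s_max), dtype=np.int64)
            for i, r in enumerate(per_window_rows):
                rows[i, :len(r)] = r
            b_idx = np.arange(len(members))[:, None]
            g["rows"] = rows
            g["tgt"] = tgt[b_idx, rows]
            g["msk"] = msk[b_idx, rows]
        groups.append(g)
        total_sup += n_sup

    def forward_group(g):
        x = Tensor(g["prefix"])
        if not row_mode:
            return model.net.encode(x, g["bias"], start=first)
        if first == n_layers - 1:
            x = model.net.layers[-1].forward_rows(x, g["rows"], g["bias"])
        else:  # head-only policy
            x = Tensor.take_rows(x, g["rows"])
        return model.net.head(model.net.final_norm(x))

    opt = Adam([p for p in model.net.parameters() if p.trainable],
               lr=config.learning_rate)
    log_rows = []
    for epoch in range(1, config.epochs + 1):
        loss = None
        acc_hits = 0.0
        for g in groups:
            logits = forward_group(g)
            part = masked_bce_with_logits(logits, g["tgt"], g["msk"]) \
                * (g["n_sup"] / total_sup)
            loss = part if loss is None else loss + part
            acc_hits += g["n_sup"] * binary_accuracy(
                logits.data, g["tgt"], g["msk"], config.accuracy_threshold)
        opt.zero_grad()
        loss.backward()
        opt.step()
        log_rows.append({"epoch": epoch, "loss": float(loss.data),
                         "binary_accuracy": acc_hits / total_sup})
    return model, pd.DataFrame(log_rows), report


def finetune_ensemble(bases: Sequence[PredictorModel],
                      records: Sequence[ProteinRecord],
                      targets: Mapping[str, TargetScoreMatrix],
                      config: FinetuneConfig,
                      validation: SyntheticCorpus,
                      ) -> tuple[EnsembleSpec, list[pd.DataFrame]]:
    """Repeat the fine-tuning procedure over all base models.

    Per-class ensemble weights are the base models' PR-AUCs on the held-out
    validation corpus (computed before fine-tuning, mirroring the use of
    the original models' benchmark PR-AUCs), normalised per class.
    """
    if len(bases) != config.n_members:
        raise ValueError(
            f"got {len(bases)} base models for n_members={config.n_members}")
    pr_aucs = [compute_pr_auc(b, validation) for b in bases]
    members, logs = [], []
    for i, base in enumerate(bases):
        member, log, report = finetune_one(base, records, targets, config,
                                           seed=config.member_seed(i))
        if not report.verify(member):
            raise AssertionError("frozen parameters changed during fine-tuning")
        members.append(member)
        logs.append(log)
    schema = bases[0].schema
    spec = EnsembleSpec.from_pr_auc(members, pr_aucs, schema=schema)
    return spec, logs
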