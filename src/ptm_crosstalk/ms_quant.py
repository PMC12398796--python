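"""MS site-intensity quantitation and the continuous training-target scheme.

Site intensities from wild-type and knock-out (or mutant) conditions are
first normalised by protein abundance, then converted to log2 fold-changes

    x = log2( (I_KO / A_KO) / (I_WT / A_WT) )

and finally mapped onto the [0, 1] training-score scale

    score(x) = (x + 1) / 2 + 0.25, clipped to [0, 1]

which anchors "no change" (x = 0) at 0.75 — the same constant assigned to
every wild-type observation — so that an unchanged site stays inside the
positive prediction class (> 0.5) while leaving headroom for both hyper-
(score -> 1) and hypo-modification (score -> 0). The transformation is
affine and strictly increasing on x in (-1.5, 0.5), hence invertible there.

Isoform-ambiguous rows (a modified peptide shared by Hsp90alpha and
Hsp90beta, written e.g. "283;275") contribute to both isoforms' target
matrices and carry an ambiguity flag throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .schema import PTMLabelSchema, DEFAULT_SCHEMA
from .sequence_io import ProteinRecord

__all__ = [
    "WT_SCORE",
    "DEAD_ZONE",
    "INTENSITY_COLUMNS",
    "SiteIntensityTable",
    "FoldChangeRecord",
    "TargetScoreMatrix",
    "normalize_and_lfc",
    "score_from_lfc",
    "lfc_from_score",
    "wt_target",
    "wt_observations",
    "build_target_matrix",
]

WT_SCORE = 0.75       # fixed target for every wild-type observation
DEAD_ZONE = 0.1       # |x| below this is called "unchanged", not hyper/hypo

INTENSITY_COLUMNS = ("protein_id", "position", "residue", "ptm_type",
                     "condition", "intensity", "protein_abundance")


class SiteIntensityTable:
    """Per-site, per-PTM-type, per-condition MS intensities.

    Wraps a pandas DataFrame with columns ``protein_id, position, residue,
    ptm_type, condition, intensity, protein_abundance`` (plus an optional
    ``isoform_pair`` flag column). ``position`` is a string: either a
    1-based index ("283") or an ambiguous alpha;beta pair ("283;275"),
    in which case ``protein_id`` is the matching "alpha_id;beta_id" pair.
    """

    def __init__(self, frame: pd.DataFrame):
        missing = set(INTENSITY_COLUMNS) - set(frame.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        frame = frame.copy()
        frame["position"] = frame["position"].astype(str)
        if "isoform_pair" not in frame.columns:
            frame["isoform_pair"] = frame["position"].str.contains(";")
        if (frame["intensity"] < 0).any():
            raise ValueError("negative intensities")
        if (frame["protein_abundance"] <= 0).any():
            raise ValueError("protein_abundance must be positive")
        key = ["protein_id", "position", "ptm_type", "condition"]
        if frame.duplicated(subset=key).any():
            dup = frame[frame.duplicated(subset=key)].iloc[0]
            raise ValueError(f"duplicate site row: {tuple(dup[key])}")
        self.frame = frame.reset_index(drop=True)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "SiteIntensityTable":
        return cls(pd.read_csv(path, sep="\t", dtype={"position": str}))

    def write_tsv(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    def conditions(self) -> list[str]:
        return sorted(self.frame["condition"].unique())


@dataclass(frozen=True)
class FoldChangeRecord:
    """A site's abundance-normalised log2 fold-change and direction call."""

    protein_id: str
    position: str          # "283" or ambiguous "283;275"
    residue: str
    ptm_type: str
    x: float               # log2((I_KO/A_KO)/(I_WT/A_WT))
    direction: str         # hyper | hypo | unchanged
    ambiguous_isoform: bool = False

    def __post_init__(self):
        expected = _direction(self.x)
        if self.direction != expected:
            raise ValueError(
                f"direction {self.direction!r} inconsistent with x={self.x}")


def _direction(x: float, dead_zone: float = DEAD_ZONE) -> str:
    if x > dead_zone:
        return "hyper"
    if x < -dead_zone:
        return "hypo"
    return "unchanged"


def normalize_and_lfc(table: SiteIntensityTable, ko_condition: str,
                      wt_condition: str = "WT",
                      dead_zone: float = DEAD_ZONE,
                      pseudo_floor: bool = False,
                      x_clip: float | None = 4.0) -> list[FoldChangeRecord]:
    """Protein-abundance-normalised log2 fold-changes, KO versus WT.

    Sites detected in only one condition are excluded by default (no
    imputation); with ``pseudo_floor=True`` a missing or zero intensity is
    replaced by half the smallest positive intensity in the table.
    ``x_clip`` symmetrically winsorises extreme fold-changes (pass None to
    disable).
    """
    df = table.frame
    if ko_condition not in set(df["condition"]):
        raise ValueError(f"condition {ko_condition!r} not present")
    floor = np.nan
    pos_int = df.loc[df["intensity"] > 0, "intensity"]
    if len(pos_int):
        floor = 0.5 * float(pos_int.min())
    # abundance fallback for conditions a site was not measured in
    cond_abundance = df.groupby("condition")["protein_abundance"].median()

    wide = df[df["condition"].isin([wt_condition, ko_condition])].pivot_table(
        index=["protein_id", "position", "residue", "ptm_type", "isoform_pair"],
        columns="condition", values=["intensity", "protein_abundance"],
        aggfunc="first")

    out: list[FoldChangeRecord] = []
    for key, row in wide.iterrows():
        protein_id, position, residue, ptm_type, ambiguous = key
        i_wt = row.get(("intensity", wt_condition), np.nan)
        i_ko = row.get(("intensity", ko_condition), np.nan)
        a_wt = row.get(("protein_abundance", wt_condition), np.nan)
        a_ko = row.get(("protein_abundance", ko_condition), np.nan)
        if pseudo_floor:
            if not i_wt > 0:
                i_wt = floor
                if not math.isfinite(a_wt):
                    a_wt = cond_abundance.get(wt_condition, np.nan)
            if not i_ko > 0:
                i_ko = floor
                if not math.isfinite(a_ko):
                    a_ko = cond_abundance.get(ko_condition, np.nan)
        ok = (i_wt > 0) and (i_ko > 0) and math.isfinite(a_wt) and math.isfinite(a_ko)
        if not ok:  # detected in one condition only (or zero): excluded
            continue
        x = math.log2((i_ko / a_ko) / (i_wt / a_wt))
        if x_clip is not None:
            x = float(np.clip(x, -x_clip, x_clip))
        out.append(FoldChangeRecord(
            protein_id=str(protein_id), position=str(position),
            residue=str(residue), ptm_type=str(ptm_type), x=x,
            direction=_direction(x, dead_zone), ambiguous_isoform=bool(ambiguous)))
    return out


def score_from_lfc(x: float | np.ndarray) -> float | np.ndarray:
    """Map a log2 fold-change onto the [0, 1] training-score scale.

    ``score = (x + 1)/2 + 0.25`` clipped to [0, 1]: monotone
    non-decreasing, with x = 0 anchored at the wild-type score 0.75.
    """
    arr = np.asarray(x, dtype=np.float64)
    if not np.isfinite(arr).all():
        raise ValueError("non-finite log fold-change")
    score = np.clip((arr + 1.0) / 2.0 + 0.25, 0.0, 1.0)
    return float(score) if np.isscalar(x) or arr.ndim == 0 else score

def lfc_from_score(score: float | np.ndarray) -> float | np.ndarray:
    """Inverse of :func:`score_from_lfc` on its strictly increasing branch
    (scores in (0, 1), i.e. x in (-1.5, 0.5))."""
    arr = np.asarray(score, dtype=np.float64)
    if ((arr <= 0.0) | (arr >= 1.0)).any():
        raise ValueError("score outside the invertible open interval (0, 1)")
    x = 2.0 * (arr - 0.25) - 1.0
    return float(x) if np.isscalar(score) or arr.ndim == 0 else x


def wt_observations(table: SiteIntensityTable,
                    wt_condition: str = "WT") -> list[FoldChangeRecord]:
    """Sites observed (intensity > 0) in the wild-type condition, as
    zero-change records; these anchor the constant 0.75 WT targets."""
    df = table.frame
    rows = df[(df["condition"] == wt_condition) & (df["intensity"] > 0)]
    return [FoldChangeRecord(protein_id=str(r.protein_id), position=str(r.position),
                             residue=str(r.residue), ptm_type=str(r.ptm_type),
                             x=0.0, direction="unchanged",
                             ambiguous_isoform=bool(r.isoform_pair))
            for r in rows.itertuples()]


def wt_target(*_args) -> float:
    """Training target for any site observed in the wild type: the constant
    0.75, independent of intensity magnitude."""
    return WT_SCORE


@dataclass
class TargetScoreMatrix:
    """Per-(residue, PTM class) training targets for one sequence record.

    ``scores`` is (L, n_classes) in [0, 1]; ``mask`` is True only at
    supervised cells — everything else is excluded from the training loss.
    """

    record_id: str
    scores: np.ndarray
    mask: np.ndarray
    schema: PTMLabelSchema = field(default_factory=lambda: DEFAULT_SCHEMA)

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=np.float64)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.scores.shape != self.mask.shape:
            raise ValueError("scores and mask shapes differ")
        if self.scores.shape[1] != self.schema.n_classes:
            raise ValueError("class dimension does not match schema")
        sup = self.scores[self.mask]
        if len(sup) and ((sup < 0) | (sup > 1)).any():
            raise ValueError("supervised targets must lie in [0, 1]")

    def set(self, position: int, ptm_type: str, score: float) -> None:
        j = self.schema.index(ptm_type)
        self.scores[position - 1, j] = score
        self.mask[position - 1, j] = True


def _positions_for_record(fc: FoldChangeRecord, record: ProteinRecord,
                          isoform_slot: int) -> list[int]:
    """Resolve a (possibly ambiguous) fold-change row to 1-based positions
    on `record`. `isoform_slot` selects the alpha (0) / beta (1) half of an
    ambiguous "283;275" position."""
    parts = fc.position.split(";")
    if fc.ambiguous_isoform and len(parts) == 2:
        return [int(parts[isoform_slot])]
    return [int(parts[0])]


def build_target_matrix(records: Sequence[ProteinRecord],
                        fold_changes_by_record: Mapping[str, Iterable[FoldChangeRecord]],
                        schema: PTMLabelSchema = DEFAULT_SCHEMA,
                        wt_record_ids: Sequence[str] = (),
                        isoform_slot_by_record: Mapping[str, int] | None = None,
                        ) -> dict[str, TargetScoreMatrix]:
    """Assemble per-record target matrices for fine-tuning.

    Wild-type records (listed in ``wt_record_ids``) receive the constant
    0.75 anchor at every site observed in the WT condition; mutant records
    receive ``score_from_lfc(x)`` at every measured site. Ambiguous
    alpha;beta rows are written into both isoforms' matrices (the slot
    mapping names which half of the pair applies to which record). At any
    cell whose residue is chemically ineligible for the class — e.g.
    acetyl-K at a K->Q mutated position — supervision is dropped.
    """
    isoform_slot_by_record = isoform_slot_by_record or {}
    out: dict[str, TargetScoreMatrix] = {}
    wt_set = set(wt_record_ids)
    for rec in records:
        L = len(rec)
        mat = TargetScoreMatrix(record_id=rec.id,
                                scores=np.zeros((L, schema.n_classes)),
                                mask=np.zeros((L, schema.n_classes), dtype=bool),
                                schema=schema)
        slot = isoform_slot_by_record.get(rec.id, 0)
        for fc in fold_changes_by_record.get(rec.id, ()):
            target = WT_SCORE if rec.id in wt_set else float(score_from_lfc(fc.x))
            for pos in _positions_for_record(fc, rec, slot):
                if not 1 <= pos <= L:
                    raise IndexError(
                        f"site {pos} outside {rec.id} (length {L})")
                if not schema.is_eligible(fc.ptm_type, rec.residue(pos)):
                    continue  # e.g. acetyl-K at the K->Q position: masked out
                mat.set(pos, fc.ptm_type, target)
        out[rec.id] = mat
    return out
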