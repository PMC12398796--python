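"""Mutant-versus-WT crosstalk analysis of predicted PTM probabilities.

The fine-tuned ensemble predicts per-residue PTM probabilities for the
wild-type and acetyl-mimetic sequences; per (site, class) the predicted
log2 fold-change log2((p_mut + eps)/(p_wt + eps)) is classified as hyper-,
hypo- or unchanged with the same dead-zone rule used for the MS data, and
sign-concordance with the MS-derived directions is summarised. Because the
model scores each isoform separately, every isoform-ambiguous MS site
resolves into distinct alpha and beta rows here.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .ms_quant import DEAD_ZONE
from .ptm_predictor import PredictionMatrix

__all__ = [
    "EPSILON_FLOOR",
    "CrosstalkResult",
    "ConcordanceSummary",
    "predicted_fold_change",
    "concordance",
    "export_heatmap_table",
]

EPSILON_FLOOR = 1e-6  # probability floor guarding log2 ratios at p ~ 0


def _direction(x: float, dead_zone: float) -> str:
    if x > dead_zone:
        return "hyper"
    if x < -dead_zone:
        return "hypo"
    return "unchanged"


@dataclass(frozen=True)
class CrosstalkResult:
    isoform: str
    position: int
    ptm_class: str
    predicted_lfc: float
    predicted_direction: str
    ms_direction: str | None = None
    concordant: bool | None = None


@dataclass(frozen=True)
class ConcordanceSummary:
    """Agreement between predicted and MS direction calls.

    Only sites with a direction call on both sides (and neither call
    'unchanged') enter the comparison; the excluded counts are reported.
    """

    n_compared: int
    n_concordant: int
    n_predicted_only: int
    n_ms_only: int
    per_class: dict[str, tuple[int, int]]  # class -> (compared, concordant)

    @property
    def fraction(self) -> float:
        if self.n_compared == 0:
            return float("nan")
        return self.n_concordant / self.n_compared


def predicted_fold_change(wt_pred: PredictionMatrix, mut_pred: PredictionMatrix,
                          isoform: str = "alpha",
                          classes: Sequence[str] | None = None,
                          dead_zone: float = DEAD_ZONE,
                          eps: float = EPSILON_FLOOR) -> list[CrosstalkResult]:
    """Per-(residue, class) predicted log2 fold-change, mutant over WT."""
    if wt_pred.classes != mut_pred.classes:
        raise ValueError("prediction matrices use different class schemas")
    if len(wt_pred.sequence) != len(mut_pred.sequence):
        raise ValueError("sequence length mismatch between WT and mutant")
    keep = set(wt_pred.classes if classes is None else classes)
    lfc = np.log2((mut_pred.values + eps) / (wt_pred.values + eps))
    out = []
    for j, cls in enumerate(wt_pred.classes):
        if cls not in keep:
            continue
        for pos0 in range(lfc.shape[0]):
            x = float(lfc[pos0, j])
            out.append(CrosstalkResult(
                isoform=isoform, position=pos0 + 1, ptm_class=cls,
                predicted_lfc=x, predicted_direction=_direction(x, dead_zone)))
    return out


def concordance(results: Iterable[CrosstalkResult],
                ms_directions: Mapping[tuple[str, int, str], str],
                ) -> ConcordanceSummary:
    """Fraction of jointly-called sites whose predicted and MS directions
    agree (hyper with hyper, hypo with hypo)."""
    compared = concordant = 0
    per_class: dict[str, list[int]] = {}
    predicted_only = 0
    seen_keys = set()
    for r in results:
        key = (r.isoform, r.position, r.ptm_class)
        ms = ms_directions.get(key)
        if ms is None:
            if r.predicted_direction != "unchanged":
                predicted_only += 1
            continue
        seen_keys.add(key)
        if ms == "unchanged" or r.predicted_direction == "unchanged":
            continue
        compared += 1
        hit = int(ms == r.predicted_direction)
        concordant += hit
        c = per_class.setdefault(r.ptm_class, [0, 0])
        c[0] += 1
        c[1] += hit
    ms_only = sum(1 for k, v in ms_directions.items()
                  if k not in seen_keys and v != "unchanged")
    return ConcordanceSummary(
        n_compared=compared, n_concordant=concordant,
        n_predicted_only=predicted_only, n_ms_only=ms_only,
        per_class={k: (v[0], v[1]) for k, v in per_class.items()})


def export_heatmap_table(results: Iterable[CrosstalkResult],
                         path: str | Path,
                         site_panel: Iterable[tuple[str, int]] | None = None,
                         ) -> pd.DataFrame:
    """Write a per-isoform heatmap table of predicted log2 fold-changes.

    One row per (isoform, position, class); alpha and beta never share a
    row, so every ambiguous MS site appears resolved. ``site_panel`` (an
    iterable of (isoform, position)) optionally restricts the rows.
    """
    rows = [{"isoform": r.isoform, "position": r.position,
             "ptm_class": r.ptm_class, "predicted_lfc": r.predicted_lfc,
             "predicted_direction": r.predicted_direction}
            for r in results]
    df = pd.DataFrame(rows, columns=["isoform", "position", "ptm_class",
                                     "predicted_lfc", "predicted_direction"])
    if site_panel is not None and len(df):
        wanted = set(site_panel)
        df = df[[(iso, pos) in wanted
                 for iso, pos in zip(df["isoform"], df["position"])]]
    df = df.sort_values(["isoform", "position", "ptm_class"]).reset_index(drop=True)
    df.to_csv(path, sep="\t", index=False)  # default float repr round-trips
    return df
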