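"""Differential interactome set analysis for drug-complex pulldowns.

Each protein's abundance in the Hsp90-drug complex is compared between a
knock-out and wild-type; proteins are called increased / decreased /
unchanged by a symmetric log2 fold-change threshold, and the calls from
the two knock-outs are partitioned into the shared/unique (Venn) cells
per direction.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "BinderTable",
    "VennCounts",
    "classify_binders",
    "venn_partition",
]

_DIRECTIONS = ("increased", "decreased", "unchanged")


class BinderTable:
    """Protein x condition abundances from an affinity-purification run.

    Wraps a DataFrame with columns ``protein_id, condition, abundance``;
    (protein, condition) pairs are unique, abundances non-negative, and a
    WT row is required for every protein that is to be classified.
    """

    def __init__(self, frame: pd.DataFrame, wt_condition: str = "WT"):
        missing = {"protein_id", "condition", "abundance"} - set(frame.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        if (frame["abundance"] < 0).any():
            raise ValueError("negative abundances")
        if frame.duplicated(subset=["protein_id", "condition"]).any():
            raise ValueError("duplicate (protein, condition) rows")
        self.frame = frame.reset_index(drop=True)
        self.wt_condition = wt_condition

    @classmethod
    def read_tsv(cls, path: str | Path, wt_condition: str = "WT") -> "BinderTable":
        return cls(pd.read_csv(path, sep="\t"), wt_condition=wt_condition)

    def write_tsv(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


def classify_binders(table: BinderTable, lfc_threshold: float = 1.0,
                     ko_conditions: tuple[str, str] = ("KO_a", "KO_b"),
                     ) -> pd.DataFrame:
    """Call each protein's binding change in each KO relative to WT.

    direction = increased if log2(KO/WT) > threshold, decreased if below
    -threshold, else unchanged. Presence/absence rule: a protein with zero
    abundance on one side only is called decreased (zero in KO) or
    increased (zero in WT) outright rather than dropped; zero on both
    sides is unchanged.
    """
    if lfc_threshold <= 0:
        raise ValueError("lfc_threshold must be > 0")
    wide = table.frame.pivot_table(index="protein_id", columns="condition",
                                   values="abundance", aggfunc="first")
    if table.wt_condition not in wide.columns:
        raise ValueError(f"no {table.wt_condition!r} rows in table")
    rows = []
    for pid, row in wide.iterrows():
        wt = row.get(table.wt_condition, np.nan)
        if np.isnan(wt):
            raise ValueError(f"protein {pid!r} has no WT row")
        entry = {"protein_id": pid}
        for ko in ko_conditions:
            ab = row.get(ko, np.nan)
            if np.isnan(ab):
                entry[ko] = "unchanged"  # not measured in this KO
            elif wt == 0 and ab == 0:
                entry[ko] = "unchanged"
            elif wt == 0:
                entry[ko] = "increased"
            elif ab == 0:
                entry[ko] = "decreased"
            else:
                x = np.log2(ab / wt)
                entry[ko] = ("increased" if x > lfc_threshold
                             else "decreased" if x < -lfc_threshold
                             else "unchanged")
        rows.append(entry)
    return pd.DataFrame(rows).set_index("protein_id")


@dataclass(frozen=True)
class VennCounts:
    """Shared/unique partition of differential binders, per direction."""

    decreased: dict[str, int]  # keys: only_a, only_b, both
    increased: dict[str, int]

    def total(self, direction: str) -> int:
        cells = getattr(self, direction)
        return cells["only_a"] + cells["only_b"] + cells["both"]


def venn_partition(classifications: pd.DataFrame,
                   ko_conditions: tuple[str, str] = ("KO_a", "KO_b"),
                   ) -> VennCounts:
    """Partition per-KO direction calls into disjoint Venn cells.

    A protein decreased in one KO and increased in the other contributes
    to the 'only' cell of each direction.
    """
    ko_a, ko_b = ko_conditions
    counts = {d: {"only_a": 0, "only_b": 0, "both": 0}
              for d in ("decreased", "increased")}
    for _pid, row in classifications.iterrows():
        for direction in ("decreased", "increased"):
            in_a = row[ko_a] == direction
            in_b = row[ko_b] == direction
            if in_a and in_b:
                counts[direction]["both"] += 1
            elif in_a:
                counts[direction]["only_a"] += 1
            elif in_b:
                counts[direction]["only_b"] += 1
    return VennCounts(decreased=counts["decreased"], increased=counts["increased"])
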