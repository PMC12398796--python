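"""The multi-label PTM class schema and residue eligibility rules.

The predictor emits 13 PTM classes covering the major modification groups
(phosphorylation, lysine/arginine methylation, acetylation, ubiquitination,
SUMOylation, N-/O-glycosylation, palmitoylation, hydroxylation). Each class
is chemically restricted to a set of acceptor residues; eligibility masking
uses these sets to zero predictions at residues that cannot carry the
modification (a glutamine cannot be acetylated on an epsilon-amine, etc.).
"""

from __future__ import annotations

from dataclasses import dataclass, field

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

_DEFAULT_CLASSES: tuple[tuple[str, frozenset[str]], ...] = (
    ("phospho_S", frozenset("S")),
    ("phospho_T", frozenset("T")),
    ("phospho_Y", frozenset("Y")),
    ("acetyl_K", frozenset("K")),
    ("methyl_K", frozenset("K")),
    ("methyl_R", frozenset("R")),
    ("ubiquitin_K", frozenset("K")),
    ("sumo_K", frozenset("K")),
    ("n_glyco_N", frozenset("N")),
    ("o_glyco_ST", frozenset("ST")),
    ("palmitoyl_C", frozenset("C")),
    ("hydroxyl_P", frozenset("P")),
    ("hydroxyl_K", frozenset("K")),
)


@dataclass(frozen=True)
class PTMLabelSchema:
    """Ordered PTM classes plus a class -> acceptor-residue map."""

    classes: tuple[str, ...] = tuple(c for c, _ in _DEFAULT_CLASSES)
    eligibility: dict[str, frozenset[str]] = field(
        default_factory=lambda: {c: r for c, r in _DEFAULT_CLASSES})

    def __post_init__(self):
        if len(self.classes) != len(set(self.classes)):
            raise ValueError("duplicate PTM class names")
        for c in self.classes:
            if c not in self.eligibility or not self.eligibility[c]:
                raise ValueError(f"class {c!r} has no eligible residues")

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    def index(self, ptm_type: str) -> int:
        return self.classes.index(ptm_type)

    def is_eligible(self, ptm_type: str, residue: str) -> bool:
        return residue.upper() in self.eligibility[ptm_type]

    def eligibility_matrix(self, sequence: str):
        """Boolean (len(sequence), n_classes) matrix of chemical eligibility."""
        import numpy as np

        mat = np.zeros((len(sequence), self.n_classes), dtype=bool)
        for j, c in enumerate(self.classes):
            allowed = self.eligibility[c]
            mat[:, j] = [aa in allowed for aa in sequence.upper()]
        return mat


DEFAULT_SCHEMA = PTMLabelSchema()
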