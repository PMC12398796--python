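"""Protein sequence handling: FASTA I/O, point mutants, the six-sequence
fine-tuning set, and explicit alpha/beta residue pairing for Hsp90.

Residue coordinates are 1-based everywhere in the public API (matching the
field's K283-style site naming); conversion to 0-based indices happens only
inside the encoder.

The packaged Hsp90 fixtures are *synthetic stand-ins*: deterministic
sequences with the real isoform lengths (alpha 732 aa, beta 724 aa) and the
correct residue identities at every site in the study panel, but not the
true HSP90AA1/HSP90AB1 sequences. Supply real isoform FASTA via
:func:`read_fasta` for analyses of the actual chaperone.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .schema import AMINO_ACIDS

__all__ = [
    "Isoform",
    "ProteinRecord",
    "MutationSpec",
    "PairedSite",
    "read_fasta",
    "write_fasta",
    "apply_mutation",
    "build_finetune_set",
    "map_site",
    "default_pairing_table",
    "load_hsp90_records",
    "DEFAULT_ALPHA_ACETYL_SITE",
    "DEFAULT_BETA_ACETYL_SITE",
]

_VALID = set(AMINO_ACIDS)


class Isoform(str, Enum):
    ALPHA = "alpha"
    BETA = "beta"
    OTHER = "other"


@dataclass(frozen=True)
class ProteinRecord:
    """An identified protein sequence with 1-based residue numbering."""

    id: str
    sequence: str
    isoform: Isoform = Isoform.OTHER

    def __post_init__(self):
        if not self.sequence:
            raise ValueError("empty sequence")
        bad = set(self.sequence) - _VALID
        if bad:
            raise ValueError(f"invalid residues in {self.id!r}: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sequence)

    def residue(self, position: int) -> str:
        """Residue letter at a 1-based position."""
        if not 1 <= position <= len(self.sequence):
            raise IndexError(f"position {position} outside 1..{len(self.sequence)}")
        return self.sequence[position - 1]


@dataclass(frozen=True)
class MutationSpec:
    """A point substitution, e.g. K283Q, in 1-based coordinates."""

    position: int
    ref: str
    alt: str

    def __post_init__(self):
        if self.position < 1:
            raise ValueError("position must be >= 1")
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")
        for aa in (self.ref, self.alt):
            if aa not in _VALID:
                raise ValueError(f"invalid residue letter {aa!r}")

    @property
    def label(self) -> str:
        return f"{self.ref}{self.position}{self.alt}"


@dataclass(frozen=True)
class PairedSite:
    """Equivalent residue positions on the two Hsp90 isoforms."""

    alpha_pos: int
    beta_pos: int


def _parse_fasta_record(rec: SeqRecord) -> ProteinRecord:
    seq = str(rec.seq).upper()
    bad = set(seq) - _VALID
    if bad:
        raise ValueError(
            f"record {rec.id!r}: illegal sequence characters {sorted(bad)} "
            "(only the 20 standard amino acids are accepted)")
    iso = Isoform.OTHER
    desc = (rec.description or rec.id).lower()
    if re.search(r"hsp90(aa1)?[\W_]*alpha|isoform[\W_]*alpha", desc):
        iso = Isoform.ALPHA
    elif re.search(r"hsp90(ab1)?[\W_]*beta|isoform[\W_]*beta", desc):
        iso = Isoform.BETA
    return ProteinRecord(id=rec.id, sequence=seq, isoform=iso)


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a protein FASTA; ids preserved, sequences upper-cased and
    validated against the 20-letter alphabet."""
    path = Path(path)
    records = [_parse_fasta_record(r) for r in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    seqrecords = [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records]
    SeqIO.write(seqrecords, str(Path(path)), "fasta")


def apply_mutation(record: ProteinRecord, m: MutationSpec) -> ProteinRecord:
    """Apply a point mutation, verifying the reference residue.

    The reference check guards against off-by-one and isoform mix-ups: the
    alpha and beta coordinate systems differ by 8 around the study sites,
    so a spec applied to the wrong isoform fails loudly here.
    """
    if m.position > len(record):
        raise IndexError(
            f"position {m.position} outside {record.id} (length {len(record)})")
    found = record.residue(m.position)
    if found != m.ref:
        raise ValueError(
            f"{record.id} position {m.position}: expected {m.ref!r}, found {found!r}")
    seq = record.sequence[:m.position - 1] + m.alt + record.sequence[m.position:]
    return replace(record, id=f"{record.id}_{m.label}", sequence=seq)


DEFAULT_ALPHA_ACETYL_SITE = 283  # hyperacetylated lysine on Hsp90alpha
DEFAULT_BETA_ACETYL_SITE = 275   # its counterpart on Hsp90beta


def build_finetune_set(alpha: ProteinRecord, beta: ProteinRecord,
                       alpha_site: int = DEFAULT_ALPHA_ACETYL_SITE,
                       beta_site: int = DEFAULT_BETA_ACETYL_SITE,
                       ) -> list[ProteinRecord]:
    """Build the six-sequence fine-tuning dataset.

    Returns exactly ``[alpha-WT, beta-WT, alpha-K->Q, alpha-K->R,
    beta-K->Q, beta-K->R]``: the two wild-type isoforms plus, for each, the
    acetylation-mimetic (K->Q) and acetylation-blocking (K->R) variant at
    the configured acetyl-lysine.
    """
    muts = []
    for rec, site in ((alpha, alpha_site), (beta, beta_site)):
        for alt in ("Q", "R"):
            muts.append(apply_mutation(rec, MutationSpec(site, "K", alt)))
    return [alpha, beta, muts[0], muts[1], muts[2], muts[3]]


# Paired alpha/beta positions printed in the study: the hyperacetylated
# K283/K275 pair, the hypoacetylated K362/K354 and K615/K607 pairs, and the
# T293/T285 phosphosite pair. No offset extrapolation beyond this table.
_DEFAULT_PAIRS: tuple[PairedSite, ...] = (
    PairedSite(283, 275),
    PairedSite(362, 354),
    PairedSite(615, 607),
    PairedSite(293, 285),
)


def default_pairing_table() -> list[PairedSite]:
    return list(_DEFAULT_PAIRS)


def map_site(pos: int, from_isoform: Isoform | str, to_isoform: Isoform | str,
             table: Sequence[PairedSite] | None = None) -> int:
    """Map a residue position between isoform coordinate systems using the
    explicit pairing table only (the divergent charged linker makes any
    constant-offset extrapolation unsafe)."""
    from_isoform = Isoform(from_isoform)
    to_isoform = Isoform(to_isoform)
    if Isoform.OTHER in (from_isoform, to_isoform):
        raise ValueError("mapping is defined between alpha and beta only")
    if from_isoform == to_isoform:
        return pos
    table = _DEFAULT_PAIRS if table is None else tuple(table)
    for pair in table:
        if from_isoform is Isoform.ALPHA and pair.alpha_pos == pos:
            return pair.beta_pos
        if from_isoform is Isoform.BETA and pair.beta_pos == pos:
            return pair.alpha_pos
    raise KeyError(
        f"no {from_isoform.value}->{to_isoform.value} pairing for position {pos}")


def load_hsp90_records() -> tuple[ProteinRecord, ProteinRecord]:
    """Load the packaged (synthetic stand-in) Hsp90 alpha/beta sequences."""
    ref = resources.files("ptm_crosstalk.data").joinpath("hsp90_synthetic.fasta")
    with resources.as_file(ref) as path:
        records = read_fasta(path)
    by_iso = {r.isoform: r for r in records}
    return by_iso[Isoform.ALPHA], by_iso[Isoform.BETA]
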