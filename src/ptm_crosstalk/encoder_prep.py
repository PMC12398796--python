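"""Sequence encoding for the PTM transformer.

Every input, regardless of protein length, is presented to the model as
fixed 514-token windows: a start token, up to 512 residue tokens, an end
token, then pad tokens. Proteins longer than 512 residues (both Hsp90
isoforms are) are split into overlapping windows and per-window predictions
are averaged over the overlap at merge time.

Token vocabulary: the 20 amino acids in alphabetical order (ids 0-19), then
start=20, end=21, pad=22. Positional information is injected as standard
128-dimensional sinusoidal encodings added to the learned token embeddings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .schema import AMINO_ACIDS
from .sequence_io import ProteinRecord

__all__ = [
    "WINDOW_LENGTH",
    "MAX_RESIDUES_PER_WINDOW",
    "WINDOW_OVERLAP",
    "START_ID",
    "END_ID",
    "PAD_ID",
    "VOCAB_SIZE",
    "TokenWindow",
    "tokenize",
    "detokenize",
    "positional_encoding",
    "merge_window_predictions",
]

WINDOW_LENGTH = 514               # uniform model input length
MAX_RESIDUES_PER_WINDOW = 512     # 514 minus the start/end specials
# Half-window overlap: consecutive windows advance by 256 residues, so any
# two positions up to 768 residues apart share at least one window. This
# matters for crosstalk analysis — a window that excludes the mutated
# residue cannot express the mutation's effect on the sites it covers.
WINDOW_OVERLAP = 256
_STRIDE = MAX_RESIDUES_PER_WINDOW - WINDOW_OVERLAP

_AA_TO_ID = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
START_ID = 20
END_ID = 21
PAD_ID = 22
VOCAB_SIZE = 23


@dataclass(frozen=True)
class TokenWindow:
    """One fixed-length model input covering a contiguous residue stretch.

    ``window_offset`` is the 0-based index (into the full protein) of the
    first residue in the window; ``valid_mask`` is True exactly at the
    residue token slots (never at start/end/pad).
    """

    token_ids: np.ndarray    # (514,) int
    window_offset: int
    valid_mask: np.ndarray   # (514,) bool

    def __post_init__(self):
        if self.token_ids.shape != (WINDOW_LENGTH,):
            raise ValueError("token_ids must have length 514")
        if self.valid_mask.shape != (WINDOW_LENGTH,):
            raise ValueError("valid_mask must have length 514")

    @property
    def n_residues(self) -> int:
        return int(self.valid_mask.sum())

    def residues(self) -> str:
        """Decode the residue letters covered by this window."""
        ids = self.token_ids[self.valid_mask]
        return "".join(AMINO_ACIDS[i] for i in ids)


def _encode_chunk(chunk: str, offset: int) -> TokenWindow:
    ids = np.full(WINDOW_LENGTH, PAD_ID, dtype=np.int64)
    mask = np.zeros(WINDOW_LENGTH, dtype=bool)
    ids[0] = START_ID
    for j, aa in enumerate(chunk):
        ids[1 + j] = _AA_TO_ID[aa]
        mask[1 + j] = True
    ids[1 + len(chunk)] = END_ID
    return TokenWindow(token_ids=ids, window_offset=offset, valid_mask=mask)


def tokenize(record: ProteinRecord) -> list[TokenWindow]:
    """Tokenize a protein into one or more 514-token windows.

    Sequences of <= 512 residues yield a single window; longer sequences
    are chunked into 512-residue windows advanced by 480 residues, so
    consecutive windows share 32 residues and every residue is covered.
    """
    seq = record.sequence
    bad = set(seq) - set(AMINO_ACIDS)
    if bad:
        raise ValueError(f"invalid residues {sorted(bad)} in {record.id!r}")
    n = len(seq)
    if n <= MAX_RESIDUES_PER_WINDOW:
        return [_encode_chunk(seq, 0)]
    offsets = list(range(0, n - WINDOW_OVERLAP, _STRIDE))
    windows = [_encode_chunk(seq[off:off + MAX_RESIDUES_PER_WINDOW], off)
               for off in offsets]
    return windows


def detokenize(windows: list[TokenWindow]) -> str:
    """Reconstruct the residue sequence from a window set.

    Inverse of :func:`tokenize`; raises if the windows leave a coverage gap
    or disagree on an overlap.
    """
    if not windows:
        raise ValueError("empty window set")
    length = max(w.window_offset + w.n_residues for w in windows)
    out: list[str | None] = [None] * length
    for w in windows:
        for j, aa in enumerate(w.residues()):
            pos = w.window_offset + j
            if out[pos] is None:
                out[pos] = aa
            elif out[pos] != aa:
                raise ValueError(f"inconsistent overlap at residue {pos + 1}")
    if any(c is None for c in out):
        missing = [i + 1 for i, c in enumerate(out) if c is None]
        raise ValueError(f"coverage gap at residues {missing[:5]}...")
    return "".join(out)  # type: ignore[arg-type]


def positional_encoding(length: int = WINDOW_LENGTH, dim: int = 128) -> np.ndarray:
    """Sinusoidal positional encodings.

    ``PE[pos, 2i] = sin(pos / 10000^(2i/dim))`` and
    ``PE[pos, 2i+1] = cos(pos / 10000^(2i/dim))`` — the standard
    transformer construction; every entry lies in [-1, 1].
    """
    if dim % 2:
        raise ValueError("positional encoding dimension must be even")
    pos = np.arange(length, dtype=np.float64)[:, None]
    i = np.arange(dim // 2, dtype=np.float64)[None, :]
    angle = pos / np.power(10000.0, 2.0 * i / dim)
    pe = np.empty((length, dim), dtype=np.float64)
    pe[:, 0::2] = np.sin(angle)
    pe[:, 1::2] = np.cos(angle)
    return pe


def merge_window_predictions(windows: list[TokenWindow],
                             predictions: list[np.ndarray]) -> np.ndarray:
    """Merge per-window per-residue predictions into one full-length matrix.

    Each prediction array has one row per residue covered by its window
    (window order matches `windows`). Residues covered by several windows
    receive the arithmetic mean of the windows' rows.
    """
    if len(windows) != len(predictions):
        raise ValueError("windows and predictions differ in length")
    if not windows:
        raise ValueError("empty window set")
    length = max(w.window_offset + w.n_residues for w in windows)
    n_classes = predictions[0].shape[1]
    total = np.zeros((length, n_classes), dtype=np.float64)
    count = np.zeros(length, dtype=np.int64)
    for w, p in zip(windows, predictions):
        if p.shape != (w.n_residues, n_classes):
            raise ValueError(
                f"prediction shape {p.shape} does not match window "
                f"({w.n_residues} residues, {n_classes} classes)")
        sl = slice(w.window_offset, w.window_offset + w.n_residues)
        total[sl] += p
        count[sl] += 1
    if (count == 0).any():
        missing = np.flatnonzero(count == 0) + 1
        raise ValueError(f"coverage gap at residues {missing[:5].tolist()}...")
    return total / count[:, None]
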