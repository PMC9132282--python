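"""Phosphoacceptor-centered sequence windows.

A phosphosite is described by a protein accession, a 1-based residue
position and the acceptor residue (S, T or Y).  Motif scoring operates on a
fixed-length window of residues centered on the acceptor (default +/-7,
i.e. 15 residues).  Positions falling outside the protein are padded with
``'-'``; non-standard residues (U, B, Z, O, J, *) are mapped to ``'X'``.
Both symbols are excluded from the 20-letter counting alphabet but are
tracked explicitly, because downstream pseudocount rules consume pad
counts.

Coordinate convention: phosphosite positions are 1-based (database
convention); internal slices are 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InputError, ValidationError

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
PAD = "-"
UNKNOWN = "X"
PAD_CODE = 20
UNKNOWN_CODE = 21
N_SYMBOLS = 22  # 20 residues + pad + unknown

#: site classes
SITE_CLASS_ST = "S/T"
SITE_CLASS_Y = "Y"
SITE_CLASS_OTHER = "other"

_NONSTANDARD = str.maketrans({c: UNKNOWN for c in "UBZOJ*"})


def sanitize_sequence(sequence: str) -> str:
    """Uppercase a protein sequence and map non-standard residues to 'X'."""
    return sequence.upper().translate(_NONSTANDARD)


def residue_site_class(residue: str) -> str:
    if residue in ("S", "T"):
        return SITE_CLASS_ST
    if residue == "Y":
        return SITE_CLASS_Y
    return SITE_CLASS_OTHER


@dataclass(frozen=True)
class Phosphosite:
    """A phosphoacceptor residue on a protein (1-based position)."""

    protein_id: str
    position: int
    residue: str

    @property
    def site_class(self) -> str:
        return residue_site_class(self.residue)

    def validate(self, sequence: str, strict: bool = True) -> bool:
        """Check the site against its source sequence.

        Returns True when the recorded acceptor matches the sequence.  In
        strict mode a mismatch (or out-of-range position) raises
        :class:`ValidationError`; in permissive mode it returns False so
        callers can flag isoform drift without aborting.
        """
        if not 1 <= self.position <= len(sequence):
            if strict:
                raise ValidationError(
                    f"{self.protein_id}: position {self.position} outside "
                    f"sequence of length {len(sequence)}"
                )
            return False
        observed = sanitize_sequence(sequence)[self.position - 1]
        if observed != self.residue:
            if strict:
                raise ValidationError(
                    f"{self.protein_id}@{self.position}: recorded residue "
                    f"{self.residue!r} but sequence has {observed!r}"
                )
            return False
        return True


@dataclass(frozen=True)
class SequenceWindow:
    """Fixed-length residue context around a phosphoacceptor.

    ``residues`` has odd length (default 15); the acceptor sits at the
    central index.  Pad symbols occur only as a contiguous prefix/suffix of
    lengths ``n_pad_left``/``n_pad_right``.
    """

    residues: str
    n_pad_left: int = 0
    n_pad_right: int = 0

    def __post_init__(self):
        n = len(self.residues)
        if n % 2 != 1:
            raise InputError(f"window length must be odd, got {n}")
        c = n // 2
        if self.residues[c] == PAD:
            raise InputError("center residue must not be the pad symbol")
        if (self.residues[: self.n_pad_left] != PAD * self.n_pad_left
                or self.residues[n - self.n_pad_right:] != PAD * self.n_pad_right):
            raise InputError("pad symbols must be a contiguous prefix/suffix")
        interior = self.residues[self.n_pad_left: n - self.n_pad_right]
        if PAD in interior:
            raise InputError("pad symbols inside the window interior")

    @property
    def center_index(self) -> int:
        return len(self.residues) // 2

    @property
    def center(self) -> str:
        return self.residues[self.center_index]

    def __len__(self) -> int:
        return len(self.residues)


def extract_window(sequence: str, position: int, flank: int = 7) -> SequenceWindow:
    """Extract the (2*flank+1)-residue window centered on ``position``.

    ``position`` is 1-based.  Window positions outside the protein are
    filled with the pad symbol and the pad counts recorded.
    """
    if not sequence:
        raise InputError("empty sequence")
    if flank < 0:
        raise InputError("flank must be >= 0")
    if not 1 <= position <= len(sequence):
        raise IndexError(
            f"position {position} out of range for sequence of length {len(sequence)}"
        )
    seq = sanitize_sequence(sequence)
    c = position - 1  # 0-based center
    lo = c - flank
    hi = c + flank + 1  # half-open
    n_pad_left = max(0, -lo)
    n_pad_right = max(0, hi - len(seq))
    core = seq[max(0, lo): min(len(seq), hi)]
    return SequenceWindow(
        residues=PAD * n_pad_left + core + PAD * n_pad_right,
        n_pad_left=n_pad_left,
        n_pad_right=n_pad_right,
    )


def window_from_string(residues: str) -> SequenceWindow:
    """Build a window from a raw string, inferring pad counts."""
    residues = sanitize_sequence(residues).replace(".", PAD)
    n = len(residues)
    left = n - len(residues.lstrip(PAD))
    right = n - len(residues.rstrip(PAD))
    return SequenceWindow(residues=residues, n_pad_left=left, n_pad_right=right)


def classify_site(window: SequenceWindow, strict: bool = True) -> str:
    """Classify a window's acceptor as S/T, Y, or (permissively) other."""
    cls = residue_site_class(window.center)
    if cls == SITE_CLASS_OTHER and strict:
        raise ValidationError(
            f"center residue {window.center!r} is not an accepted phosphoacceptor"
        )
    return cls


def encode_window(window: SequenceWindow | str) -> np.ndarray:
    """Encode a window as integer codes (0-19 residues, 20 pad, 21 unknown)."""
    residues = window.residues if isinstance(window, SequenceWindow) else window
    codes = np.empty(len(residues), dtype=np.int8)
    for i, ch in enumerate(residues):
        if ch == PAD:
            codes[i] = PAD_CODE
        elif ch == UNKNOWN:
            codes[i] = UNKNOWN_CODE
        else:
            try:
                codes[i] = AA_INDEX[ch]
            except KeyError:
                raise InputError(f"residue {ch!r} not in alphabet") from None
    return codes


def encode_windows(windows) -> np.ndarray:
    """Stack encodings of same-length windows into an (n, L) int array."""
    if len(windows) == 0:
        raise InputError("no windows to encode")
    mat = np.vstack([encode_window(w) for w in windows])
    if len(set(mat.shape[1:])) > 1:  # pragma: no cover - vstack already errors
        raise InputError("windows of unequal length")
    return mat


def decode_window(codes: np.ndarray) -> str:
    symbols = AMINO_ACIDS + PAD + UNKNOWN
    return "".join(symbols[c] for c in codes)
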