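"""Alignment and matrix file I/O.

Protein alignments are read from FASTA into an integer-coded representation
over an extended 22-symbol alphabet: the 20 standard amino acids, one gap
symbol, and one placeholder for any non-standard residue code. Matrices move
between the compute and visualization stages in a plain-text triple-per-line
format, one cell per line as ``row column value`` with 1-based alignment
positions, so residue numbering in exported files matches biologist
convention (e.g. "Y70").
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import AlignmentError, InputError, ParseError

logger = logging.getLogger("coevomi")

# --- extended alphabet ------------------------------------------------------

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
NON_STANDARD = "X"  # rendered symbol for every non-standard residue code
#: Ordered 22-symbol alphabet; index in this string is the integer code.
ALPHABET = AMINO_ACIDS + GAP + NON_STANDARD
ALPHABET_SIZE = len(ALPHABET)  # 22

GAP_CODE = ALPHABET.index(GAP)  # 20
NON_STANDARD_CODE = ALPHABET.index(NON_STANDARD)  # 21

_ENCODE = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
_ENCODE[GAP] = GAP_CODE
_ENCODE["."] = GAP_CODE  # alternate gap character used by some aligners


def encode_symbol(ch: str) -> int:
    """Map one residue character to its alphabet code (case-insensitive).

    Anything that is not a standard amino acid or a gap character maps to the
    non-standard placeholder (this covers ambiguity codes such as B, Z, J and
    the rare residues U and O).
    """
    return _ENCODE.get(ch.upper(), NON_STANDARD_CODE)


def decode_symbol(code: int) -> str:
    """Inverse of :func:`encode_symbol` on the 22 canonical codes."""
    return ALPHABET[code]


def encode_sequence(seq: str) -> np.ndarray:
    return np.fromiter((encode_symbol(c) for c in seq), dtype=np.uint8, count=len(seq))


def decode_sequence(codes: Iterable[int]) -> str:
    return "".join(ALPHABET[c] for c in codes)


def as_codes(col) -> np.ndarray:
    """Coerce a symbol vector (string, list of chars, or code array) to codes."""
    if isinstance(col, str):
        return encode_sequence(col)
    arr = np.asarray(col)
    if arr.dtype.kind in "US":
        return np.fromiter((encode_symbol(str(c)) for c in arr), dtype=np.uint8,
                           count=arr.size)
    return arr.astype(np.uint8, copy=False)


# --- alignment container ----------------------------------------------------

@dataclass
class Alignment:
    """An aligned set of sequences, integer-coded over the extended alphabet.

    ``codes`` has shape (n_sequences, n_columns); row order is FASTA record
    order, which also serves as sequence identity.
    """

    ids: list[str]
    codes: np.ndarray = field(repr=False)

    def __post_init__(self):
        self.codes = np.asarray(self.codes, dtype=np.uint8)
        if self.codes.ndim != 2:
            raise AlignmentError("alignment codes must be a 2-D array")
        if len(self.ids) != self.codes.shape[0]:
            raise AlignmentError("number of ids does not match number of rows")

    @property
    def n_sequences(self) -> int:
        return self.codes.shape[0]

    @property
    def n_columns(self) -> int:
        return self.codes.shape[1]

    def column(self, j: int) -> np.ndarray:
        return get_column(self, j)


def read_fasta(path) -> Alignment:
    """Read an aligned FASTA file into an :class:`Alignment`.

    Requires at least two records of identical length; residues are encoded
    case-insensitively through the extended alphabet. Ragged records raise
    :class:`AlignmentError` naming the offending record.
    """
    path = Path(path)
    try:
        with open(path) as fh:
            head = fh.read(1)
            fh.seek(0)
            if head and head not in (">", ";"):
                raise ParseError(f"{path}: not FASTA (first record has no '>' header)")
            records = list(SeqIO.parse(fh, "fasta"))
    except ValueError as exc:  # Biopython parse failure
        raise ParseError(f"{path}: {exc}") from exc
    if not records:
        raise InputError(f"{path}: no FASTA records found")
    if len(records) < 2:
        raise InputError(f"{path}: an alignment needs at least 2 sequences, got 1")

    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        logger.warning("duplicate FASTA ids in %s; record order is identity", path)

    length = len(records[0].seq)
    rows = np.empty((len(records), length), dtype=np.uint8)
    for k, rec in enumerate(records):
        s = str(rec.seq)
        if len(s) == 0:
            raise InputError(f"{path}: record '{rec.id}' is empty")
        if len(s) != length:
            raise AlignmentError(
                f"{path}: record '{rec.id}' has length {len(s)}, "
                f"expected {length} (ragged alignment)"
            )
        rows[k] = encode_sequence(s)
    return Alignment(ids=ids, codes=rows)


def write_fasta(aln: Alignment, path) -> None:
    """Write an alignment back to FASTA (decoded through the alphabet)."""
    records = [
        SeqRecord(Seq(decode_sequence(row)), id=name, description="")
        for name, row in zip(aln.ids, aln.codes)
    ]
    SeqIO.write(records, str(path), "fasta")


def get_column(aln: Alignment, j: int) -> np.ndarray:
    """Return alignment column ``j`` (1-based) top-to-bottom in record order."""
    if not 1 <= j <= aln.n_columns:
        raise IndexError(f"column {j} out of range 1..{aln.n_columns}")
    return aln.codes[:, j - 1].copy()


# --- triple-per-line matrix format ------------------------------------------

def write_matrix_triples(m: np.ndarray, path, mask: np.ndarray | None = None,
                         header: str | None = None) -> None:
    """Write matrix cells as ``row column value`` lines, 1-based, row-major.

    NaN cells are treated as masked/undefined and omitted, as are cells where
    an optional boolean ``mask`` is False. Values are written with 17
    significant digits so a write->read round trip is lossless for doubles.
    """
    m = np.asarray(m, dtype=float)
    if m.ndim != 2:
        raise InputError("matrix must be 2-D")
    keep = np.isfinite(m)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != m.shape:
            raise InputError("mask shape does not match matrix shape")
        keep &= mask
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        for i, j in zip(*np.nonzero(keep)):
            fh.write(f"{i + 1} {j + 1} {m[i, j]:.17g}\n")


def read_matrix_triples(path) -> np.ndarray:
    """Read a triple-per-line matrix file into a dense array.

    Fields may be separated by whitespace or commas; blank lines and lines
    starting with ``#`` are ignored. Cells absent from the file are NaN
    (missing); no symmetric completion is applied. Duplicate cells raise
    :class:`InputError`, unparseable lines :class:`ParseError` with the line
    number.
    """
    entries: dict[tuple[int, int], float] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.replace(",", " ").split()
            if len(fields) != 3:
                raise ParseError(
                    f"expected 'row column value', got {len(fields)} fields",
                    line=lineno,
                )
            try:
                r, c = int(fields[0]), int(fields[1])
                v = float(fields[2])
            except ValueError as exc:
                raise ParseError(str(exc), line=lineno) from exc
            if r < 1 or c < 1:
                raise ParseError("indices must be >= 1", line=lineno)
            if (r, c) in entries:
                raise InputError(f"{path}: duplicate cell ({r}, {c}) at line {lineno}")
            entries[(r, c)] = v
    if not entries:
        raise InputError(f"{path}: no matrix entries found")
    n_rows = max(r for r, _ in entries)
    n_cols = max(c for _, c in entries)
    m = np.full((n_rows, n_cols), np.nan)
    for (r, c), v in entries.items():
        m[r - 1, c - 1] = v
    return m
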