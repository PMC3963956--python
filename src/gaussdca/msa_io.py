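"""Alignment input/output and integer / one-hot encoding.

Reads aligned FASTA and Stockholm (Pfam dialect) files, cleans them into an
integer-coded alignment over a 21-letter alphabet (gap + 20 amino acids in
alphabetical order), and produces the binary (q-1 one-hot) encoding in which
each column maps to 20 indicator variables and the gap maps to an all-zero
block.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO

#: Canonical alphabet: index 0 is the gap, 1..20 the amino acids in
#: alphabetical one-letter order.  Shared by every module.
ALPHABET = "-ACDEFGHIKLMNPQRSTVWY"

#: Amino-acid codes with no slot in the 20-letter one-hot scheme; mapped to
#: the gap class (index 0).
AMBIGUOUS = frozenset("BJOUXZ")

_INDEX = {c: i for i, c in enumerate(ALPHABET)}


class AlignmentFormatError(ValueError):
    """Raised when an input alignment cannot be interpreted."""


class EmptyAlignmentError(ValueError):
    """Raised when cleaning leaves no sequences."""


@dataclass
class RawAlignment:
    """Sequences as read from disk, before cleaning.

    ``records`` holds ``(id, seq)`` pairs; sequences may contain upper- and
    lowercase letters, ``-`` (deletion) and ``.`` (insert gap).  Lowercase
    letters and ``.`` mark insert states relative to the match columns.
    """

    records: list[tuple[str, str]]

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class Alignment:
    """Integer-coded MSA: ``symbols`` is M x N with values in ``0..q-1``.

    Index 0 is the gap class; for protein data (q = 21) indices 1..20 follow
    :data:`ALPHABET`.  Synthetic alignments may use smaller alphabets.
    """

    symbols: np.ndarray
    ids: list[str] = field(default_factory=list)
    q: int = 21

    def __post_init__(self) -> None:
        self.symbols = np.ascontiguousarray(self.symbols, dtype=np.int8)
        if self.symbols.ndim != 2:
            raise ValueError("symbols must be a 2-d matrix")
        if self.symbols.size and (
            self.symbols.min() < 0 or self.symbols.max() >= self.q
        ):
            raise ValueError(f"symbol out of range for q={self.q}")
        if not self.ids:
            self.ids = [f"seq{m+1}" for m in range(self.symbols.shape[0])]
        if len(self.ids) != self.symbols.shape[0]:
            raise ValueError("ids/symbols row mismatch")

    @property
    def M(self) -> int:
        return self.symbols.shape[0]

    @property
    def N(self) -> int:
        return self.symbols.shape[1]

    def to_sequences(self) -> list[str]:
        """Decode to letter strings; symbol k maps to ALPHABET[k]."""
        if self.q > len(ALPHABET):
            raise ValueError("alphabet too large to decode")
        lut = np.frombuffer(ALPHABET.encode(), dtype="S1")
        return [
            b"".join(lut[row]).decode() for row in np.asarray(self.symbols)
        ]


def _matched_only(seq: str) -> str:
    """Drop insert states (lowercase letters and '.')."""
    return "".join(c for c in seq if not (c.islower() or c == "."))


def _parse_stockholm(path) -> list[tuple[str, str]]:
    """Pfam-dialect Stockholm reader that preserves the '.'/'-' distinction.

    (Generic Stockholm parsers normalise '.' to '-', which erases the
    insert-gap / match-gap distinction the cleaning step relies on.)
    Handles interleaved blocks; '#' annotation lines and '//' are skipped.
    """
    seqs: dict[str, list[str]] = {}
    order: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("//"):
                continue
            parts = line.split(None, 1)
            if len(parts) != 2:
                raise AlignmentFormatError(
                    f"malformed Stockholm sequence line: {line!r}"
                )
            name, chunk = parts
            if name not in seqs:
                seqs[name] = []
                order.append(name)
            seqs[name].append(chunk.replace(" ", ""))
    return [(name, "".join(seqs[name])) for name in order]


def read_alignment(path, format: str = "fasta") -> RawAlignment:
    """Read an aligned FASTA or Stockholm file.

    Stockholm annotation lines (``#=GC`` etc.) are ignored; one record per
    sequence, file order preserved.  Raises :class:`AlignmentFormatError`
    when the matched-column lengths disagree, naming the offending record.
    """
    format = format.lower()
    if format not in ("fasta", "stockholm"):
        raise ValueError(f"unsupported alignment format: {format!r}")
    try:
        if format == "stockholm":
            records = _parse_stockholm(path)
        else:
            records = [
                (r.id, str(r.seq)) for r in SeqIO.parse(str(path), format)
            ]
    except FileNotFoundError:
        raise
    except AlignmentFormatError:
        raise
    except Exception as exc:  # Biopython raises assorted ValueErrors
        raise AlignmentFormatError(f"cannot parse {path} as {format}: {exc}")
    if not records:
        raise AlignmentFormatError(f"no sequences found in {path}")
    ref_len = len(_matched_only(records[0][1]))
    for k, (rid, seq) in enumerate(records, start=1):
        n = len(_matched_only(seq))
        if n != ref_len:
            raise AlignmentFormatError(
                f"record {k} ({rid!r}) has {n} matched columns, "
                f"expected {ref_len}"
            )
    return RawAlignment(records)


def preprocess(raw: RawAlignment, max_gap_fraction: float = 0.9) -> Alignment:
    """Clean a raw alignment into an integer-coded :class:`Alignment`.

    Removes insert states (lowercase, '.'), maps ``-`` and the ambiguous
    codes B, J, O, U, X, Z to the gap class, and drops every sequence whose
    gap fraction is ``>= max_gap_fraction`` (i.e. a sequence that is 90% or
    more gaps is removed under the default).
    """
    if not raw.records:
        raise EmptyAlignmentError("empty input alignment")
    rows, ids = [], []
    n_cols = None
    for rid, seq in raw.records:
        matched = _matched_only(seq).upper()
        if n_cols is None:
            n_cols = len(matched)
        elif len(matched) != n_cols:
            raise AlignmentFormatError(
                f"record {rid!r}: ragged matched-column length"
            )
        row = np.array(
            [0 if c in AMBIGUOUS else _INDEX.get(c, 0) for c in matched],
            dtype=np.int8,
        )
        if n_cols and (row == 0).sum() / n_cols >= max_gap_fraction:
            continue
        rows.append(row)
        ids.append(rid)
    if not rows:
        raise EmptyAlignmentError(
            "all sequences removed by the gap-fraction filter"
        )
    return Alignment(np.vstack(rows), ids=ids, q=21)


def encode_onehot(aln: Alignment) -> np.ndarray:
    """Binary (q-1)-state one-hot encoding, an M x ((q-1)*N) 0/1 matrix.

    Row m, block i carries a single 1 at slot ``symbols[m, i]`` when the
    symbol is a residue; the gap (symbol 0) leaves the whole block zero.
    """
    M, N = aln.symbols.shape
    s = aln.q - 1
    X = np.zeros((M, s * N), dtype=np.float64)
    cols = np.arange(N) * s
    sym = np.asarray(aln.symbols, dtype=np.int64)
    rows_idx, col_idx = np.nonzero(sym)
    X[rows_idx, cols[col_idx] + sym[rows_idx, col_idx] - 1] = 1.0
    return X


def write_ranked_pairs(pairs, scores, path, header: bool = False) -> None:
    """Write ranked pairs as plain text rows ``i j score`` (1-based, i < j).

    The caller supplies pairs already ranked; order is preserved verbatim so
    ties keep their incoming (lexicographic) order.
    """
    out = sys.stdout if path in ("-", None) else open(path, "w")
    try:
        if header:
            out.write("i\tj\tscore\n")
        for (i, j), s in zip(pairs, scores):
            out.write(f"{i} {j} {s!r}\n")
    finally:
        if out is not sys.stdout:
            out.close()


def write_fasta(aln: Alignment, path) -> None:
    """Write a (protein) alignment back to aligned FASTA."""
    with open(path, "w") as fh:
        for rid, seq in zip(aln.ids, aln.to_sequences()):
            fh.write(f">{rid}\n{seq}\n")
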