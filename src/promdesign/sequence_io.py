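"""Reading, validation and encoding of fixed-length promoter corpora.

A corpus is a list of :class:`PromoterRecord`: an identifier, a DNA
sequence over the strict four-letter alphabet ``{A, C, G, T}`` and an
optional strictly positive strength (an expression proxy in arbitrary
units).  Sequences are uppercased on input and validated character by
character; ambiguity codes such as ``N`` are rejected rather than
imputed.  Error messages report 1-based sequence offsets; all internal
indexing is 0-based.

One-hot encoding uses the fixed column order ``(A, C, G, T)`` throughout
the package so that feature tensors from different modules always align.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

__all__ = [
    "BASES",
    "BASE_INDEX",
    "PromoterRecord",
    "read_fasta",
    "write_fasta",
    "read_strengths",
    "write_strengths",
    "attach_strengths",
    "one_hot_encode",
    "one_hot_decode",
]

#: Fixed base order used for every one-hot / count feature in the package.
BASES = ("A", "C", "G", "T")
BASE_INDEX = {b: i for i, b in enumerate(BASES)}


class SequenceValidationError(ValueError):
    """A sequence violates the corpus contract (alphabet or length)."""


@dataclass(frozen=True)
class PromoterRecord:
    """One promoter: id, fixed-length ACGT sequence, optional strength."""

    id: str
    sequence: str
    strength: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", _validate_sequence(self.sequence, self.id))
        if self.strength is not None:
            s = float(self.strength)
            if not np.isfinite(s) or s <= 0:
                raise ValueError(
                    f"record {self.id!r}: strength must be finite and > 0, got {self.strength}"
                )
            object.__setattr__(self, "strength", s)

    def __len__(self) -> int:
        return len(self.sequence)


def _validate_sequence(seq: str, record_id: str) -> str:
    seq = seq.upper()
    for off, ch in enumerate(seq):
        if ch not in BASE_INDEX:
            raise SequenceValidationError(
                f"record {record_id!r}: invalid character {ch!r} at position {off + 1} "
                "(alphabet is A/C/G/T; ambiguity codes are rejected)"
            )
    return seq


def read_fasta(path: str | Path, expected_length: int | None = None) -> list[PromoterRecord]:
    """Read a multi-record FASTA file into a list of :class:`PromoterRecord`.

    Records are returned in file order; ids are the header token up to the
    first whitespace.  If ``expected_length`` is given, every sequence must
    have exactly that length.
    """
    records: list[PromoterRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        pr = PromoterRecord(id=rec.id, sequence=str(rec.seq))
        if expected_length is not None and len(pr) != expected_length:
            raise SequenceValidationError(
                f"record {pr.id!r}: length {len(pr)} != expected {expected_length}"
            )
        records.append(pr)
    return records


def write_fasta(records: Iterable[PromoterRecord], path: str | Path) -> None:
    """Write records as unwrapped FASTA, in input order."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.sequence}\n")


def read_strengths(path: str | Path) -> dict[str, float]:
    """Read a two-column (id, strength) TSV into an ordered id->strength map.

    A first line whose second field does not parse as a number is treated
    as a header and skipped.  Duplicate ids and non-positive strengths are
    errors: the downstream log transform requires strict positivity.
    """
    strengths: dict[str, float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(f"{path}: line {lineno}: expected 2 tab-separated fields")
            ident, raw = fields[0].strip(), fields[1].strip()
            try:
                value = float(raw)
            except ValueError:
                if lineno == 1:  # optional header
                    continue
                raise ValueError(f"{path}: line {lineno}: unparseable strength {raw!r}")
            if ident in strengths:
                raise ValueError(f"{path}: line {lineno}: duplicate id {ident!r}")
            if not np.isfinite(value) or value <= 0:
                raise ValueError(
                    f"{path}: line {lineno}: strength for {ident!r} must be > 0, got {raw}"
                )
            strengths[ident] = value
    return strengths


def write_strengths(strengths: dict[str, float], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("id\tstrength\n")
        for ident, value in strengths.items():
            fh.write(f"{ident}\t{value:.10g}\n")


def attach_strengths(
    records: Sequence[PromoterRecord], strengths: dict[str, float]
) -> list[PromoterRecord]:
    """Return records with strengths attached; every record must be covered."""
    out = []
    for rec in records:
        if rec.id not in strengths:
            raise KeyError(f"no strength for record {rec.id!r}")
        out.append(PromoterRecord(rec.id, rec.sequence, strengths[rec.id]))
    return out


def one_hot_encode(sequence: str) -> np.ndarray:
    """Encode a DNA string as an L x 4 binary matrix, columns (A, C, G, T)."""
    sequence = _validate_sequence(sequence, "<anonymous>")
    mat = np.zeros((len(sequence), 4), dtype=np.float64)
    for i, ch in enumerate(sequence):
        mat[i, BASE_INDEX[ch]] = 1.0
    return mat


def one_hot_decode(matrix: np.ndarray) -> str:
    """Inverse of :func:`one_hot_encode` (argmax over the base axis)."""
    matrix = np.asarray(matrix)
    if matrix.ndim != 2 or matrix.shape[1] != 4:
        raise ValueError(f"expected an L x 4 matrix, got shape {matrix.shape}")
    return "".join(BASES[j] for j in matrix.argmax(axis=1))
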