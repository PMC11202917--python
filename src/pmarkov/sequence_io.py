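"""Sequence input: FASTA / plain-text readers, alphabet validation, symbol counts.

Sequences are modelled as strings over a small, fixed, ordered alphabet
(for DNA: ``a, c, g, t``).  All characters are lower-cased on read.  Characters
outside the alphabet either abort the read (``unknown_policy="error"``) or
split the record into segments (``unknown_policy="split"``) so that no
transition is ever counted across a removed symbol.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO

__all__ = [
    "Alphabet",
    "Sequence",
    "DNA",
    "read_fasta",
    "read_plain",
    "symbol_frequencies",
]


@dataclass(frozen=True)
class Alphabet:
    """An ordered alphabet of distinct single characters.

    The ordering is fixed and used everywhere a table is emitted
    (column order of count matrices, probability rows, ...).
    """

    symbols: tuple[str, ...]
    _index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __init__(self, symbols: Iterable[str]):
        syms = tuple(symbols)
        if len(syms) < 2:
            raise ValueError("alphabet needs at least 2 symbols")
        if len(set(syms)) != len(syms):
            raise ValueError(f"alphabet symbols are not unique: {syms!r}")
        for s in syms:
            if len(s) != 1:
                raise ValueError(f"alphabet symbols must be single characters, got {s!r}")
        object.__setattr__(self, "symbols", syms)
        object.__setattr__(self, "_index", {s: i for i, s in enumerate(syms)})

    @property
    def size(self) -> int:
        return len(self.symbols)

    def index(self, symbol: str) -> int:
        return self._index[symbol]

    def __contains__(self, symbol: str) -> bool:
        return symbol in self._index

    def __iter__(self):
        return iter(self.symbols)

    def __len__(self) -> int:
        return len(self.symbols)


#: The DNA alphabet used throughout the genomic application.
DNA = Alphabet("acgt")


@dataclass(frozen=True)
class Sequence:
    """A validated sequence over an :class:`Alphabet`."""

    id: str
    symbols: str

    @property
    def length(self) -> int:
        return len(self.symbols)

    def __len__(self) -> int:
        return len(self.symbols)


def _validate(symbols: str, alphabet: Alphabet, where: str) -> None:
    for pos, ch in enumerate(symbols):
        if ch not in alphabet:
            raise ValueError(
                f"{where}: symbol {ch!r} at position {pos + 1} is not in the "
                f"alphabet {{{','.join(alphabet.symbols)}}}"
            )


def _segment(record_id: str, symbols: str, alphabet: Alphabet) -> list[Sequence]:
    """Split at non-alphabet characters; drop empty segments; suffix ids."""
    pattern = "[^" + re.escape("".join(alphabet.symbols)) + "]+"
    parts = [p for p in re.split(pattern, symbols) if p]
    if len(parts) == 1 and parts[0] == symbols:
        return [Sequence(record_id, symbols)]
    return [Sequence(f"{record_id}/{k}", p) for k, p in enumerate(parts, start=1)]


def read_fasta(
    path: str | Path,
    alphabet: Alphabet = DNA,
    unknown_policy: str = "error",
) -> list[Sequence]:
    """Read a (possibly multi-record, possibly line-wrapped) FASTA file.

    Parameters
    ----------
    path:
        FASTA file path.
    alphabet:
        The declared alphabet; all symbols are lower-cased before validation.
    unknown_policy:
        ``"error"``: any character outside the alphabet aborts with an error
        naming the record and position.  ``"split"``: each record is divided at
        runs of non-alphabet characters (e.g. ambiguity codes such as ``N``)
        into segments returned as separate sequences with ids suffixed
        ``/1, /2, ...``, so that no transition can later span a removed symbol.
    """
    if unknown_policy not in ("error", "split"):
        raise ValueError(f"unknown_policy must be 'error' or 'split', got {unknown_policy!r}")
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    out: list[Sequence] = []
    for rec in records:
        body = str(rec.seq).lower()
        if not body:
            raise ValueError(f"{path}: record {rec.id!r} is empty")
        if unknown_policy == "error":
            _validate(body, alphabet, f"{path}: record {rec.id!r}")
            out.append(Sequence(rec.id, body))
        else:
            segs = _segment(rec.id, body, alphabet)
            if not segs:
                raise ValueError(
                    f"{path}: record {rec.id!r} contains no alphabet symbols"
                )
            out.extend(segs)
    return out


def read_plain(
    path: str | Path,
    alphabet: Alphabet = DNA,
    unknown_policy: str = "error",
    id: str | None = None,
) -> list[Sequence]:
    """Read one sequence from a plain-text file, ignoring all whitespace."""
    path = Path(path)
    body = "".join(path.read_text().split()).lower()
    if not body:
        raise ValueError(f"{path}: file contains no symbols")
    seq_id = id if id is not None else path.stem
    if unknown_policy == "error":
        _validate(body, alphabet, str(path))
        return [Sequence(seq_id, body)]
    return _segment(seq_id, body, alphabet)


def symbol_frequencies(seq: Sequence, alphabet: Alphabet = DNA) -> dict[str, int]:
    """Count each alphabet symbol over the whole sequence.

    The counts sum to ``seq.length``; symbols never seen get count 0.
    """
    _validate(seq.symbols, alphabet, f"sequence {seq.id!r}")
    return {a: seq.symbols.count(a) for a in alphabet.symbols}
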