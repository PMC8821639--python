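"""FASTA input/output and the SequenceRecord container.

Normalization policy on read: sequences are uppercased; the gap characters
``-`` and ``.`` are stripped; any remaining character outside the residue
alphabet is mapped to ``X`` with a warning (or raises in strict mode).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from os import PathLike
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

from .alphabet import DEFAULT_ALPHABET, ResidueAlphabet


class Label(str, Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"
    UNKNOWN = "unknown"


@dataclass
class SequenceRecord:
    """One protein sequence with identifier, class label, and family tag."""

    id: str
    sequence: str
    label: Label = Label.UNKNOWN
    family: Optional[str] = None
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be nonempty")
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: sequence must be nonempty")
        if any(c.isspace() for c in self.sequence):
            raise ValueError(f"record {self.id!r}: sequence contains whitespace")
        self.label = Label(self.label)

    def __len__(self) -> int:
        return len(self.sequence)


_STRIP_CHARS = "-."


def _normalize(
    raw: str,
    record_id: str,
    alphabet: ResidueAlphabet,
    strict: bool,
) -> str:
    seq = raw.upper()
    seq = "".join(c for c in seq if c not in _STRIP_CHARS)
    allowed = set(alphabet.residue_symbols)
    out = []
    for pos, c in enumerate(seq):
        if c in allowed:
            out.append(c)
        elif strict:
            raise ValueError(
                f"record {record_id!r}: character {c!r} at position {pos} "
                "is outside the residue alphabet (strict mode)"
            )
        else:
            warnings.warn(
                f"record {record_id!r}: character {c!r} at position {pos} "
                "mapped to 'X'",
                stacklevel=3,
            )
            out.append("X")
    return "".join(out)


def read_fasta(
    path: str | PathLike,
    label: Label | str = Label.UNKNOWN,
    family: Optional[str] = None,
    alphabet: ResidueAlphabet = DEFAULT_ALPHABET,
    strict: bool = False,
) -> list[SequenceRecord]:
    """Read a FASTA file into validated, normalized records.

    Parameters
    ----------
    path
        FASTA file; multi-line (wrapped) sequences are allowed.
    label
        Class label applied to every record in the file.
    family
        Optional family tag (e.g. ``"alpha"``) applied to every record.
    strict
        If True, characters outside the alphabet raise instead of being
        mapped to ``'X'``.
    """
    path = Path(path)
    label = Label(label)
    records: list[SequenceRecord] = []
    seen_ids: set[str] = set()
    with open(path) as handle:
        bio_records = list(SeqIO.parse(handle, "fasta"))
    for bio_rec in bio_records:
        seq = _normalize(str(bio_rec.seq), bio_rec.id, alphabet, strict)
        if not seq:
            raise ValueError(f"header {bio_rec.id!r}: empty sequence")
        if bio_rec.id in seen_ids:
            raise ValueError(f"duplicate record id {bio_rec.id!r} in {path}")
        seen_ids.add(bio_rec.id)
        records.append(
            SequenceRecord(
                id=bio_rec.id,
                sequence=seq,
                label=label,
                family=family,
                description=bio_rec.description,
            )
        )
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | PathLike) -> None:
    """Write records to *path*; round-trips (id, sequence) through read_fasta."""
    bio_records = [
        _BioRecord(Seq(r.sequence), id=r.id, description=r.description or "")
        for r in records
    ]
    with open(path, "w") as handle:
        SeqIO.write(bio_records, handle, "fasta-2line")
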