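"""Protein sequence records, FASTA I/O and residue-numbering conventions.

All coordinates in this package are 1-based and inclusive at both ends.
Two numbering schemes are supported:

``UNIPROT_MET1``
    The database convention: the initiator methionine (when present) is
    residue 1.  This is the default, because the bundled reference
    sequences are database entries and the structural fixtures were
    produced from Met-containing crystal constructs.

``MATURE``
    The physiological convention for proteins whose initiator Met is
    cleaved: the residue *after* the initiator Met is residue 1.  Every
    coordinate shifts down by exactly one relative to ``UNIPROT_MET1``.

Mixing the two schemes is the classic source of +/-1 disagreements in
published residue coordinates, so records carry their scheme explicitly
and downstream joins refuse to mix schemes silently.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

#: The 20 standard residues plus X (unknown).  X never satisfies an anchor
#: constraint but is accepted in spacer ("any residue") positions.
AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWYX")


class NumberingScheme(str, enum.Enum):
    UNIPROT_MET1 = "uniprot"
    MATURE = "mature"


@dataclass(frozen=True)
class SequenceRecord:
    """An identified protein sequence with a declared numbering scheme."""

    id: str
    residues: str
    description: str = ""
    numbering_scheme: NumberingScheme = NumberingScheme.UNIPROT_MET1

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"record {self.id!r}: empty sequence")
        bad = [
            (i + 1, c)
            for i, c in enumerate(self.residues)
            if c not in AMINO_ACIDS
        ]
        if bad:
            pos, c = bad[0]
            raise ValueError(
                f"record {self.id!r}: illegal residue character {c!r} "
                f"at position {pos}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    def residue(self, position: int) -> str:
        """Return the one-letter code at a 1-based *position*."""
        if not 1 <= position <= len(self.residues):
            raise IndexError(
                f"position {position} outside 1..{len(self.residues)} "
                f"of record {self.id!r}"
            )
        return self.residues[position - 1]

    def slice(self, start: int, end: int) -> str:
        """Inclusive 1-based slice ``[start, end]``."""
        if start < 1 or end > len(self.residues) or start > end:
            raise IndexError(
                f"invalid interval {start}-{end} on record {self.id!r} "
                f"(length {len(self.residues)})"
            )
        return self.residues[start - 1 : end]


def read_fasta(
    path: str | Path,
    numbering_scheme: NumberingScheme = NumberingScheme.UNIPROT_MET1,
) -> list[SequenceRecord]:
    """Read a (multi-record) FASTA file into :class:`SequenceRecord` objects.

    Records come back in file order.  An empty file raises ``ValueError``
    ("no records"); an illegal residue raises with the offending record id
    and position.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(
            SequenceRecord(
                id=rec.id,
                description=rec.description[len(rec.id) :].strip(),
                residues=str(rec.seq).upper(),
                numbering_scheme=numbering_scheme,
            )
        )
    if not records:
        raise ValueError(f"no records in FASTA file {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    """Write records as wrapped FASTA (round-trips with :func:`read_fasta`)."""
    bio = [
        _BioSeqRecord(Seq(r.residues), id=r.id, description=r.description)
        for r in records
    ]
    SeqIO.write(bio, str(path), "fasta")


def renumber(
    record: SequenceRecord, target: NumberingScheme
) -> SequenceRecord:
    """Convert a record between Met-inclusive and mature numbering.

    ``UNIPROT_MET1 -> MATURE`` drops the initiator Met, so the residue at
    mature position *p* is the residue at Met-inclusive position *p + 1*.
    The reverse direction restores an initiator Met.  Converting a record
    already in the target scheme returns it unchanged.
    """
    if record.numbering_scheme == target:
        return record
    if target == NumberingScheme.MATURE:
        if not record.residues.startswith("M"):
            raise ValueError(
                f"record {record.id!r} does not start with the initiator "
                "methionine; cannot renumber to mature coordinates"
            )
        return replace(
            record,
            residues=record.residues[1:],
            numbering_scheme=NumberingScheme.MATURE,
        )
    # MATURE -> UNIPROT_MET1: restore the initiator Met.
    return replace(
        record,
        residues="M" + record.residues,
        numbering_scheme=NumberingScheme.UNIPROT_MET1,
    )
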