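"""Topology regions, cavity-lining residue sets and oligomer stoichiometry.

These types carry the outputs of third-party structural predictors
(membrane-topology classifiers such as MEMSAT-SVM, and pore/cavity
detectors such as PoreWalker) into the overlap analysis.  The predictors
themselves are out of scope; their results are consumed as tab-separated
annotation tables.

Formats
-------
Region tables: TSV with header
``protein_id  label  start  end  [start_res]  [end_res]``; labels are the
members of :class:`RegionLabel`.  Residue-set listings: TSV with header
``protein_id  position`` (one residue per row, PoreWalker-style), or the
single-set block format read by :func:`parse_residue_set`.  ``#`` lines
are comments everywhere.

Regions and residue sets are keyed by ``(protein_id, numbering_scheme)``
so that initiator-Met offset questions stay explicit; see
:func:`validate_endpoints` for the diagnostic that distinguishes the two
schemes when published endpoint letters disagree with a sequence.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from .seq_io import NumberingScheme, SequenceRecord


class RegionLabel(str, enum.Enum):
    TM_HELIX = "TM_HELIX"
    PORE_LINING = "PORE_LINING"
    CYTOPLASMIC = "CYTOPLASMIC"
    EXTRACELLULAR = "EXTRACELLULAR"
    SIGNAL = "SIGNAL"
    TRANSIT = "TRANSIT"
    REENTRANT = "REENTRANT"


@dataclass(frozen=True)
class Region:
    """A labelled 1-based inclusive interval on a protein, optionally with
    the published endpoint residue letters for validation."""

    protein_id: str
    label: RegionLabel
    start: int
    end: int
    start_residue: str | None = None
    end_residue: str | None = None
    numbering_scheme: NumberingScheme = NumberingScheme.UNIPROT_MET1

    def __post_init__(self):
        if self.start < 1:
            raise ValueError(
                f"{self.protein_id}: region start {self.start} < 1"
            )
        if self.start > self.end:
            raise ValueError(
                f"{self.protein_id}: region start {self.start} > end "
                f"{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def positions(self) -> frozenset[int]:
        return frozenset(range(self.start, self.end + 1))


@dataclass(frozen=True)
class ResidueSet:
    """An explicit set of residue positions (e.g. cavity-lining)."""

    protein_id: str
    positions: frozenset[int]
    source_label: str = "cavity_lining"
    numbering_scheme: NumberingScheme = NumberingScheme.UNIPROT_MET1

    def __post_init__(self):
        if any(p < 1 for p in self.positions):
            raise ValueError(
                f"{self.protein_id}: residue positions must be >= 1"
            )

    def __len__(self) -> int:
        return len(self.positions)

    def sorted(self) -> list[int]:
        return sorted(self.positions)


@dataclass(frozen=True)
class OligomerSpec:
    """Chain stoichiometry of a multimer, e.g. the alpha2-beta2 tetramer
    as ``OligomerSpec("Hb", (("HBA", 2), ("HBB", 2)))``."""

    name: str
    chains: tuple[tuple[str, int], ...]

    def __post_init__(self):
        if not self.chains:
            raise ValueError(f"oligomer {self.name!r}: no chains")
        for pid, copies in self.chains:
            if copies < 1:
                raise ValueError(
                    f"oligomer {self.name!r}: chain {pid} has copies "
                    f"{copies} < 1"
                )


def _data_rows(path: str | Path):
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line


def parse_region_table(
    path: str | Path,
    numbering_scheme: NumberingScheme = NumberingScheme.UNIPROT_MET1,
) -> list[Region]:
    """Read a region TSV (header required); errors carry row numbers."""
    rows = _data_rows(path)
    try:
        _, header = next(rows)
    except StopIteration:
        raise ValueError(f"{path}: empty region table") from None
    cols = header.split("\t")
    if cols[:4] != ["protein_id", "label", "start", "end"]:
        raise ValueError(
            f"{path}: expected header protein_id/label/start/end, got "
            f"{cols[:4]}"
        )
    regions = []
    for lineno, line in rows:
        f = line.split("\t")
        try:
            label = RegionLabel(f[1])
        except ValueError:
            raise ValueError(
                f"{path}:{lineno}: unknown region label {f[1]!r}"
            ) from None
        try:
            start, end = int(f[2]), int(f[3])
        except ValueError:
            raise ValueError(
                f"{path}:{lineno}: non-integer coordinate in {f[2:4]}"
            ) from None
        try:
            regions.append(
                Region(
                    protein_id=f[0],
                    label=label,
                    start=start,
                    end=end,
                    start_residue=f[4] or None if len(f) > 4 else None,
                    end_residue=f[5] or None if len(f) > 5 else None,
                    numbering_scheme=numbering_scheme,
                )
            )
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: {exc}") from None
    return regions


def write_region_table(regions: Iterable[Region], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\tlabel\tstart\tend\tstart_res\tend_res\n")
        for r in regions:
            fh.write(
                f"{r.protein_id}\t{r.label.value}\t{r.start}\t{r.end}\t"
                f"{r.start_residue or ''}\t{r.end_residue or ''}\n"
            )


def parse_residue_set(
    path: str | Path,
    numbering_scheme: NumberingScheme = NumberingScheme.UNIPROT_MET1,
) -> ResidueSet:
    """Read a single residue set: first data line ``protein_id [label]``,
    then whitespace-separated positions.  Duplicates collapse."""
    rows = _data_rows(path)
    try:
        _, first = next(rows)
    except StopIteration:
        raise ValueError(f"{path}: empty residue-set file") from None
    head = first.split()
    protein_id = head[0]
    label = head[1] if len(head) > 1 else "cavity_lining"
    positions: set[int] = set()
    for lineno, line in rows:
        for tok in line.split():
            try:
                pos = int(tok)
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: non-integer position {tok!r}"
                ) from None
            if pos < 1:
                raise ValueError(
                    f"{path}:{lineno}: position {pos} < 1"
                )
            positions.add(pos)
    return ResidueSet(
        protein_id=protein_id,
        positions=frozenset(positions),
        source_label=label,
        numbering_scheme=numbering_scheme,
    )


def write_residue_set(rs: ResidueSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"{rs.protein_id} {rs.source_label}\n")
        for p in rs.sorted():
            fh.write(f"{p}\n")


def read_residue_listing(
    path: str | Path,
    source_label: str = "cavity_lining",
    numbering_scheme: NumberingScheme = NumberingScheme.UNIPROT_MET1,
) -> dict[str, ResidueSet]:
    """Read a per-residue listing TSV (``protein_id  position`` rows,
    header required) into one :class:`ResidueSet` per protein."""
    rows = _data_rows(path)
    try:
        _, header = next(rows)
    except StopIteration:
        raise ValueError(f"{path}: empty residue listing") from None
    if header.split("\t")[:2] != ["protein_id", "position"]:
        raise ValueError(f"{path}: expected header protein_id/position")
    acc: dict[str, set[int]] = {}
    for lineno, line in rows:
        f = line.split("\t")
        try:
            pos = int(f[1])
        except (IndexError, ValueError):
            raise ValueError(
                f"{path}:{lineno}: expected protein_id<TAB>integer"
            ) from None
        if pos < 1:
            raise ValueError(f"{path}:{lineno}: position {pos} < 1")
        acc.setdefault(f[0], set()).add(pos)
    return {
        pid: ResidueSet(
            protein_id=pid,
            positions=frozenset(ps),
            source_label=source_label,
            numbering_scheme=numbering_scheme,
        )
        for pid, ps in acc.items()
    }


@dataclass
class EndpointCheck:
    """Outcome of checking one published region endpoint letter."""

    position: int
    expected: str
    found: str | None  # None: position beyond the sequence
    found_plus: str | None  # letter one position later (Met-offset, one way)
    found_minus: str | None  # letter one position earlier (the other way)
    passed: bool

    @property
    def off_by_one(self) -> bool:
        """True when the letter matches under a one-residue shift in
        either direction — the signature of an initiator-Met offset."""
        return (not self.passed) and self.expected in (
            self.found_plus,
            self.found_minus,
        )


@dataclass
class EndpointReport:
    region: Region
    checks: list[EndpointCheck] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return all(c.passed for c in self.checks)

    @property
    def suggests_met_offset(self) -> bool:
        return (not self.passed) and all(
            c.passed or c.off_by_one for c in self.checks
        )


def validate_endpoints(
    region: Region, seq: SequenceRecord
) -> EndpointReport:
    """Check a region's published endpoint letters against a sequence.

    For each provided endpoint letter the report records the letter found
    at that position under the record's own numbering and under the
    interpretation shifted by one (the other Met convention), so that a
    systematic off-by-one shows up as ``suggests_met_offset`` rather than
    as a bare failure.  A region reaching beyond the sequence end yields
    failing checks, not an exception.
    """
    report = EndpointReport(region=region)
    n = len(seq)
    for pos, expected in (
        (region.start, region.start_residue),
        (region.end, region.end_residue),
    ):
        if expected is None:
            continue

        def _at(p: int) -> str | None:
            return seq.residues[p - 1] if 1 <= p <= n else None

        found = _at(pos)
        report.checks.append(
            EndpointCheck(
                position=pos,
                expected=expected,
                found=found,
                found_plus=_at(pos + 1),
                found_minus=_at(pos - 1),
                passed=(found == expected),
            )
        )
    return report
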