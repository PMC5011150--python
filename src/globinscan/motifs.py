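"""CRAC / CARC / caveolin-binding motif scanning.

Motif grammars
--------------
Cholesterol recognition motifs are short linear patterns with two terminal
anchors and one mandatory central aromatic::

    CRAC   (L/V) - X(1-5) - Y     - X(1-5) - (K/R)
    CARC   (K/R) - X(1-5) - (Y/F) - X(1-5) - (L/V)      ("inverted CRAC")

``X`` is any residue (including X = unknown); anchors must be one of the
listed residues, so an X in the sequence never satisfies an anchor.
Matches are 5-13 residues long.  Caveolin-binding motifs are spaced
aromatic triples/quadruples with Phi in {W, Y, F}::

    CAV_8B   Phi x Phi x x x x Phi                (length 8)
    CAV_8A   Phi x x x x Phi x x Phi              (length 9)
    CAV_11   Phi x Phi x x x x Phi x x Phi        (length 11)

Enumeration is exhaustive: every admissible (start, central, end) triple
is reported, including mutually overlapping ones.  Overlapping matches of
one class are then merged transitively into *domains*; domains of
different classes are never merged, so a CARC ending where a CRAC begins
is reported as two domains.

Because a single aromatic center flanked by a basic residue on one side
and an aliphatic residue on the other can satisfy both the CRAC and the
CARC reading, counting CRAC and CARC domains independently can count one
physical cholesterol-docking center twice.  :func:`cholesterol_sites`
therefore additionally groups CRAC/CARC domains that share a mandatory
central aromatic into one *site*; the distinct-site count is the number
of docking centers a cholesterol molecule could plausibly address.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .seq_io import AMINO_ACIDS, SequenceRecord

ANY = frozenset(AMINO_ACIDS)
AROMATIC = frozenset("WYF")

CHOLESTEROL_CLASSES = ("CRAC", "CARC")
CAVEOLIN_CLASSES = ("CAV_8B", "CAV_8A", "CAV_11")
ALL_CLASSES = CHOLESTEROL_CLASSES + CAVEOLIN_CLASSES


@dataclass(frozen=True)
class MotifPattern:
    """An ordered list of (residue_class, min_count, max_count) elements."""

    class_name: str
    elements: tuple[tuple[frozenset, int, int], ...]

    @property
    def min_length(self) -> int:
        return sum(lo for _, lo, _ in self.elements)

    @property
    def max_length(self) -> int:
        return sum(hi for _, _, hi in self.elements)


def _anchor(residues: str):
    return (frozenset(residues), 1, 1)


def _spacer(lo: int, hi: int):
    return (ANY, lo, hi)


BUILTIN_PATTERNS: dict[str, MotifPattern] = {
    "CRAC": MotifPattern(
        "CRAC",
        (_anchor("LV"), _spacer(1, 5), _anchor("Y"), _spacer(1, 5), _anchor("KR")),
    ),
    "CARC": MotifPattern(
        "CARC",
        (_anchor("KR"), _spacer(1, 5), _anchor("YF"), _spacer(1, 5), _anchor("LV")),
    ),
    # Phi x x x x Phi x x Phi
    "CAV_8A": MotifPattern(
        "CAV_8A",
        (
            (AROMATIC, 1, 1), _spacer(4, 4), (AROMATIC, 1, 1),
            _spacer(2, 2), (AROMATIC, 1, 1),
        ),
    ),
    # Phi x Phi x x x x Phi
    "CAV_8B": MotifPattern(
        "CAV_8B",
        (
            (AROMATIC, 1, 1), _spacer(1, 1), (AROMATIC, 1, 1),
            _spacer(4, 4), (AROMATIC, 1, 1),
        ),
    ),
    # Phi x Phi x x x x Phi x x Phi
    "CAV_11": MotifPattern(
        "CAV_11",
        (
            (AROMATIC, 1, 1), _spacer(1, 1), (AROMATIC, 1, 1),
            _spacer(4, 4), (AROMATIC, 1, 1), _spacer(2, 2), (AROMATIC, 1, 1),
        ),
    ),
}


@dataclass(frozen=True, order=True)
class MotifMatch:
    """A single pattern hit; ``central`` is the mandatory aromatic of
    CRAC/CARC matches and ``None`` for caveolin classes."""

    start: int
    end: int
    central: int | None
    class_name: str
    matched_text: str

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class MotifDomain:
    """A maximal run of same-class, mutually overlapping matches."""

    class_name: str
    start: int
    end: int
    support: list[MotifMatch] = field(default_factory=list)

    @property
    def centrals(self) -> frozenset[int]:
        return frozenset(
            m.central for m in self.support if m.central is not None
        )

    @property
    def minimal_match(self) -> MotifMatch:
        """Shortest supporting match (ties: leftmost) — the span style in
        which published motif tables usually quote a domain."""
        return min(self.support, key=lambda m: (m.length, m.start))

    def overlaps(self, start: int, end: int) -> bool:
        return self.start <= end and start <= self.end


def enumerate_matches(
    seq: SequenceRecord | str, pattern: MotifPattern
) -> list[MotifMatch]:
    """Every (start, end[, central]) satisfying *pattern*, sorted by
    (start, end, central).  Exhaustive: all spacer-length combinations
    are tested at every start position."""
    s = seq.residues if isinstance(seq, SequenceRecord) else seq
    n = len(s)
    hits: list[MotifMatch] = []

    def extend(pos: int, elem_idx: int, centrals: list[int], start: int):
        if elem_idx == len(pattern.elements):
            central = centrals[0] if centrals else None
            hits.append(
                MotifMatch(
                    start=start + 1,
                    end=pos,
                    central=central,
                    class_name=pattern.class_name,
                    matched_text=s[start:pos],
                )
            )
            return
        residue_class, lo, hi = pattern.elements[elem_idx]
        is_anchor = residue_class is not ANY
        for length in range(lo, hi + 1):
            if pos + length > n:
                break
            window = s[pos : pos + length]
            if is_anchor:
                # anchors are width 1 in all built-in grammars; X never
                # satisfies an anchor because X is not in residue_class
                if any(c not in residue_class for c in window):
                    continue
            new_centrals = centrals
            # the mandatory aromatic of CRAC/CARC is the middle anchor
            if (
                is_anchor
                and pattern.class_name in CHOLESTEROL_CLASSES
                and elem_idx == 2
            ):
                new_centrals = centrals + [pos + 1]
            extend(pos + length, elem_idx + 1, new_centrals, start)

    for start in range(n):
        extend(start, 0, [], start)
    hits.sort(key=lambda m: (m.start, m.end, m.central or 0))
    return hits


def collapse_to_domains(matches: Iterable[MotifMatch]) -> list[MotifDomain]:
    """Merge overlapping matches of one class, transitively, into domains.

    Matches of different classes are never merged.  The domain span is the
    union of its supporting matches.  Idempotent in the sense that
    re-collapsing the minimal matches of the result changes nothing.
    """
    by_class: dict[str, list[MotifMatch]] = {}
    for m in matches:
        by_class.setdefault(m.class_name, []).append(m)
    domains: list[MotifDomain] = []
    for cls in sorted(by_class):
        pool = sorted(by_class[cls], key=lambda m: (m.start, m.end))
        current: MotifDomain | None = None
        for m in pool:
            if current is not None and m.start <= current.end:
                current.end = max(current.end, m.end)
                current.support.append(m)
            else:
                current = MotifDomain(cls, m.start, m.end, [m])
                domains.append(current)
    domains.sort(key=lambda d: (d.start, d.end, d.class_name))
    return domains


_CAV_PRECEDENCE = {"CAV_11": 3, "CAV_8A": 2, "CAV_8B": 1}


def scan_caveolin(seq: SequenceRecord | str) -> list[MotifDomain]:
    """All caveolin-binding motifs, merged across the three variants.

    Overlapping caveolin hits of any variant form one domain, labelled by
    the longest supporting variant (CAV_11 beats both 8-residue forms, so
    an 11-mer whose prefix also matches the 8-mer grammar is reported
    once, as CAV_11).
    """
    matches: list[MotifMatch] = []
    for cls in CAVEOLIN_CLASSES:
        matches.extend(enumerate_matches(seq, BUILTIN_PATTERNS[cls]))
    matches.sort(key=lambda m: (m.start, m.end))
    domains: list[MotifDomain] = []
    current: MotifDomain | None = None
    for m in matches:
        if current is not None and m.start <= current.end:
            current.end = max(current.end, m.end)
            current.support.append(m)
        else:
            current = MotifDomain("CAV", m.start, m.end, [m])
            domains.append(current)
    for d in domains:
        best = max(
            d.support, key=lambda m: (m.length, _CAV_PRECEDENCE[m.class_name])
        )
        d.class_name = best.class_name
    return domains


def scan_cholesterol(
    seq: SequenceRecord | str,
) -> dict[str, list[MotifDomain]]:
    """CRAC and CARC domains of a sequence, keyed by class."""
    out = {}
    for cls in CHOLESTEROL_CLASSES:
        out[cls] = collapse_to_domains(
            enumerate_matches(seq, BUILTIN_PATTERNS[cls])
        )
    return out


def cholesterol_sites(
    crac_domains: Sequence[MotifDomain], carc_domains: Sequence[MotifDomain]
) -> list[list[MotifDomain]]:
    """Group CRAC/CARC domains into distinct cholesterol-docking sites.

    Domains (of either class) sharing at least one mandatory central
    aromatic position are one site: the same aromatic read N->C as CRAC
    and C->N as CARC is a single docking center, not two.  Returns the
    list of sites, each a list of member domains.
    """
    domains = list(crac_domains) + list(carc_domains)
    n = len(domains)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if domains[i].centrals & domains[j].centrals:
                parent[find(i)] = find(j)
    groups: dict[int, list[MotifDomain]] = {}
    for i, d in enumerate(domains):
        groups.setdefault(find(i), []).append(d)
    sites = sorted(
        groups.values(), key=lambda g: min(d.start for d in g)
    )
    return sites


@dataclass(frozen=True)
class MotifCounts:
    """Per-class domain tallies for one sequence.

    ``combined_cholesterol`` is the plain CRAC + CARC domain count;
    ``cholesterol_sites`` is the distinct-docking-center count after
    merging CRAC/CARC domains that share their central aromatic.
    """

    crac_domains: int
    carc_domains: int
    caveolin_domains: int
    cholesterol_sites: int

    @property
    def combined_cholesterol(self) -> int:
        return self.crac_domains + self.carc_domains


def count_domains(seq: SequenceRecord | str) -> MotifCounts:
    """Run the full scan (both cholesterol classes, all caveolin
    variants) and tally domains."""
    chol = scan_cholesterol(seq)
    cav = scan_caveolin(seq)
    sites = cholesterol_sites(chol["CRAC"], chol["CARC"])
    return MotifCounts(
        crac_domains=len(chol["CRAC"]),
        carc_domains=len(chol["CARC"]),
        caveolin_domains=len(cav),
        cholesterol_sites=len(sites),
    )


def scan_all(seq: SequenceRecord | str) -> list[MotifDomain]:
    """Cholesterol and caveolin domains of a sequence, position-sorted."""
    chol = scan_cholesterol(seq)
    domains = chol["CRAC"] + chol["CARC"] + scan_caveolin(seq)
    domains.sort(key=lambda d: (d.start, d.end, d.class_name))
    return domains
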