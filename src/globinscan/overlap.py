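"""Cross-referencing of motifs, topology regions and cavity residue sets.

This is the analysis stage proper: strict interval/set arithmetic over
1-based residue coordinates, per-protein summary reports, and linear
tallies over oligomer stoichiometries.  Overlap means exact set
intersection; an optional ``tolerance`` widens one operand by +/-t
positions so that published near-miss counts (boundary disagreements of
one residue between two predictors) can be reported alongside the strict
number, never instead of it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .annotations import OligomerSpec, Region, RegionLabel, ResidueSet
from .motifs import MotifDomain, cholesterol_sites, scan_caveolin, scan_cholesterol
from .seq_io import SequenceRecord


def region_to_set(region: Region) -> ResidueSet:
    """The residue set {start, ..., end} of a region."""
    return ResidueSet(
        protein_id=region.protein_id,
        positions=region.positions(),
        source_label=region.label.value.lower(),
        numbering_scheme=region.numbering_scheme,
    )


def _check_joinable(a: ResidueSet, b: ResidueSet) -> None:
    if a.protein_id != b.protein_id:
        raise ValueError(
            f"cannot intersect residue sets of different proteins "
            f"({a.protein_id!r} vs {b.protein_id!r})"
        )
    if a.numbering_scheme != b.numbering_scheme:
        raise ValueError(
            f"numbering schemes differ ({a.numbering_scheme.value} vs "
            f"{b.numbering_scheme.value}); renumber one operand first"
        )


def intersect_count(
    a: ResidueSet, b: ResidueSet, tolerance: int = 0
) -> tuple[int, list[int]]:
    """Exact (or +/-tolerance widened) intersection of two residue sets.

    Returns ``(count, sorted positions of b that intersect)``.  With
    ``tolerance`` t > 0 the first operand is widened by t positions on
    each side, so a position of *b* counts when it lies within t of some
    position of *a* — the way a one-residue boundary disagreement
    between two predictors is flagged.  Commutative for t = 0.
    """
    _check_joinable(a, b)
    if tolerance == 0:
        shared = a.positions & b.positions
    else:
        widened = set()
        for p in a.positions:
            widened.update(range(p - tolerance, p + tolerance + 1))
        shared = widened & b.positions
    return len(shared), sorted(shared)


def motif_cavity_overlap(
    domains: Sequence[MotifDomain], cavity: ResidueSet
) -> list[tuple[MotifDomain, list[int]]]:
    """Domains sharing at least one position with the cavity set, each
    with its sorted overlapping positions."""
    out = []
    for d in domains:
        shared = sorted(
            p for p in cavity.positions if d.start <= p <= d.end
        )
        if shared:
            out.append((d, shared))
    return out


def oligomer_tally(
    spec: OligomerSpec, per_chain_counts: Mapping[str, int]
) -> int:
    """Total count over an oligomer: sum of copies x per-chain count."""
    total = 0
    for pid, copies in spec.chains:
        if pid not in per_chain_counts:
            raise KeyError(
                f"oligomer {spec.name!r}: no count supplied for chain "
                f"{pid!r}"
            )
        total += copies * per_chain_counts[pid]
    return total


def site_in_domain(
    position: int, domains: Sequence[MotifDomain]
) -> list[MotifDomain]:
    """All domains containing a residue position (at most one per class,
    since same-class domains never overlap)."""
    return [d for d in domains if d.start <= position <= d.end]


@dataclass
class OverlapReport:
    """Per-protein summary: motif inventory, topology regions, and
    cavity cross-references."""

    protein_id: str
    length: int
    numbering_scheme: str
    pore_lining_regions: list[Region]
    tm_helices: list[Region]
    crac_domains: list[MotifDomain]
    carc_domains: list[MotifDomain]
    caveolin_domains: list[MotifDomain]
    cholesterol_site_count: int
    pore_cavity_overlap: tuple[int, list[int]]
    pore_cavity_overlap_tolerant: tuple[int, list[int]]
    tolerance: int
    motif_cavity_domains: list[tuple[MotifDomain, list[int]]]
    cavity_size: int

    @property
    def combined_cholesterol(self) -> int:
        return len(self.crac_domains) + len(self.carc_domains)

    @property
    def counts(self) -> dict[str, int]:
        return {
            "crac_domains": len(self.crac_domains),
            "carc_domains": len(self.carc_domains),
            "combined_cholesterol": self.combined_cholesterol,
            "cholesterol_sites": self.cholesterol_site_count,
            "caveolin_domains": len(self.caveolin_domains),
            "pore_cavity_shared": self.pore_cavity_overlap[0],
            "motif_cavity_domains": len(self.motif_cavity_domains),
        }


def build_report(
    seq: SequenceRecord,
    regions: Iterable[Region] = (),
    cavity: ResidueSet | None = None,
    tolerance: int = 1,
) -> OverlapReport:
    """Scan a sequence and cross-reference it with its annotations.

    ``tolerance`` controls only the *additional* widened pore/cavity
    number reported next to the strict one (strict is always computed
    and is the headline figure).
    """
    regions = [r for r in regions if r.protein_id == seq.id]
    pore = [r for r in regions if r.label == RegionLabel.PORE_LINING]
    tm = [r for r in regions if r.label == RegionLabel.TM_HELIX]
    chol = scan_cholesterol(seq)
    cav = scan_caveolin(seq)
    sites = cholesterol_sites(chol["CRAC"], chol["CARC"])

    empty = ResidueSet(
        protein_id=seq.id,
        positions=frozenset(),
        numbering_scheme=seq.numbering_scheme,
    )
    cavity = cavity or empty
    pore_set_positions: set[int] = set()
    for r in pore:
        pore_set_positions |= r.positions()
    pore_set = ResidueSet(
        protein_id=seq.id,
        positions=frozenset(pore_set_positions),
        source_label="pore_lining",
        numbering_scheme=seq.numbering_scheme,
    )
    strict = intersect_count(pore_set, cavity)
    tolerant = intersect_count(pore_set, cavity, tolerance=tolerance)
    all_domains = chol["CRAC"] + chol["CARC"] + cav
    all_domains.sort(key=lambda d: (d.start, d.end, d.class_name))
    return OverlapReport(
        protein_id=seq.id,
        length=len(seq),
        numbering_scheme=seq.numbering_scheme.value,
        pore_lining_regions=pore,
        tm_helices=tm,
        crac_domains=chol["CRAC"],
        carc_domains=chol["CARC"],
        caveolin_domains=cav,
        cholesterol_site_count=len(sites),
        pore_cavity_overlap=strict,
        pore_cavity_overlap_tolerant=tolerant,
        tolerance=tolerance,
        motif_cavity_domains=motif_cavity_overlap(all_domains, cavity),
        cavity_size=len(cavity),
    )


def _fmt_domains(domains: Sequence[MotifDomain]) -> str:
    if not domains:
        return "-"
    parts = []
    for d in domains:
        m = d.minimal_match
        parts.append(f"{d.class_name}:{d.start}-{d.end}(min {m.start}-{m.end})")
    return ",".join(parts)


def render_tsv(reports: Sequence[OverlapReport]) -> str:
    """Deterministic TSV rendering (byte-identical for equal inputs)."""
    cols = [
        "protein_id", "length", "numbering", "pore_lining", "tm_helix",
        "crac_domains", "carc_domains", "combined_cholesterol",
        "cholesterol_sites", "caveolin_domains", "cavity_size",
        "pore_cavity_shared", "pore_cavity_shared_tol",
        "pore_cavity_residues", "motif_cavity_domains",
    ]
    lines = ["\t".join(cols)]
    for r in sorted(reports, key=lambda x: x.protein_id):
        lines.append(
            "\t".join(
                [
                    r.protein_id,
                    str(r.length),
                    r.numbering_scheme,
                    ";".join(f"{x.start}-{x.end}" for x in r.pore_lining_regions) or "-",
                    ";".join(f"{x.start}-{x.end}" for x in r.tm_helices) or "-",
                    _fmt_domains(r.crac_domains),
                    _fmt_domains(r.carc_domains),
                    str(r.combined_cholesterol),
                    str(r.cholesterol_site_count),
                    _fmt_domains(r.caveolin_domains),
                    str(r.cavity_size),
                    str(r.pore_cavity_overlap[0]),
                    str(r.pore_cavity_overlap_tolerant[0]),
                    ",".join(map(str, r.pore_cavity_overlap[1])) or "-",
                    str(len(r.motif_cavity_domains)),
                ]
            )
        )
    return "\n".join(lines) + "\n"


def render_text(reports: Sequence[OverlapReport]) -> str:
    """Human-readable per-protein summary (deterministic)."""
    out = []
    for r in sorted(reports, key=lambda x: x.protein_id):
        out.append(f"== {r.protein_id} ({r.length} aa, {r.numbering_scheme})")
        out.append(
            f"   pore-lining: "
            + (";".join(f"{x.start}-{x.end}" for x in r.pore_lining_regions) or "none")
            + "   TM helix: "
            + (";".join(f"{x.start}-{x.end}" for x in r.tm_helices) or "none")
        )
        out.append(
            f"   CRAC {_fmt_domains(r.crac_domains)} | "
            f"CARC {_fmt_domains(r.carc_domains)}"
        )
        out.append(
            f"   cholesterol domains {r.combined_cholesterol} "
            f"(distinct sites {r.cholesterol_site_count}); "
            f"caveolin {_fmt_domains(r.caveolin_domains)}"
        )
        strict_n, strict_res = r.pore_cavity_overlap
        tol_n, _ = r.pore_cavity_overlap_tolerant
        flag = ""
        if tol_n != strict_n:
            flag = (
                f"  [note: widening by +/-{r.tolerance} residue(s) gives "
                f"{tol_n} — boundary disagreement between predictors]"
            )
        out.append(
            f"   pore/cavity shared residues: {strict_n} "
            f"({','.join(map(str, strict_res)) or '-'}){flag}"
        )
        out.append(
            f"   motif domains touching the cavity: "
            f"{len(r.motif_cavity_domains)}"
        )
    return "\n".join(out) + "\n"
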