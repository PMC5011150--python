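"""Smith-Waterman local alignment with affine gaps, Waterman-Eggert
non-intersecting suboptimal alignments, and LALIGN-style statistics.

The dynamic programme is the Gotoh three-state recurrence.  A gap of
length *L* costs ``gap_open + L * gap_extend``, so with the default
BLOSUM50 / open 12 / extend 2 a one-residue gap costs 14 — the gap model
used by the lalign36 family of programs, whose protein defaults these
are.  EMBOSS Water-style defaults (BLOSUM62 / open 10 / extend 0.5) are
available through :func:`water_params`.

Waterman-Eggert suboptimal alignments are produced by invalidating every
aligned residue pair (i, j) consumed by earlier alignments and re-running
the programme, so the reported alignments share no aligned pair.

Statistics follow the conventions of the FASTA/LALIGN output line
"xx.x% identity (yy.y% similar) in N aa overlap":

* ``overlap_length`` — number of alignment columns, gap columns included;
* ``pct_identity``  — identical columns / overlap_length;
* ``pct_similar``   — columns whose substitution score is >= 0
  (identities included) / overlap_length; gap columns count as neither.

The similarity cutoff is configurable (``similar_cutoff``); strictly
positive scoring ("conservative replacement only") corresponds to
``similar_cutoff > 0``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

from Bio.Align import substitution_matrices

from .seq_io import SequenceRecord

GAP = "-"
_NEG = float("-inf")


@dataclass(frozen=True)
class ScoringParams:
    """Substitution matrix plus affine gap penalties (penalties are
    magnitudes; they are subtracted)."""

    matrix_name: str = "BLOSUM50"
    gap_open: float = 12.0
    gap_extend: float = 2.0
    similar_cutoff: float = 0.0

    def __post_init__(self):
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties are non-negative magnitudes")

    @property
    def matrix(self) -> dict[str, dict[str, float]]:
        return _matrix_as_dict(self.matrix_name)

    def score(self, a: str, b: str) -> float:
        try:
            return self.matrix[a][b]
        except KeyError:
            raise KeyError(
                f"residue pair ({a!r}, {b!r}) not in matrix "
                f"{self.matrix_name}"
            ) from None


def lalign_params() -> ScoringParams:
    """lalign36 protein defaults: BLOSUM50, gap open 12, extend 2."""
    return ScoringParams("BLOSUM50", 12.0, 2.0)


def water_params() -> ScoringParams:
    """EMBOSS Water protein defaults: BLOSUM62, gap open 10, extend 0.5."""
    return ScoringParams("BLOSUM62", 10.0, 0.5)


_MATRIX_CACHE: dict[str, object] = {}
_DICT_CACHE: dict[str, dict] = {}


def _load_matrix(name: str):
    if name not in _MATRIX_CACHE:
        _MATRIX_CACHE[name] = substitution_matrices.load(name)
    return _MATRIX_CACHE[name]


def _matrix_as_dict(name: str) -> dict[str, dict[str, float]]:
    """Substitution matrix as nested dicts (fast inner-loop lookups)."""
    if name not in _DICT_CACHE:
        mat = _MATRIX_CACHE.get(name) or _load_matrix(name)
        alpha = mat.alphabet
        _DICT_CACHE[name] = {
            x: {y: float(mat[x, y]) for y in alpha} for x in alpha
        }
    return _DICT_CACHE[name]


def register_matrix(
    name: str, scores: dict[tuple[str, str], float]
) -> str:
    """Register a custom symmetric substitution matrix under *name*.

    *scores* maps residue pairs to scores; missing symmetric pairs are
    filled in, and asymmetric inputs are rejected.
    """
    table: dict[str, dict[str, float]] = {}
    for (x, y), s in scores.items():
        rev = scores.get((y, x), s)
        if rev != s:
            raise ValueError(
                f"matrix {name!r} is asymmetric at ({x}, {y})"
            )
        table.setdefault(x, {})[y] = float(s)
        table.setdefault(y, {})[x] = float(s)
    _DICT_CACHE[name] = table
    return name


def simple_matrix(
    name: str, alphabet: str, match: float, mismatch: float
) -> str:
    """Register and return a match/mismatch matrix over *alphabet*."""
    return register_matrix(
        name,
        {
            (x, y): (match if x == y else mismatch)
            for x in alphabet
            for y in alphabet
        },
    )


def read_matrix_file(path) -> str:
    """Register an NCBI-format substitution matrix file under its stem
    name and return that name for use in :class:`ScoringParams`."""
    from pathlib import Path

    p = Path(path)
    with open(p) as fh:
        _MATRIX_CACHE[p.stem] = substitution_matrices.read(fh)
    return p.stem


@dataclass
class AlignmentResult:
    """A local alignment and its Waterman-Eggert score and statistics.

    ``aligned_a``/``aligned_b`` are equal-length gapped strings; the
    1-based coordinates ``start_a..end_a`` / ``start_b..end_b`` delimit
    the aligned segments (all zero for an empty alignment)."""

    id_a: str
    id_b: str
    score: float
    aligned_a: str
    aligned_b: str
    start_a: int
    end_a: int
    start_b: int
    end_b: int
    pct_identity: float
    pct_similar: float
    overlap_length: int
    aligned_pairs: frozenset = field(default_factory=frozenset, repr=False)

    @property
    def is_empty(self) -> bool:
        return self.overlap_length == 0

    def rescore(self, params: ScoringParams) -> float:
        """Recompute the score column-by-column (substitution scores
        minus affine gap penalties); must reproduce ``score`` exactly."""
        total = 0.0
        in_gap = False
        for x, y in zip(self.aligned_a, self.aligned_b):
            if x == GAP or y == GAP:
                if not in_gap:
                    total -= params.gap_open
                    in_gap = True
                total -= params.gap_extend
            else:
                in_gap = False
                total += params.score(x, y)
        return total


def alignment_stats(
    aligned_a: str, aligned_b: str, params: ScoringParams
) -> tuple[float, float, int]:
    """(pct_identity, pct_similar, overlap_length) of a gapped pair."""
    if len(aligned_a) != len(aligned_b):
        raise ValueError("aligned strings differ in length")
    overlap = len(aligned_a)
    if overlap == 0:
        return 0.0, 0.0, 0
    ident = similar = 0
    for x, y in zip(aligned_a, aligned_b):
        if x == GAP or y == GAP:
            continue
        if x == y:
            ident += 1
        if params.score(x, y) >= params.similar_cutoff:
            similar += 1
    return 100.0 * ident / overlap, 100.0 * similar / overlap, overlap


def _residues(seq: SequenceRecord | str) -> tuple[str, str]:
    if isinstance(seq, SequenceRecord):
        return seq.residues, seq.id
    return seq, ""


def _empty_result(id_a, id_b):
    return AlignmentResult(
        id_a, id_b, 0.0, "", "", 0, 0, 0, 0, 0.0, 0.0, 0
    )


def sw_align(
    a: SequenceRecord | str,
    b: SequenceRecord | str,
    params: ScoringParams | None = None,
    banned: frozenset | None = None,
) -> AlignmentResult:
    """Optimal local alignment of *a* and *b* under affine-gap scoring.

    Ties between co-optimal end cells are broken toward the smallest
    (end_a, end_b) and the traceback prefers substitutions, which yields
    the shortest leftmost alignment among co-optimal ones.  *banned* is
    the set of (i, j) residue pairs unavailable for alignment (used by
    :func:`waterman_eggert`).
    """
    params = params or lalign_params()
    sa, id_a = _residues(a)
    sb, id_b = _residues(b)
    if not sa or not sb:
        raise ValueError("sequences must be non-empty")
    banned = banned or frozenset()
    mat = _matrix_as_dict(params.matrix_name)
    for tag, s in (("first", sa), ("second", sb)):
        for c in s:
            if c not in mat:
                raise KeyError(
                    f"residue {c!r} in {tag} sequence not covered by "
                    f"matrix {params.matrix_name}"
                )
    go, ge = params.gap_open, params.gap_extend
    n, m = len(sa), len(sb)

    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[_NEG] * (m + 1) for _ in range(n + 1)]
    F = [[_NEG] * (m + 1) for _ in range(n + 1)]
    best, bi, bj = 0.0, 0, 0
    for i in range(1, n + 1):
        Hi, Hp = H[i], H[i - 1]
        Ei, Fi, Fp = E[i], F[i], F[i - 1]
        ca = sa[i - 1]
        row = mat[ca]
        for j in range(1, m + 1):
            e = max(Ei[j - 1] - ge, Hi[j - 1] - go - ge)
            f = max(Fp[j] - ge, Hp[j] - go - ge)
            s = _NEG if (i, j) in banned else row[sb[j - 1]]
            h = Hp[j - 1] + s
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0.0:
                h = 0.0
            Ei[j], Fi[j], Hi[j] = e, f, h
            if h > best:
                best, bi, bj = h, i, j
    if best <= 0.0:
        return _empty_result(id_a, id_b)

    # traceback
    i, j, state = bi, bj, "H"
    out_a: list[str] = []
    out_b: list[str] = []
    pairs = []
    while i > 0 and j > 0:
        if state == "H":
            if H[i][j] == 0.0:
                break
            s = _NEG if (i, j) in banned else mat[sa[i - 1]][sb[j - 1]]
            if H[i][j] == H[i - 1][j - 1] + s:
                out_a.append(sa[i - 1])
                out_b.append(sb[j - 1])
                pairs.append((i, j))
                i -= 1
                j -= 1
            elif H[i][j] == E[i][j]:
                state = "E"
            elif H[i][j] == F[i][j]:
                state = "F"
            else:  # pragma: no cover - recurrence guarantees a branch
                raise AssertionError("traceback failed")
        elif state == "E":
            out_a.append(GAP)
            out_b.append(sb[j - 1])
            if E[i][j] == H[i][j - 1] - go - ge:
                state = "H"
            j -= 1
        else:
            out_a.append(sa[i - 1])
            out_b.append(GAP)
            if F[i][j] == H[i - 1][j] - go - ge:
                state = "H"
            i -= 1
    aligned_a = "".join(reversed(out_a))
    aligned_b = "".join(reversed(out_b))
    pid, psim, overlap = alignment_stats(aligned_a, aligned_b, params)
    return AlignmentResult(
        id_a=id_a,
        id_b=id_b,
        score=best,
        aligned_a=aligned_a,
        aligned_b=aligned_b,
        start_a=i + 1,
        end_a=bi,
        start_b=j + 1,
        end_b=bj,
        pct_identity=pid,
        pct_similar=psim,
        overlap_length=overlap,
        aligned_pairs=frozenset(pairs),
    )


def waterman_eggert(
    a: SequenceRecord | str,
    b: SequenceRecord | str,
    params: ScoringParams | None = None,
    k: int = 3,
) -> list[AlignmentResult]:
    """Top *k* non-intersecting local alignments, best first.

    ``result[0]`` equals :func:`sw_align`; each later alignment is the
    best alignment sharing no aligned residue pair with any earlier one.
    The list stops early when no positive-scoring alignment remains, so
    it may be shorter than *k*.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    params = params or lalign_params()
    results: list[AlignmentResult] = []
    banned: set = set()
    for _ in range(k):
        r = sw_align(a, b, params, banned=frozenset(banned))
        if r.is_empty:
            break
        results.append(r)
        banned |= r.aligned_pairs
    return results


def internal_duplications(
    seq: SequenceRecord | str,
    params: ScoringParams | None = None,
    k: int = 3,
) -> list[AlignmentResult]:
    """Non-trivial self-alignments of one sequence.

    The optimal self-alignment is the identity diagonal; the alignments
    after it (with the diagonal — in both orientations — invalidated)
    are the internal sequence duplications LALIGN is classically used to
    reveal.  Returns the *k* best off-diagonal alignments.
    """
    params = params or lalign_params()
    s, _ = _residues(seq)
    results: list[AlignmentResult] = []
    first = sw_align(seq, seq, params)
    banned = set(first.aligned_pairs)
    banned |= {(j, i) for i, j in first.aligned_pairs}
    for _ in range(k):
        r = sw_align(seq, seq, params, banned=frozenset(banned))
        if r.is_empty:
            break
        results.append(r)
        banned |= r.aligned_pairs
        banned |= {(j, i) for i, j in r.aligned_pairs}
    return results


DEFAULT_SWEEP_GRID = {
    "matrix": ("BLOSUM50", "BLOSUM62"),
    "gap_open": (10.0, 12.0, 14.0),
    "gap_extend": (0.5, 1.0, 2.0, 4.0),
}


def sweep_parameters(
    a: SequenceRecord | str,
    b: SequenceRecord | str,
    grid: dict | None = None,
) -> list[tuple[ScoringParams, AlignmentResult]]:
    """Align *a* and *b* under every setting of a small parameter grid
    (matrices x gap penalties); used to calibrate against published
    alignment tables when the original program settings are unknown."""
    grid = grid or DEFAULT_SWEEP_GRID
    out = []
    for mname, go, ge in itertools.product(
        grid["matrix"], grid["gap_open"], grid["gap_extend"]
    ):
        p = ScoringParams(mname, go, ge)
        out.append((p, sw_align(a, b, p)))
    return out


def format_alignment(r: AlignmentResult, width: int = 60) -> str:
    """Plain-text pairwise alignment block."""
    if r.is_empty:
        return f"{r.id_a} x {r.id_b}: empty alignment (score 0)\n"
    lines = [
        f"{r.id_a} x {r.id_b}  score {r.score:g}  "
        f"{r.pct_identity:.1f}% identity ({r.pct_similar:.1f}% similar) "
        f"in {r.overlap_length} aa overlap "
        f"({r.start_a}-{r.end_a}:{r.start_b}-{r.end_b})"
    ]
    for off in range(0, r.overlap_length, width):
        xa = r.aligned_a[off : off + width]
        xb = r.aligned_b[off : off + width]
        mid = "".join(
            "|" if p == q and p != GAP else " " for p, q in zip(xa, xb)
        )
        lines += [xa, mid, xb, ""]
    return "\n".join(lines)
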