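"""Synthetic sequences and annotations with known ground truth.

The generator emulates the study inputs — protein sequences with
controlled residue composition, planted motif instances, and random
region/residue-set annotations — so that every pipeline stage can be
exercised end-to-end without any download.

Exact-recovery construction: the filler alphabet
``ACDEGHIMNPQST`` (the 20 residues minus the anchor set {L, V, Y, F, W,
K, R}) provably cannot form any CRAC, CARC or caveolin match, so a motif
instance planted in such a background is recovered by the scanner
exactly, and nothing else is.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .motifs import ANY, BUILTIN_PATTERNS, enumerate_matches
from .seq_io import NumberingScheme, SequenceRecord

#: Residues that appear in no motif grammar as anchor or aromatic.
ANCHOR_FREE_ALPHABET = "ACDEGHIMNPQST"
#: Residues excluded from the filler alphabet.
ANCHOR_RESIDUES = frozenset("LVYFWKR")

#: Approximate residue frequencies of the human proteome (UniProt
#: composition statistics, rounded); used by "realistic" backgrounds.
HUMAN_PROTEOME_FREQS = {
    "A": 0.070, "R": 0.056, "N": 0.036, "D": 0.047, "C": 0.023,
    "Q": 0.048, "E": 0.071, "G": 0.066, "H": 0.026, "I": 0.043,
    "L": 0.100, "K": 0.057, "M": 0.021, "F": 0.037, "P": 0.063,
    "S": 0.083, "T": 0.054, "W": 0.012, "Y": 0.027, "V": 0.060,
}


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def random_sequence(
    length: int,
    freqs: dict[str, float] | None = None,
    seed=0,
    record_id: str = "synthetic",
) -> SequenceRecord:
    """An i.i.d. random sequence; uniform over the 20 residues unless
    *freqs* is given.  Frequencies must sum to 1 (tolerance 1e-9)."""
    if length < 1:
        raise ValueError("length must be >= 1")
    if freqs is None:
        letters = sorted("ACDEFGHIKLMNPQRSTVWY")
        probs = np.full(len(letters), 1.0 / len(letters))
    else:
        letters = sorted(freqs)
        probs = np.array([freqs[c] for c in letters], dtype=float)
        if abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError(
                f"frequencies sum to {probs.sum():.12f}, not 1"
            )
    rng = _rng(seed)
    seq = "".join(rng.choice(letters, size=length, p=probs))
    return SequenceRecord(id=record_id, residues=seq)


def realize_motif(
    class_name: str,
    spacer_lengths: tuple[int, ...] | None = None,
    filler_alphabet: str = ANCHOR_FREE_ALPHABET,
    seed=0,
) -> str:
    """A concrete string matching one pattern with the requested spacer
    lengths, guaranteed to contain no other match of any class.

    Anchors are drawn uniformly from their residue class, spacers from
    *filler_alphabet*, which must contain no anchor residue — otherwise
    the no-extra-match guarantee would fail and a ``ValueError`` is
    raised.
    """
    if set(filler_alphabet) & ANCHOR_RESIDUES:
        raise ValueError(
            "filler alphabet contains anchor residues "
            f"{sorted(set(filler_alphabet) & ANCHOR_RESIDUES)}"
        )
    pattern = BUILTIN_PATTERNS[class_name]
    rng = _rng(seed)
    spacers = list(spacer_lengths) if spacer_lengths is not None else None
    out = []
    si = 0
    filler = sorted(set(filler_alphabet))
    for residue_class, lo, hi in pattern.elements:
        if residue_class is not ANY:
            out.append(rng.choice(sorted(residue_class)))
        else:
            if spacers is not None:
                n = spacers[si]
                si += 1
                if not lo <= n <= hi:
                    raise ValueError(
                        f"spacer length {n} outside {lo}..{hi} for "
                        f"{class_name}"
                    )
            else:
                n = int(rng.integers(lo, hi + 1))
            out.append("".join(rng.choice(filler, size=n)))
    return "".join(out)


@dataclass
class PlantedInstance:
    class_name: str
    position: int  # 1-based start in the final sequence
    text: str

    @property
    def end(self) -> int:
        return self.position + len(self.text) - 1


def plant(
    background: SequenceRecord,
    instances: list[str],
    positions: list[int],
    classes: list[str] | None = None,
) -> tuple[SequenceRecord, list[PlantedInstance]]:
    """Overwrite *background* with motif instances at 1-based positions.

    Placements must be non-overlapping and within bounds; the returned
    truth table lists each instance with its final coordinates.  When the
    background is anchor-free, scanning the product recovers exactly the
    truth table (exact-recovery mode); over realistic backgrounds the
    scan returns a superset.
    """
    if len(instances) != len(positions):
        raise ValueError("instances and positions differ in length")
    n = len(background)
    intervals = sorted(
        (p, p + len(t) - 1, t, i)
        for i, (t, p) in enumerate(zip(instances, positions))
    )
    prev_end = 0
    for start, end, _, _ in intervals:
        if start < 1 or end > n:
            raise ValueError(
                f"planted instance {start}-{end} outside sequence 1..{n}"
            )
        if start <= prev_end:
            raise ValueError(
                f"planted instances overlap at position {start}"
            )
        prev_end = end
    residues = list(background.residues)
    truth = []
    for i, (text, pos) in enumerate(zip(instances, positions)):
        residues[pos - 1 : pos - 1 + len(text)] = text
        cls = classes[i] if classes else _classify(text)
        truth.append(PlantedInstance(cls, pos, text))
    truth.sort(key=lambda t: t.position)
    rec = SequenceRecord(
        id=background.id,
        residues="".join(residues),
        description=background.description,
        numbering_scheme=background.numbering_scheme,
    )
    return rec, truth


def _classify(text: str) -> str:
    for cls, pattern in BUILTIN_PATTERNS.items():
        for m in enumerate_matches(text, pattern):
            if m.start == 1 and m.end == len(text):
                return cls
    raise ValueError(f"string {text!r} matches no motif pattern exactly")


@dataclass
class SyntheticScenario:
    """A reproducible planted-motif scenario: background + instances +
    ground truth."""

    seed: int
    sequence_length: int = 400
    n_crac: int = 3
    n_carc: int = 2
    n_caveolin: int = 1
    record: SequenceRecord = field(init=False)
    truth: list[PlantedInstance] = field(init=False)

    def __post_init__(self):
        rng = np.random.default_rng(self.seed)
        freqs = {c: 1.0 / len(ANCHOR_FREE_ALPHABET) for c in ANCHOR_FREE_ALPHABET}
        background = random_sequence(
            self.sequence_length, freqs, rng, record_id=f"scenario{self.seed}"
        )
        classes = (
            ["CRAC"] * self.n_crac
            + ["CARC"] * self.n_carc
            + ["CAV_11"] * self.n_caveolin
        )
        texts = [realize_motif(cls, seed=rng) for cls in classes]
        # place left to right with random anchor-free padding
        total = sum(len(t) for t in texts)
        slack = self.sequence_length - total
        if slack < len(texts):
            raise ValueError("sequence too short for requested instances")
        gaps = rng.multinomial(slack - len(texts), [1 / len(texts)] * len(texts))
        positions = []
        cursor = 1
        for t, g in zip(texts, gaps):
            cursor += int(g) + 1
            positions.append(cursor)
            cursor += len(t)
        self.record, self.truth = plant(background, texts, positions, classes)


def random_overlap_null(
    protein_length: int,
    region_length: int,
    set_size: int,
    reps: int = 10_000,
    seed=0,
    return_se: bool = False,
):
    """Empirical mean of |random interval ∩ random residue set|.

    A length-*m* interval and a size-*s* uniform random subset of
    1..n intersect in m*s/n positions on average; this Monte-Carlo
    estimate backs the overlap-analysis property tests.  With
    ``return_se`` the standard error of the mean is returned too.
    """
    n, m, s = protein_length, region_length, set_size
    if m > n or s > n:
        raise ValueError("region and set must fit in the protein")
    rng = _rng(seed)
    if s == 0:
        return (0.0, 0.0) if return_se else 0.0
    counts = np.empty(reps)
    for r in range(reps):
        start = int(rng.integers(1, n - m + 2))
        members = rng.choice(n, size=s, replace=False) + 1
        counts[r] = ((members >= start) & (members <= start + m - 1)).sum()
    mean = float(counts.mean())
    if return_se:
        se = float(counts.std(ddof=1) / np.sqrt(reps))
        return mean, se
    return mean
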