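# Methods

This note documents the models implemented in `globinscan`, the
conventions and calibrations behind them, the provenance and known
defects of the bundled fixtures, and what the test suite does and does
not establish.

## Motif grammars and enumeration

CRAC ((L/V)–X₁₋₅–Y–X₁₋₅–(K/R)) and CARC ((K/R)–X₁₋₅–(Y/F)–X₁₋₅–(L/V))
are applied to the sequence read N→C exactly as written in one-letter
code.  CARC is the mirror image of CRAC with the relaxation that the
central aromatic may be F; consequently a CRAC match in a sequence is
exactly a central-Y CARC match in the reversed sequence (a property the
suite tests).  Matches are 5–13 residues.  The unknown residue X
satisfies spacer positions ("any residue") but never an anchor: spacers
are permissive, anchors strict.  Caveolin-binding motifs are the three
spaced-aromatic patterns ΦxΦxxxxΦ (8), ΦxxxxΦxxΦ (9) and ΦxΦxxxxΦxxΦ
(11), Φ ∈ {W, Y, F}.

Enumeration is exhaustive over every admissible spacer-length
combination at every start, so mutually overlapping matches are all
reported.  This is deliberately brute-force-equivalent: the acceptance
property suite checks the engine against an independent
direct-inspection enumerator on hundreds of random sequences.

## Domains and cholesterol sites

Within one class, overlapping matches merge transitively into a
*domain* whose span is the union of its support; the shortest
supporting match is also reported, because published motif tables
typically quote minimal spans.  Domains of different classes never
merge — published inventories list boundary-sharing CRAC and CARC spans
(e.g. hemoglobin β 121–127 and 127–133, sharing Val127) as distinct
entries, and so do we.

Counting CRAC and CARC domains independently can, however, count one
physical docking center twice: a single aromatic flanked by a basic
residue on one side and an aliphatic on the other satisfies both
grammars in opposite orientations.  Cytoglobin is the textbook case —
the CRAC at 119–125 and an overlapping CARC both read central Tyr123.
The *distinct cholesterol sites* statistic therefore merges CRAC/CARC
domains that share a mandatory central aromatic.  This reproduces the
published per-chain counts for cytoglobin (3, hence 6 for the dimer),
neuroglobin (5), myoglobin (2) and hemoglobin α (2).

For hemoglobin β the scan finds **six** sites where the published count
is five: the sixth is a genuine CRAC at 32–41 (³²LLVVYPWTQR⁴¹, central
Tyr36) — its matched text contains the same ³⁶YPWTQRFFESF⁴⁶ segment the
published analysis itself quotes as the β-chain caveolin motif, so the
match is beyond doubt.  The published inventory is internally
inconsistent about this chain (five spans in its table, "four motifs"
in its glycosylation discussion); we report what the grammar yields.
The corresponding α₂β₂ tetramer tally is 2×(2+6) = 16 measured, versus
2×(2+5) = 14 under the published per-chain counts; the acceptance
script reports both.

Caveolin variants: where an 11-mer subsumes an 8-mer over the same
anchors the longest variant labels the merged domain, matching the
published preference for quoting the 11-mer.

## Local alignment

Smith–Waterman with affine gaps via the Gotoh three-state recurrence; a
gap of length L costs `open + L·extend`.  Waterman–Eggert suboptimal
alignments are produced by invalidating the aligned residue pairs of
earlier alignments and re-running, so reported alignments share no
aligned pair; scores are non-increasing.  Self-comparison invalidates
the main diagonal (both orientations) first, making the top reported
alignment the best internal duplication — the classical LALIGN use.
Ties between co-optimal end cells resolve to the smallest (end_a,
end_b) with substitution-preferring traceback; this is deterministic
and reproduces the published coordinates.

Statistics follow the FASTA/LALIGN output conventions: overlap = number
of alignment columns including gap columns; % identity = identical
columns / overlap; % similar = columns whose substitution score is ≥ 0
(identities included) / overlap; gap columns count as neither.  The
≥ 0 cutoff (rather than > 0) is what the published similarity
percentages require and is exposed as a parameter.

**Calibration.**  The published pairwise table names its programs but
not their parameters.  Sweeping {BLOSUM50, BLOSUM62} × open {10, 12,
14} × extend {0.5, 1, 2, 4} identifies exactly one family of settings —
BLOSUM50, open 12, extend 2, the lalign36 protein defaults — at which
the published cells reproduce.  The reproduction also shows the
published column labels to be scrambled: the printed coordinate ranges
are impossible under their own headers (a "neuroglobin" range ending at
152 on a 151-residue chain; a "hemoglobin α" range ending at 146 on a
142-residue chain), while at the calibrated setting the printed
score/identity/similarity/coordinate cells match, exactly, the pairs
cytoglobin×myoglobin (251 / 29.4 / 63.4 / 19–171:3–152),
cytoglobin×hemoglobin-α (227 / 28.9 / 63.1 / 149 columns), 
myoglobin×hemoglobin-β (161 / 25.5 / 58.6 / 145 columns, ranges
swapped), and — for the low-scoring "28 aa overlap" column — the
*second* Waterman–Eggert alignment of myoglobin against itself
(41 / 39.3 / 46.4 / 17–39:57–84), i.e. the internal duplication the
program was run to find.  23 of the 24 published cells reproduce
exactly; the sole exception prints a 154-column overlap where the
computed optimal alignment has 153.  The acceptance tests assert the
reproduction under these re-identified pairings.  This agreement across
every residue of every chain also functions as a whole-sequence
checksum for the bundled FASTA.

## Numbering conventions

All coordinates are 1-based, inclusive.  The default scheme counts the
initiator methionine as residue 1 (database convention, and the
convention of the digitized cavity tables — their heme-ligand
histidines land on His64/His93 of hemoglobin β only under Met-inclusive
counting).  Mature numbering (initiator Met removed, everything shifts
by −1) is an explicit opt-in.  Published region endpoints mix the two
conventions; `validate_endpoints` checks a published endpoint letter
under the declared scheme and under both ±1 shifts, so a systematic
initiator-Met offset is diagnosed rather than silently accepted (the
hemoglobin β pore-lining row is the worked example: its start letter is
mature-convention, its end letter matches neither convention).

## Fixtures and their known defects

The digitized cavity-lining table carries, verbatim, the per-protein
residue lists of the published structural pore analysis: neuroglobin 38
positions and hemoglobin β 35, both equal to the published totals;
myoglobin 53 of the stated 55 (two cells were lost in the available
rendering of the source table and cannot be reconstructed — the
corresponding acceptance assertion is left failing rather than patched);
cytoglobin 56, recorded but asserted nowhere because the source states
two contradictory totals (43 and 57) for that column.  Strict
intersection of the published pore-lining intervals with these sets
gives 10 (cytoglobin), 9 (neuroglobin) and 8 (hemoglobin β), matching
the published counts; for myoglobin strict intersection gives 9 against
a published 10 that requires cavity residue 104 to match a pore interval
starting at 105.  Overlap is strict by default; a `--tolerance` option
widens the interval operand and the report prints both numbers, flagging
the boundary disagreement instead of baking it in.

The published motif-span table is shipped with a `verifiable` flag:
rows whose printed coordinates are internally impossible (start > end,
positions beyond the chain length, endpoint letters that fit neither
grammar) are excluded from exact-span assertions; every verifiable row
is asserted to coincide with an enumerated match.

**Band 3 surrogate.**  The band 3 / AE3 chain (P48751, 1232 residues)
is represented by a deterministic *synthetic* surrogate: an anchor-free
background with one grammar-valid motif instance planted at each
published span (10 cholesterol, 4 caveolin; four spans with misprinted
coordinates are repaired to the nearest grammar-valid reading, noted in
the fixture).  Scanning it tests the pipeline's inventory arithmetic at
full scale, but — unlike the five globins — its counts are correct by
construction, not an independent confirmation of the published band 3
analysis.

## Synthetic data

The generator emulates the study inputs: i.i.d. backgrounds (uniform by
default, human-proteome composition optionally), motif realizations
with chosen spacer geometry, and planted scenarios with serialized
ground truth.  The filler alphabet ACDEGHIMNPQST (the 20 residues minus
all anchors {L,V,Y,F,W,K,R}) provably admits no match of any grammar,
so exact-recovery scenarios have a bidirectional truth table; realistic
backgrounds guarantee only total recall of planted instances.  What
passing these tests shows is that the scanner is complete and exact
over its grammars — not that the grammars themselves predict functional
cholesterol binding (motif presence is known to produce false
positives), and not anything about 3-D structure, which enters only
through digitized third-party annotations.

## Numerical choices

Dynamic-programming scores are floats; with the bundled integer and
half-integer penalties all comparisons are exact in binary floating
point, and every reported alignment must re-score to its claimed value
column-by-column (asserted in tests).  Monte-Carlo checks (composition,
overlap null against the analytic mean m·s/n) use three standard errors
of the empirical mean.  Problem sizes in routine runs — chains ≤ 1232
residues, 10⁴ Monte-Carlo replicates, 100 planted scenarios — keep the
full suite and the acceptance script in the seconds range.

## Limitations

Sequence-only: no docking, energetics or structure prediction; the
topology and cavity inputs are consumed as annotations, not computed.
The motif-count reproduction inherits the source's internal
inconsistencies documented above (hemoglobin β five-vs-six, the
myoglobin cavity table truncation), which are reported honestly rather
than reconciled.  The band 3 figures rest on a synthetic surrogate.
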