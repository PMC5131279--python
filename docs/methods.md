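# Methods

## Motif model

A putative G-quadruplex sequence (PQS) is modelled as exactly four guanine
tracts separated by three loops:

```
G{Y1} X{Y2} G{Y1} X{Y2} G{Y1} X{Y2} G{Y1}
```

Tract length Y1 ranges over `min_tract..max_tract` (default 2..7) and loop
length Y2 over `min_loop..max_loop` (default 1..7); X is any nucleotide,
including G and N.  The implied maximum hit span is
`4·max_tract + 3·max_loop` — 49 bases at the defaults — and is a consequence
of the ranges, not a separate post-filter.  Two-tetrad quadruplexes are
admitted (minimum tract 2); bulged tracts, mismatched tetrads, sliding-score
methods (G4Hunter-style) and intermolecular quadruplexes are out of scope.

### Match semantics

Matching is leftmost and non-overlapping per strand: the scan reports the
match with the smallest start position, then resumes immediately after its
end.  Within a match, tracts are greedy (longest first) and loops lazy
(shortest first), left to right, with full backtracking — so a hit is
reported whenever *any* tract/loop assignment exists at a start position, and
the reported decomposition is the first in that priority order.  Greedy
tracts maximise the guanines assigned to tetrads, which is the conservative
PQS call; the combination is deterministic, so identical inputs always give
byte-identical output.  These are precisely the semantics of a Python regular
expression with greedy tract quantifiers and lazy loop quantifiers, which is
the implementation; the test suite proves equivalence against an exhaustive
brute-force enumerator on a thousand random sequences.

Consequences worth knowing:

- A G-run longer than `max_tract` contributes its leftmost `max_tract`
  guanines to a tract; surplus guanines can be consumed by the adjacent loop
  (X includes G) or by a later tract via backtracking.
- A five-tract region yields one hit (the leftmost four tracts), not an
  enumeration of alternatives.
- `N` is accepted in loops ("any nucleotide") but never counts as a tract
  guanine; all other IUPAC ambiguity codes are rejected outright rather than
  silently matched.

### Strands and coordinates

Coordinates are 1-based inclusive in input-sequence space.  The antisense
scan runs on the reverse complement and its hits are mapped back through
`(start, end) -> (L-end+1, L-start+1)`; hit sequences are reported as read
5'→3' on the hit strand.  The two strand scans are independent — non-overlap
is enforced within each strand only, and a sense hit may overlap an antisense
hit.  RNA input is handled by mapping U→T for the scan and restoring U in
reported hit sequences; a sequence containing both T and U is rejected.

## cG/cC score

The cG score of a window is cumulative over every overlapping all-G
substring: each contributes 10 per base (10 for a lone G, 20 for each GG, 30
for each GGG, "and so on").  Summing over the windows inside a maximal run of
L guanines gives the closed form

```
cG(run of L) = Σ_{k=1..L} 10·k·(L−k+1) = 10·L(L+1)(L+2)/6
```

so runs score 10, 40, 100, 200, ... — the score grows cubically with run
length, rewarding long tracts much more than scattered guanines.  cC is the
same with cytosine.  The cumulative-overlapping-window reading is the one
consistent with the verbal definition this score follows; the tests pin it to
a brute-force all-substring oracle exhaustively for short strings and on
10,000 random strings.  `N` contributes nothing and breaks runs.

The cG/cC ratio compares G-richness with C-richness of the same window:
values well above 1 indicate the G-rich strand dominates locally and the
motif is more likely to readily fold.  The ratio is `inf` when cC = 0 < cG
and undefined (NaN, serialised `NA`) when both are 0; sentinels, not
exceptions, so tabular output stays total.

Hits are scored over `[start − flank, end + flank]` clipped to the sequence,
on the hit strand (an antisense hit is scored on the reverse complement of
its window, reflecting the guanines of the strand the motif lies on).  The
default flank is 15 nt per side: "a few base pairs upstream and downstream"
is not quantified by the score's description, so 15 — half a maximal loop
short of a third tetrad span, and in line with flank conventions of
context-aware G4 scores — was fixed once and made configurable; `flank=0`
scores the motif alone.

## Interaction-record store

Records follow a flat schema of 20 fields (identifiers, target, binding
parameters ΔTm [°C], Ka [1/M], Kd [M], provenance).  Validation enforces:
non-empty unique interaction IDs, category ∈ {DNA, RNA}, target sequence
alphabet consistent with category, Ka and Kd strictly positive when present,
PMID all digits.  Persistence is TSV (header mandatory, list fields joined on
";", UTF-8) or JSON (array of snake_case objects); loading and saving
round-trip exactly.

Search semantics are deliberately simple and deterministic: case-insensitive
substring matching everywhere, including PMIDs and sequences.  Quick search
matches one query against every text field; advanced search AND-combines up
to ten per-field criteria (interaction_id, target_name, target_sequence,
protein_name, uniprot_id, uniprot_entry_name, gene_name, gene_synonyms, pmid,
author).  A single-criterion advanced search is therefore always a subset of
the quick search for the same string.  Results are sorted by interaction ID.
Interaction IDs are free-form strings (both `G4DIP1`- and `G4PIBD28`-style
patterns occur in practice), so no ID grammar is enforced, and the same
protein may appear under distinct IDs in both categories.

## Synthetic data

`generate_sequence_with_motifs` emulates the one property a scanner-recall
experiment needs: a background that provably contains no motif on either
strand, with grammar-conforming motifs planted at known coordinates.
Background nucleotides are i.i.d. over {A, C, G, T} with guanine and cytosine
run lengths capped below `min_tract`; planted loops use {A, T} only and every
motif is flanked by an A, so the scanner's greedy decomposition recovers the
planted one exactly; inter-motif gaps exceed `max_loop`, so no match can
bridge two motifs.  Antisense motifs are planted as reverse complements.
Each fixture is re-verified by scanning it after assembly.  This emulates
none of the composition structure of real genomes (repeats, CpG islands,
strand asymmetries, near-miss motifs with 8-nt loops or single-G "tracts"),
so perfect recall on fixtures demonstrates correctness of the matcher, not
real-genome precision/recall, which depends on the grammar itself.

`generate_records` emits schema-valid records with plausible parameters: Kd
log-uniform over 1e-9..1e-6 M (typical of reported G4-protein affinities),
ΔTm uniform over 0..25 °C, categories split ~50/50, 7-digit PMIDs.  On
request the first three records are fixed anchors reproducing the worked
search identifiers (Nucleolin under `G4DIP1`, a `G4PIBD28` entry with PMID
25679041, an FMRP entry); the anchors are synthetic stand-ins — only those
identifiers are real, every other field value is invented.  Generation is a
pure function of its arguments; seeds are explicit, no global random state.

## Numerical and design choices

- Scores are exact integers (multiples of 10); the only floating-point
  quantity is the ratio.  No tolerances are needed anywhere.
- Scan and search are fully deterministic; ties cannot occur by construction
  (priority order is total).
- Degenerate inputs: empty sequences scan to zero hits and score 0/0/NA;
  empty search queries are errors (distinct from match-all); hits outside a
  sequence's bounds are errors.
- Problem sizes in the test suite — 1,000 random sequences of ≤ 200 nt for
  oracle equivalence, 100 seeds × 1,000 nt × 5 motifs for recall, 10,000
  random strings for scoring, a 200-record store for search — were chosen as
  the smallest sets that exercise every code path and boundary many times
  over; all are exact checks, so larger sizes would add runtime, not
  information.
- CLI exit codes: 0 success (empty results included), 1 usage error, 2
  data/validation error.  Results go to stdout or `--out`; logs to stderr.

## Known limitations

- The grammar is fixed at four tracts; regions with more tracts are not
  enumerated combinatorially.
- No thermodynamic stability estimate, fold/unfold classification threshold,
  or sliding-window score is provided; the cG/cC ratio is a relative
  propensity, not a probability.
- The store is a flat file: no indexing, no relational constraints beyond ID
  uniqueness, and substring search semantics (a PMID query matches any record
  whose PMID *contains* the digits).
- Genome-scale scanning works but streams nothing: sequences are held in
  memory.
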