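"""Putative G-quadruplex sequence (PQS) scanner.

A PQS is four guanine tracts separated by three loops:

    G{Y1} X{Y2} G{Y1} X{Y2} G{Y1} X{Y2} G{Y1}

where each tract length Y1 is 2-7 guanines, each loop length Y2 is 1-7
nucleotides of any composition (X = A, C, G, T/U or N), giving a default
maximum motif span of 4*7 + 3*7 = 49 bases.  Matching is leftmost and
non-overlapping per strand: after each accepted match the scan resumes just
past its end.  Within a match, tracts are greedy (longest first) and loops
lazy (shortest first), with backtracking, so a hit is reported whenever any
tract/loop assignment exists at that start; the reported decomposition is the
one preferred by that order.  These are exactly the semantics of a Python
regular expression with greedy tract quantifiers and lazy loop quantifiers,
which is how the scan is implemented.

Both strands are scanned independently: the antisense scan runs on the
reverse complement and hit coordinates are mapped back to input coordinates
(1-based, inclusive).  Sense and antisense hits may overlap each other.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Literal

from .errors import AlphabetError
from .sequences import NucleotideSequence, normalize_for_scan, reverse_complement_str

N_TRACTS = 4  # the grammar has exactly four G-tracts and three loops

Strand = Literal["sense", "antisense"]

_SCAN_ALPHABET = frozenset("ACGTN")


@dataclass(frozen=True)
class PQSParams:
    """Scanner configuration.

    ``min_tract``/``max_tract`` bound the guanine tract length Y1 (defaults
    2..7); ``min_loop``/``max_loop`` bound the loop length Y2 (defaults 1..7).
    ``scan_antisense`` toggles the reverse-complement scan.
    """

    min_tract: int = 2
    max_tract: int = 7
    min_loop: int = 1
    max_loop: int = 7
    scan_antisense: bool = True

    def __post_init__(self) -> None:
        if not (1 <= self.min_tract <= self.max_tract):
            raise ValueError(
                f"require 1 <= min_tract <= max_tract, got {self.min_tract}..{self.max_tract}"
            )
        if not (0 < self.min_loop <= self.max_loop):
            raise ValueError(
                f"require 0 < min_loop <= max_loop, got {self.min_loop}..{self.max_loop}"
            )

    @property
    def n_tracts(self) -> int:
        return N_TRACTS


@dataclass(frozen=True)
class PQSHit:
    """One detected motif, in 1-based inclusive input-sequence coordinates.

    ``hit_seq`` is the motif as read 5'->3' on the hit strand, so an
    antisense hit's sequence is the reverse complement of the corresponding
    stretch of the input.
    """

    seq_id: str
    strand: Strand
    start: int
    end: int
    length: int
    hit_seq: str
    tract_lengths: tuple[int, int, int, int]
    loop_lengths: tuple[int, int, int]

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != self.length:
            raise ValueError("hit length inconsistent with coordinates")
        if sum(self.tract_lengths) + sum(self.loop_lengths) != self.length:
            raise ValueError("hit length inconsistent with decomposition")

    def decompose(self) -> tuple[list[str], list[str]]:
        """Split hit_seq into its four tracts and three loops."""
        tracts, loops, pos = [], [], 0
        for i in range(N_TRACTS):
            t = self.tract_lengths[i]
            tracts.append(self.hit_seq[pos:pos + t])
            pos += t
            if i < N_TRACTS - 1:
                l = self.loop_lengths[i]
                loops.append(self.hit_seq[pos:pos + l])
                pos += l
        return tracts, loops


@dataclass(frozen=True)
class ScanResult:
    """All hits of one sequence, sorted by (strand, start), with counts."""

    hits: tuple[PQSHit, ...]
    n_sense: int
    n_antisense: int
    n_total: int

    def __post_init__(self) -> None:
        if self.n_total != self.n_sense + self.n_antisense or self.n_total != len(self.hits):
            raise ValueError("inconsistent hit counts")


@lru_cache(maxsize=32)
def _compile_pattern(min_tract: int, max_tract: int, min_loop: int, max_loop: int) -> re.Pattern:
    tract = f"(G{{{min_tract},{max_tract}}})"
    loop = f"([ACGTN]{{{min_loop},{max_loop}}}?)"
    return re.compile(tract + (loop + tract) * (N_TRACTS - 1))


def max_motif_span(params: PQSParams | None = None) -> int:
    """Maximum possible hit length: 4 maximal tracts plus 3 maximal loops.

    49 bases at the default parameters.  No reported hit can exceed it, so it
    is implied by the ranges rather than applied as a post-filter.
    """
    p = params or PQSParams()
    return N_TRACTS * p.max_tract + (N_TRACTS - 1) * p.max_loop


def find_pqs_single_strand(
    seq: str,
    params: PQSParams | None = None,
    seq_id: str = "",
    strand: Strand = "sense",
) -> list[PQSHit]:
    """Leftmost, non-overlapping grammar matches on one already-normalised strand.

    ``seq`` must be upper case over ``ACGTN`` (U pre-mapped to T).
    """
    p = params or PQSParams()
    bad = set(seq) - _SCAN_ALPHABET
    if bad:
        raise AlphabetError(f"scan input contains illegal characters: {sorted(bad)}")
    pattern = _compile_pattern(p.min_tract, p.max_tract, p.min_loop, p.max_loop)
    hits = []
    for m in pattern.finditer(seq):
        groups = m.groups()
        hits.append(
            PQSHit(
                seq_id=seq_id,
                strand=strand,
                start=m.start() + 1,
                end=m.end(),
                length=m.end() - m.start(),
                hit_seq=m.group(0),
                tract_lengths=tuple(len(groups[i]) for i in (0, 2, 4, 6)),
                loop_lengths=tuple(len(groups[i]) for i in (1, 3, 5)),
            )
        )
    return hits


def map_antisense_coordinates(start_rc: int, end_rc: int, length: int) -> tuple[int, int]:
    """Mirror 1-based inclusive coordinates on the reverse complement back to
    input coordinates.  Applying the map twice returns the original pair."""
    if not (1 <= start_rc <= end_rc <= length):
        raise ValueError(
            f"coordinates ({start_rc}, {end_rc}) out of bounds for length {length}"
        )
    return length - end_rc + 1, length - start_rc + 1


def scan_both_strands(s: NucleotideSequence, params: PQSParams | None = None) -> ScanResult:
    """Scan a sequence on the sense strand and (optionally) its reverse
    complement, reporting all hits in input coordinates.

    The two scans are independent: non-overlap is enforced within each strand
    only, and a sense hit may overlap an antisense hit.  RNA hit sequences are
    reported with U restored.
    """
    p = params or PQSParams()
    norm = normalize_for_scan(s)
    hits = find_pqs_single_strand(norm, p, seq_id=s.id, strand="sense")
    n_sense = len(hits)
    if p.scan_antisense:
        rc = reverse_complement_str(norm, "DNA")
        for h in find_pqs_single_strand(rc, p, seq_id=s.id, strand="antisense"):
            start, end = map_antisense_coordinates(h.start, h.end, len(norm))
            hits.append(
                PQSHit(
                    seq_id=h.seq_id, strand="antisense", start=start, end=end,
                    length=h.length, hit_seq=h.hit_seq,
                    tract_lengths=h.tract_lengths, loop_lengths=h.loop_lengths,
                )
            )
    n_antisense = len(hits) - n_sense
    if s.kind == "RNA":
        hits = [
            PQSHit(
                seq_id=h.seq_id, strand=h.strand, start=h.start, end=h.end,
                length=h.length, hit_seq=h.hit_seq.replace("T", "U"),
                tract_lengths=h.tract_lengths, loop_lengths=h.loop_lengths,
            )
            for h in hits
        ]
    hits.sort(key=lambda h: (h.strand != "sense", h.start))
    return ScanResult(
        hits=tuple(hits),
        n_sense=n_sense,
        n_antisense=n_antisense,
        n_total=len(hits),
    )
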