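"""cG / cC scoring of quadruplex motifs and their flanking context.

The cG score of a substring is cumulative over every overlapping all-G
window it contains: each lone G contributes 10, each GG pair 20, each GGG
triplet 30, and so on.  A maximal run of L consecutive guanines therefore
contributes

    sum_{k=1..L} 10 * k * (L - k + 1)  =  10 * L * (L + 1) * (L + 2) / 6

(10 for L=1, 40 for L=2, 100 for L=3, ...).  The cC score is identical with
cytosine in place of guanine, and the cG/cC ratio gauges whether local
G-richness dominates C-richness: motifs with a higher ratio are more likely
to readily fold into a quadruplex.  Scores are computed over a window that
extends the motif by a configurable flank (default 15 nt per side) to damp
false positives from C-rich surroundings; flank=0 scores the motif alone.

The ratio uses IEEE sentinels rather than exceptions: ``inf`` when cC is 0
and cG positive, ``nan`` ("undefined") when both are 0.  ``N`` contributes
nothing to either score and breaks runs.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass

from .errors import AlphabetError
from .sequences import NucleotideSequence, normalize_for_scan, reverse_complement_str
from .scanner import PQSHit

_SCAN_ALPHABET = frozenset("ACGTN")
_G_RUN = re.compile("G+")
_C_RUN = re.compile("C+")

DEFAULT_FLANK = 15


@dataclass(frozen=True)
class G4Score:
    """cG, cC and their ratio over a scoring window.

    ``window_start``/``window_end`` are the actual (clipped) 1-based input
    coordinates scored; ``flank`` is the number of nucleotides requested on
    each side of the motif.
    """

    cG: int
    cC: int
    ratio: float  # cG/cC; inf if cC==0<cG; nan if both zero
    window_start: int
    window_end: int
    flank: int


def _run_score(run_length: int) -> int:
    return 10 * run_length * (run_length + 1) * (run_length + 2) // 6


def _validate(s: str) -> None:
    bad = set(s) - _SCAN_ALPHABET
    if bad:
        raise AlphabetError(f"scoring input contains illegal characters: {sorted(bad)}")


def cg_score(s: str) -> int:
    """Cumulative guanine score: every overlapping all-G window of length k
    contributes 10*k."""
    _validate(s)
    return sum(_run_score(m.end() - m.start()) for m in _G_RUN.finditer(s))


def cc_score(s: str) -> int:
    """Cumulative cytosine score, symmetric to :func:`cg_score`."""
    _validate(s)
    return sum(_run_score(m.end() - m.start()) for m in _C_RUN.finditer(s))


def cg_cc_ratio(s: str) -> float:
    """cG/cC with sentinel values instead of exceptions."""
    cg, cc = cg_score(s), cc_score(s)
    if cc > 0:
        return cg / cc
    return math.inf if cg > 0 else math.nan


def format_ratio(ratio: float) -> str:
    """Serialise a ratio for tabular output: ``inf`` / ``NA`` / decimal."""
    if math.isnan(ratio):
        return "NA"
    if math.isinf(ratio):
        return "inf"
    return format(ratio, "g")


def score_window(s: str) -> tuple[int, int, float]:
    """cG, cC and ratio of one window in a single pass."""
    cg, cc = cg_score(s), cc_score(s)
    if cc > 0:
        ratio = cg / cc
    else:
        ratio = math.inf if cg > 0 else math.nan
    return cg, cc, ratio


def score_hit(hit: PQSHit, full_seq: NucleotideSequence, flank: int = DEFAULT_FLANK) -> G4Score:
    """Score a scanner hit over its motif plus flanking context.

    The window ``[start - flank, end + flank]`` is clipped to the sequence and
    scored on the hit strand: antisense hits are scored on the reverse
    complement of the window, so their cG reflects guanines of the strand the
    motif actually lies on.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    L = len(full_seq)
    if not (1 <= hit.start <= hit.end <= L):
        raise ValueError(
            f"hit {hit.start}..{hit.end} outside sequence {full_seq.id!r} of length {L}"
        )
    ws = max(1, hit.start - flank)
    we = min(L, hit.end + flank)
    window = normalize_for_scan(full_seq)[ws - 1:we]
    if hit.strand == "antisense":
        window = reverse_complement_str(window, "DNA")
    cg, cc, ratio = score_window(window)
    return G4Score(cG=cg, cC=cc, ratio=ratio, window_start=ws, window_end=we, flank=flank)
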