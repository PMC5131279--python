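"""Nucleotide sequence containers, FASTA I/O and strand operations.

Sequences are DNA or RNA over the alphabet ``{A, C, G, T, U, N}``.  Any other
IUPAC ambiguity code is rejected: the motif grammar downstream treats ``N`` as
"any nucleotide" in loops but never as a guanine, and silently matching other
ambiguity codes would blur that distinction.  Input is normalised to upper
case; a sequence is classified as RNA iff it contains ``U`` and no ``T``
(mixing both in one record is an error).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal

from Bio import SeqIO

from .errors import AlphabetError, FastaParseError

logger = logging.getLogger(__name__)

DNA_ALPHABET = frozenset("ACGTN")
RNA_ALPHABET = frozenset("ACGUN")
FULL_ALPHABET = frozenset("ACGTUN")

_DNA_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_RNA_COMPLEMENT = str.maketrans("ACGUN", "UGCAN")

Kind = Literal["DNA", "RNA"]


@dataclass(frozen=True)
class NucleotideSequence:
    """An identified, normalised DNA or RNA sequence.

    Attributes
    ----------
    id : str
        Record identifier (first whitespace-delimited token of a FASTA header).
    seq : str
        Upper-case sequence over ``ACGTN`` (DNA) or ``ACGUN`` (RNA).  May be
        empty.
    kind : {"DNA", "RNA"}
    description : str
        Remainder of the FASTA header after the id, if any.
    """

    id: str
    seq: str
    kind: Kind = "DNA"
    description: str = ""

    def __post_init__(self) -> None:
        allowed = DNA_ALPHABET if self.kind == "DNA" else RNA_ALPHABET
        for pos, ch in enumerate(self.seq, start=1):
            if ch not in allowed:
                raise AlphabetError(
                    f"record {self.id!r}: illegal character {ch!r} at position "
                    f"{pos} for kind {self.kind}"
                )

    def __len__(self) -> int:
        return len(self.seq)

    @classmethod
    def from_string(
        cls, id: str, raw: str, description: str = ""
    ) -> "NucleotideSequence":
        """Normalise a raw sequence string and detect whether it is DNA or RNA.

        Mixed-case input is accepted (a warning is logged); whitespace is not.
        A sequence containing both ``T`` and ``U`` is rejected.
        """
        if raw != raw.upper():
            logger.warning("record %r: mixed/lower-case input normalised to upper case", id)
            raw = raw.upper()
        for pos, ch in enumerate(raw, start=1):
            if ch not in FULL_ALPHABET:
                raise AlphabetError(
                    f"record {id!r}: illegal character {ch!r} at position {pos}"
                )
        has_t, has_u = "T" in raw, "U" in raw
        if has_t and has_u:
            raise AlphabetError(f"record {id!r}: sequence contains both T and U")
        kind: Kind = "RNA" if has_u else "DNA"
        return cls(id=id, seq=raw, kind=kind, description=description)


def read_fasta(path: str | Path) -> list[NucleotideSequence]:
    """Read a FASTA file into a list of :class:`NucleotideSequence`.

    Both line-wrapped and single-line records are accepted.  A file whose
    first non-blank line is not a header raises :class:`FastaParseError`
    naming the offending line.
    """
    path = Path(path)
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise FastaParseError(
                    f"{path}: line {lineno}: sequence data before first '>' header"
                )
            break
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        records.append(NucleotideSequence.from_string(rec.id, str(rec.seq), desc))
    return records


def write_fasta(path: str | Path, seqs: Iterable[NucleotideSequence]) -> None:
    """Write sequences as single-line FASTA records."""
    with Path(path).open("w") as fh:
        for s in seqs:
            header = f">{s.id} {s.description}".rstrip()
            fh.write(f"{header}\n{s.seq}\n")


def complement(seq: str, kind: Kind = "DNA") -> str:
    """Base-pair complement of a plain sequence string, without reversal."""
    table = _DNA_COMPLEMENT if kind == "DNA" else _RNA_COMPLEMENT
    return seq.translate(table)


def reverse_complement_str(seq: str, kind: Kind = "DNA") -> str:
    """Reverse complement of a plain sequence string."""
    return complement(seq, kind)[::-1]


def reverse_complement(s: NucleotideSequence) -> NucleotideSequence:
    """Reverse complement; DNA pairs A-T, RNA pairs A-U, G-C always, N-N."""
    return NucleotideSequence(
        id=s.id,
        seq=reverse_complement_str(s.seq, s.kind),
        kind=s.kind,
        description=s.description,
    )


def normalize_for_scan(s: NucleotideSequence) -> str:
    """Map U to T so one pattern engine serves DNA and RNA alike.

    The reporting layer restores U in hit sequences of RNA records.
    """
    return s.seq.replace("U", "T")
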