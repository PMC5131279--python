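"""Deterministic generators of scanner inputs with planted ground truth and of
synthetic interaction records.

``generate_sequence_with_motifs`` builds a DNA sequence whose background can
contain no quadruplex motif on either strand, then plants a known number of
grammar-conforming motifs (sense or antisense) at known coordinates, so that
scanner recall can be measured against exact truth.  Motif-freeness of the
background is guaranteed by construction — guanine and cytosine run lengths
are kept below the minimum tract length, loop characters are drawn from
``{A, T}`` only, and inter-motif gaps exceed the maximum loop length — and
then re-verified by scanning the assembled sequence.

``generate_records`` emits schema-valid interaction records with plausible
binding parameters (Kd log-uniform over 1e-9..1e-6 M, delta-Tm uniform over
0..25 degC, categories split ~50/50).  On request the first three records are
fixed "anchor" entries exercising the store's worked search examples
(a Nucleolin entry under interaction ID G4DIP1, an entry with PMID 25679041,
and an FMRP entry); these anchors are synthetic stand-ins that reproduce only
those identifiers, every other field value is invented.

All generation is a pure function of its arguments; the seed fully determines
the output and no global random state is touched.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .scanner import PQSParams, PQSHit, scan_both_strands, Strand
from .sequences import NucleotideSequence, reverse_complement_str, write_fasta
from .store import InteractionRecord

_AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class PlantedMotif:
    start: int  # 1-based inclusive, input coordinates
    end: int
    strand: Strand
    tract_lengths: tuple[int, int, int, int]
    loop_lengths: tuple[int, int, int]


@dataclass(frozen=True)
class PlantedTruth:
    sequence: NucleotideSequence
    motifs: tuple[PlantedMotif, ...]


def _background(rng: np.random.Generator, n: int, min_tract: int) -> str:
    """Background that cannot host a G-tract on either strand.

    i.i.d. over {A, C, G, T} but with G and C run lengths capped below
    ``min_tract`` (for min_tract <= 1 G and C are excluded entirely).
    """
    if n <= 0:
        return ""
    if min_tract <= 1:
        return "".join(rng.choice(["A", "T"], size=n))
    chars = []
    run_char, run_len = "", 0
    draws = rng.choice(list("ACGT"), size=n, p=[0.35, 0.15, 0.15, 0.35])
    for c in draws:
        c = str(c)
        if c in "GC" and c == run_char and run_len >= min_tract - 1:
            c = "A" if run_char == "G" else "T"
        if c == run_char:
            run_len += 1
        else:
            run_char, run_len = c, 1
        chars.append(c)
    return "".join(chars)


def _motif(rng: np.random.Generator, params: PQSParams) -> tuple[str, tuple, tuple]:
    tracts = tuple(int(t) for t in rng.integers(params.min_tract, params.max_tract + 1, 4))
    loops = tuple(int(l) for l in rng.integers(params.min_loop, params.max_loop + 1, 3))
    # loops over {A,T} only: no G or C on either strand outside the tracts,
    # so the scanner's greedy decomposition recovers the planted one exactly
    parts = []
    for i in range(4):
        parts.append("G" * tracts[i])
        if i < 3:
            parts.append("".join(rng.choice(["A", "T"], size=loops[i])))
    return "".join(parts), tracts, loops


def generate_sequence_with_motifs(
    length: int,
    n_motifs: int,
    params: PQSParams | None = None,
    strand_mix: float = 0.5,
    seed: int = 0,
    seq_id: str = "synthetic",
) -> PlantedTruth:
    """Plant ``n_motifs`` non-overlapping quadruplex motifs in a motif-free
    background of the given total length.

    ``strand_mix`` is the probability that a motif is planted on the
    antisense strand (as the reverse complement of a sense-style motif);
    ignored when ``params.scan_antisense`` is false.  Raises ``ValueError``
    when the motifs cannot be packed into ``length``.
    """
    p = params or PQSParams()
    if not 0.0 <= strand_mix <= 1.0:
        raise ValueError("strand_mix must be in [0, 1]")
    if not p.scan_antisense:
        strand_mix = 0.0
    rng = np.random.default_rng([seed, 0x9C5])

    motifs = [_motif(rng, p) for _ in range(n_motifs)]
    antisense = rng.random(n_motifs) < strand_mix

    # interior gaps long enough that no match can bridge two motifs, and with
    # an A forced at each motif boundary so adjacent background G/C cannot
    # extend a planted tract
    min_interior = p.max_loop + 2
    min_total = sum(len(m[0]) for m in motifs) + max(0, n_motifs - 1) * min_interior
    slack = length - min_total
    if slack < 0:
        raise ValueError(
            f"cannot pack {n_motifs} motifs ({min_total} nt minimum) into {length} nt"
        )
    extra = rng.multinomial(slack, [1.0 / (n_motifs + 1)] * (n_motifs + 1))
    gap_lens = [int(extra[0])]
    gap_lens += [min_interior + int(e) for e in extra[1:n_motifs]]
    if n_motifs > 0:
        gap_lens.append(int(extra[n_motifs]))

    def gap(n: int, pad_left: bool, pad_right: bool) -> str:
        if n <= 0:
            return ""
        core = _background(rng, n, p.min_tract)
        if pad_left and n >= 1:
            core = "A" + core[1:]
        if pad_right and n >= 1:
            core = core[:-1] + "A"
        return core

    pieces = []
    truth = []
    pos = 0
    for i, (motif_seq, tracts, loops) in enumerate(motifs):
        g = gap(gap_lens[i], pad_left=i > 0, pad_right=True)
        pieces.append(g)
        pos += len(g)
        start = pos + 1
        if antisense[i]:
            pieces.append(reverse_complement_str(motif_seq, "DNA"))
            strand: Strand = "antisense"
        else:
            pieces.append(motif_seq)
            strand = "sense"
        pos += len(motif_seq)
        truth.append(PlantedMotif(start, pos, strand, tracts, loops))
    if n_motifs > 0:
        pieces.append(gap(gap_lens[-1], pad_left=True, pad_right=False))
    else:
        pieces.append(_background(rng, length, p.min_tract))

    seq = NucleotideSequence(id=seq_id, seq="".join(pieces), kind="DNA")
    assert len(seq) == length
    planted = PlantedTruth(sequence=seq, motifs=tuple(truth))
    _verify(planted, p)
    return planted


def _verify(planted: PlantedTruth, params: PQSParams) -> None:
    result = scan_both_strands(planted.sequence, params)
    found = {
        (h.start, h.end, h.strand, h.tract_lengths, h.loop_lengths)
        for h in result.hits
    }
    expected = {
        (m.start, m.end, m.strand, m.tract_lengths, m.loop_lengths)
        for m in planted.motifs
    }
    if found != expected:
        raise RuntimeError(
            "planted fixture failed self-verification: "
            f"scanner found {sorted(found)}, planted {sorted(expected)}"
        )


def write_planted_fixture(
    planted: PlantedTruth, fasta_path: str | Path, truth_path: str | Path
) -> None:
    """Persist a planted fixture as FASTA plus a truth TSV."""
    write_fasta(fasta_path, [planted.sequence])
    with Path(truth_path).open("w") as fh:
        fh.write("seq_id\tstrand\tstart\tend\ttract_lengths\tloop_lengths\n")
        for m in planted.motifs:
            strand = "+" if m.strand == "sense" else "-"
            fh.write(
                f"{planted.sequence.id}\t{strand}\t{m.start}\t{m.end}\t"
                f"{','.join(map(str, m.tract_lengths))}\t"
                f"{','.join(map(str, m.loop_lengths))}\n"
            )


def _anchor_records() -> list[InteractionRecord]:
    """Synthetic stand-ins reproducing the store's worked search identifiers."""
    return [
        InteractionRecord(
            interaction_id="G4DIP1",
            category="DNA",
            protein_name="Nucleolin",
            protein_synonyms=["NCL", "C23"],
            uniprot_id="P19338",
            uniprot_entry_name="NUCL_HUMAN",
            organism="Homo sapiens",
            gene_name="NCL",
            gene_synonyms=[],
            target_name="c-myc promoter NHE III quadruplex",
            target_sequence="TGGGGAGGGTGGGGAGGGTGGGGAAGG",
            delta_tm=12.5,
            kd=2.4e-8,
            technique="EMSA",
            pmid="10094414",
            authors=["Hanakahi L", "Sun H", "Maizels N"],
        ),
        InteractionRecord(
            interaction_id="G4PIBD28",
            category="DNA",
            protein_name="Nucleoside diphosphate kinase 1",
            protein_synonyms=["zmNDPK1", "NM23-H2 homologue"],
            uniprot_id="P93555",
            uniprot_entry_name="NDK1_MAIZE",
            organism="Zea mays",
            gene_name="NDPK1",
            target_name="maize quadruplex DNA",
            target_sequence="GGGAGGGAGGGAGGGA",
            kd=8.0e-9,
            technique="EMSA",
            pmid="25679041",
            authors=["Kopylov M", "Bass H W"],
        ),
        InteractionRecord(
            interaction_id="G4RIP1",
            category="RNA",
            protein_name="FMRP",
            protein_synonyms=["Fragile X mental retardation protein"],
            uniprot_id="Q06787",
            uniprot_entry_name="FMR1_HUMAN",
            organism="Homo sapiens",
            gene_name="FMR1",
            target_name="sc1 mRNA quadruplex",
            target_sequence="GGAGGUAGGAGGUAGG",
            kd=5.0e-9,
            technique="Filter binding",
            pmid="11719189",
            authors=["Darnell J C", "Brown V"],
        ),
    ]


_PROTEIN_POOL = [
    ("RHAU helicase", ["DHX36", "G4R1"], "DHX36"),
    ("BLM helicase", ["Bloom syndrome protein"], "BLM"),
    ("UP1", ["hnRNP A1 fragment"], "HNRNPA1"),
    ("TPP1", ["ACD"], "ACD"),
    ("TDP-43", ["TAR DNA-binding protein 43"], "TARDBP"),
    ("SRSF1", ["ASF", "SF2"], "SRSF1"),
    ("POT1", ["Protection of telomeres 1"], "POT1"),
    ("TRF2", ["TERF2"], "TERF2"),
    ("NOA1", ["Nitric oxide-associated protein 1"], "NOA1"),
    ("IGF2 binding factor", ["IMP"], "IGF2BP1"),
]
_ORGANISMS = ["Homo sapiens", "Mus musculus", "Zea mays", "Saccharomyces cerevisiae",
              "Escherichia coli"]
_TECHNIQUES = ["ITC", "SPR", "EMSA", "CD spectroscopy", "FRET",
               "Fluorescence titration", "NMR titration"]
_SURNAMES = ["Garcia", "Chen", "Patel", "Okafor", "Ivanova", "Schmidt", "Rossi",
             "Tanaka", "Silva", "Novak"]


def _random_target(rng: np.random.Generator, category: str, n: int = 24) -> str:
    letters = ["A", "C", "G", "T" if category == "DNA" else "U"]
    return "".join(rng.choice(letters, size=n, p=[0.2, 0.15, 0.45, 0.2]))


def generate_records(
    n: int, seed: int = 0, anchors: bool = False
) -> list[InteractionRecord]:
    """Generate ``n`` schema-valid interaction records, deterministically.

    With ``anchors=True`` (requires ``n >= 3``) the first three records are
    the fixed anchor entries used by the worked search examples.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    records: list[InteractionRecord] = []
    if anchors:
        if n < 3:
            raise ValueError("anchors=True requires n >= 3")
        records.extend(_anchor_records())
    rng = np.random.default_rng([seed, 0x64B])
    i = 0
    while len(records) < n:
        category = "DNA" if i % 2 == 0 else "RNA"
        name, synonyms, gene = _PROTEIN_POOL[i % len(_PROTEIN_POOL)]
        # generated IDs start at 200 so none contains an anchor ID as substring
        rid = f"G4DIP{200 + i}" if category == "DNA" else f"G4RIP{200 + i}"
        kd = float(10 ** rng.uniform(-9, -6)) if rng.random() < 0.8 else None
        ka = float(1.0 / kd) if kd is not None and rng.random() < 0.5 else None
        delta_tm = float(np.round(rng.uniform(0, 25), 1)) if rng.random() < 0.7 else None
        n_pdb = int(rng.integers(0, 3))
        pdb_ids = [
            f"{rng.integers(1, 10)}" + "".join(rng.choice(list("ABCDEFXYZ"), size=3))
            for _ in range(n_pdb)
        ]
        residues = [
            f"{rng.choice(list('RKHSTNQ'))}{rng.integers(10, 400)}"
            for _ in range(int(rng.integers(0, 4)))
        ]
        authors = [
            f"{rng.choice(_SURNAMES)} {chr(65 + int(rng.integers(0, 26)))}"
            for _ in range(int(rng.integers(1, 4)))
        ]
        records.append(
            InteractionRecord(
                interaction_id=rid,
                category=category,
                protein_name=f"{name} variant {i}",
                protein_synonyms=list(synonyms),
                uniprot_id=f"P{rng.integers(10000, 99999)}",
                uniprot_entry_name=f"{gene}_{'HUMAN' if i % 3 else 'MOUSE'}",
                organism=str(rng.choice(_ORGANISMS)),
                gene_name=gene,
                gene_synonyms=[f"{gene}L{i}"] if rng.random() < 0.5 else [],
                protein_fasta="".join(rng.choice(list(_AMINO_ACIDS), size=40)),
                target_name=f"target quadruplex {i}",
                target_sequence=_random_target(rng, category),
                delta_tm=delta_tm,
                ka=ka,
                kd=kd,
                pdb_ids=pdb_ids,
                interacting_residues=residues,
                technique=str(rng.choice(_TECHNIQUES)),
                # 7-digit PMIDs: an 8-digit anchor PMID can never be a substring
                pmid=str(rng.integers(1_000_000, 9_999_999)),
                authors=authors,
            )
        )
        i += 1
    return records
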