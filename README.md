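# g4kit

Desk-scale toolkit for putative G-quadruplex sequence (PQS) analysis and for
curated G-quadruplex/protein interaction records.

G-quadruplexes (G4) are four-stranded nucleic-acid structures built from
stacked tetrads of guanines, found in telomeres, promoters and UTRs, and bound
by proteins of therapeutic interest (Nucleolin, FMRP, helicases, ...).  g4kit
provides three things:

1. **A PQS scanner.**  A putative quadruplex sequence is a match of the motif
   grammar

   ```
   G{Y1} X{Y2} G{Y1} X{Y2} G{Y1} X{Y2} G{Y1}
   ```

   with tract lengths Y1 = 2..7 guanines, loop lengths Y2 = 1..7 nucleotides of
   any composition (X in {A, C, G, T/U, N}), giving a default maximum motif
   span of 4·7 + 3·7 = 49 bases.  The scanner reports leftmost,
   non-overlapping matches with 1-based start/end coordinates, on both the
   sense strand and the reverse complement simultaneously, for DNA and RNA
   (FASTA files or literal strings).

2. **cG/cC scoring.**  Each hit is scored over a window extending the motif by
   a configurable flank (default 15 nt per side).  The cG score is cumulative
   over every overlapping all-G window: 10 per G, 20 per GG, 30 per GGG and so
   on — a maximal run of L guanines contributes 10·L(L+1)(L+2)/6.  cC is the
   cytosine analogue, and a high cG/cC ratio marks motifs more likely to
   readily fold into a quadruplex.

3. **An interaction-record store.**  A flat-file (TSV/JSON) schema for curated
   G4–protein interactions — protein names and synonyms, UniProt ID and entry
   name, organism, gene, target name and sequence, ΔTm, Ka, Kd, PDB IDs,
   interacting residues, technique, PMID, authors — with category browsing
   (G4-DNA vs G4-RNA binders), quick search (one query over all text fields)
   and advanced search (AND-combination of ten criterion fields).

A synthetic-data module generates motif-planted sequences with exact ground
truth and schema-valid interaction records, so everything is testable offline.

## Worked example

```sh
$ g4kit scan "GGGAGGGAGGGAGGG"
# seq_id=query	n_sense=1	n_antisense=0	n_total=1
seq_id	strand	start	end	length	hit_seq	tract_lengths	loop_lengths	cG	cC	cG_cC_ratio	window_start	window_end
query	+	1	15	15	GGGAGGGAGGGAGGG	3,3,3,3	1,1,1	400	0	inf	1	15
```

One sense-strand hit covers positions 1–15: four G-tracts of length 3
separated by three 1-nt loops.  Its cG over the (here unflanked) window is
4 × 100 = 400; with no cytosines the cG/cC ratio is infinite — maximally
G-dominated, i.e. a strong folding candidate.  A C-rich input such as
`CCCTCCCTCCCTCCC` yields the mirror hit on the antisense strand (`-`), with
coordinates mapped back to the input sequence.

Library use:

```python
from g4kit import NucleotideSequence, scan_both_strands, score_hit

s = NucleotideSequence.from_string("myc", "TGGGGAGGGTGGGGAGGGTGGGGAAGG")
result = scan_both_strands(s)
for hit in result.hits:
    print(hit.start, hit.end, hit.strand, score_hit(hit, s, flank=15).ratio)
```

Record search mirrors a curated database front end:

```sh
g4kit fixtures records --n 200 --seed 7 --anchors --out records.tsv
g4kit db-search --db records.tsv --query FMRP
g4kit db-search --db records.tsv --field pmid=25679041 --field protein_name=kinase
```

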