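"""Independent brute-force oracles used to check g4kit against ground truth.

Deliberately naive: the scan oracle enumerates every tract/loop assignment at
every start position and applies leftmost non-overlapping selection with the
documented tie-break (greedy tracts, lazy loops) as an explicit lexicographic
priority over the full candidate set; the scoring oracle enumerates every
all-G (all-C) substring; the search oracles are plain per-record filters.
None of them share code with the package implementation.
"""

from __future__ import annotations

LOOP_ALPHABET = set("ACGTN")


def enumerate_assignments(s, params, start):
    """All (t1, l1, t2, l2, t3, l3, t4) assignments valid at one start."""
    out = []

    def rec(pos, parts):
        k = len(parts)
        if k == 7:
            out.append(tuple(parts))
            return
        if k % 2 == 0:  # tract
            for t in range(params.min_tract, params.max_tract + 1):
                seg = s[pos:pos + t]
                if len(seg) == t and all(c == "G" for c in seg):
                    rec(pos + t, parts + [t])
        else:  # loop
            for l in range(params.min_loop, params.max_loop + 1):
                seg = s[pos:pos + l]
                if len(seg) == l and all(c in LOOP_ALPHABET for c in seg):
                    rec(pos + l, parts + [l])

    rec(start, [])
    return out


def preference_key(assignment):
    """Greedy tracts (longer first), lazy loops (shorter first), left to right."""
    t1, l1, t2, l2, t3, l3, t4 = assignment
    return (-t1, l1, -t2, l2, -t3, l3, -t4)


def oracle_scan_single_strand(s, params):
    """Leftmost non-overlapping hits: list of (start, end, tracts, loops), 1-based."""
    hits = []
    min_len = 4 * params.min_tract + 3 * params.min_loop
    i = 0
    n = len(s)
    while i <= n - min_len:
        if s[i] != "G":
            i += 1
            continue
        cands = enumerate_assignments(s, params, i)
        if not cands:
            i += 1
            continue
        best = min(cands, key=preference_key)
        length = sum(best)
        tracts = (best[0], best[2], best[4], best[6])
        loops = (best[1], best[3], best[5])
        hits.append((i + 1, i + length, tracts, loops))
        i += length
    return hits


def oracle_cg_score(s, base="G"):
    """Sum 10*len over every substring made only of ``base``."""
    total = 0
    n = len(s)
    for i in range(n):
        for j in range(i + 1, n + 1):
            if all(c == base for c in s[i:j]):
                total += 10 * (j - i)
            else:
                break
    return total


def oracle_quick_search(records, query):
    """Naive per-record filter over every searchable text field."""
    q = query.lower()
    out = []
    for r in records:
        texts = (
            [r.interaction_id, r.protein_name, r.target_name, r.target_sequence,
             r.protein_fasta, r.uniprot_id, r.uniprot_entry_name, r.gene_name,
             r.technique, r.pmid]
            + r.protein_synonyms + r.gene_synonyms + r.authors
        )
        if any(q in t.lower() for t in texts if t):
            out.append(r)
    return sorted(out, key=lambda r: r.interaction_id)


def oracle_advanced_search(records, criteria):
    """Naive AND-of-substring filter over the criterion fields."""
    def field_values(r, name):
        if name == "gene_synonyms":
            return r.gene_synonyms
        if name == "author":
            return r.authors
        return [getattr(r, name)]

    out = []
    for r in records:
        if all(
            any(v.lower() in t.lower() for t in field_values(r, name) if t)
            for name, v in criteria.items()
        ):
            out.append(r)
    return sorted(out, key=lambda r: r.interaction_id)
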