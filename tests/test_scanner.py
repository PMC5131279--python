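import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from g4kit import (
    NucleotideSequence,
    PQSParams,
    find_pqs_single_strand,
    map_antisense_coordinates,
    max_motif_span,
    reverse_complement,
    scan_both_strands,
)

from conftest import random_dna
from helpers_oracles import oracle_scan_single_strand

DEFAULTS = PQSParams()


class TestParams:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"min_tract": 0},
            {"min_tract": 5, "max_tract": 3},
            {"min_loop": 0},
            {"min_loop": 4, "max_loop": 2},
        ],
    )
    def test_invalid_ranges_rejected(self, kwargs):
        with pytest.raises(ValueError):
            PQSParams(**kwargs)

    def test_grammar_has_four_tracts(self):
        assert DEFAULTS.n_tracts == 4

    @pytest.mark.parametrize(
        "params, span",
        [
            (DEFAULTS, 49),
            (PQSParams(min_tract=2, max_tract=2, min_loop=1, max_loop=1), 11),
            (PQSParams(min_tract=3, max_tract=5, min_loop=2, max_loop=4), 32),
        ],
    )
    def test_max_motif_span(self, params, span):
        assert max_motif_span(params) == span


class TestSingleStrand:
    @pytest.mark.parametrize(
        "seq, expected",
        [
            # (start, end, tracts, loops) frozen from the brute-force oracle
            ("GGGAGGGAGGGAGGG", [(1, 15, (3, 3, 3, 3), (1, 1, 1))]),
            ("ATATATATAT", []),
            ("GGAGGAGGAGG", [(1, 11, (2, 2, 2, 2), (1, 1, 1))]),
            ("GGGAGGGAGGGAGGG" + "TTTT" + "GGGAGGGAGGGAGGG",
             [(1, 15, (3, 3, 3, 3), (1, 1, 1)), (20, 34, (3, 3, 3, 3), (1, 1, 1))]),
        ],
    )
    def test_examples_match_frozen_oracle_values(self, seq, expected):
        hits = find_pqs_single_strand(seq, DEFAULTS)
        got = [(h.start, h.end, h.tract_lengths, h.loop_lengths) for h in hits]
        assert got == expected
        assert got == [
            (s, e, t, l) for s, e, t, l in oracle_scan_single_strand(seq, DEFAULTS)
        ]

    def test_hits_satisfy_decomposition_invariants(self):
        seq = "GGGGGGGGGGAGGATGGGCGGTTTGGGGAGGGAGGGAGGGTTT"
        for h in find_pqs_single_strand(seq, DEFAULTS):
            tracts, loops = h.decompose()
            assert all(set(t) == {"G"} for t in tracts)
            assert all(DEFAULTS.min_tract <= len(t) <= DEFAULTS.max_tract for t in tracts)
            assert all(DEFAULTS.min_loop <= len(l) <= DEFAULTS.max_loop for l in loops)
            assert h.end - h.start + 1 == h.length == len(h.hit_seq)

    def test_n_allowed_in_loops_but_not_tracts(self):
        assert len(find_pqs_single_strand("GGNGGNGGNGG", DEFAULTS)) == 1
        # N cannot stand in for a tract guanine
        assert find_pqs_single_strand("GNAGGAGGAGG", DEFAULTS) == []

    def test_oracle_equivalence_on_random_sequences(self):
        rng = np.random.default_rng(101)
        for _ in range(150):
            seq = random_dna(rng, int(rng.integers(20, 200)), gc=float(rng.uniform(0.2, 0.7)))
            got = [
                (h.start, h.end, h.tract_lengths, h.loop_lengths)
                for h in find_pqs_single_strand(seq, DEFAULTS)
            ]
            assert got == oracle_scan_single_strand(seq, DEFAULTS)

    def test_nondefault_params_against_oracle(self):
        rng = np.random.default_rng(202)
        params = PQSParams(min_tract=3, max_tract=5, min_loop=2, max_loop=5)
        for _ in range(60):
            seq = random_dna(rng, 150, gc=0.6)
            got = [
                (h.start, h.end, h.tract_lengths, h.loop_lengths)
                for h in find_pqs_single_strand(seq, params)
            ]
            assert got == oracle_scan_single_strand(seq, params)

    def test_nonoverlap_and_sorted_per_strand(self):
        rng = np.random.default_rng(33)
        seq = random_dna(rng, 500, gc=0.65)
        hits = find_pqs_single_strand(seq, DEFAULTS)
        for a, b in zip(hits, hits[1:]):
            assert a.end < b.start

    def test_five_tract_region_yields_single_leftmost_hit(self):
        # five tracts: one hit using the leftmost four
        seq = "GGGAGGGAGGGAGGGAGGG"
        hits = find_pqs_single_strand(seq, DEFAULTS)
        assert [(h.start, h.end) for h in hits] == [(1, 15)]

    def test_long_g_run_handled_by_backtracking(self):
        # G9 run: tract takes at most 7 Gs, surplus feeds the loop
        seq = "GGGGGGGGGAGGAGGAGG"
        (hit,) = find_pqs_single_strand(seq, DEFAULTS)
        assert hit.start == 1 and hit.end == len(seq)
        assert [(hit.start, hit.end, hit.tract_lengths, hit.loop_lengths)] == [
            (s, e, t, l) for s, e, t, l in oracle_scan_single_strand(seq, DEFAULTS)
        ]


class TestCoordinateMapping:
    @pytest.mark.parametrize(
        "args, expected", [((1, 15, 15), (1, 15)), ((1, 11, 20), (10, 20))]
    )
    def test_mirror_arithmetic(self, args, expected):
        assert map_antisense_coordinates(*args) == expected

    @settings(derandomize=True, max_examples=60)
    @given(st.data())
    def test_mapping_is_an_involution(self, data):
        L = data.draw(st.integers(1, 1000))
        start = data.draw(st.integers(1, L))
        end = data.draw(st.integers(start, L))
        s2, e2 = map_antisense_coordinates(start, end, L)
        assert map_antisense_coordinates(s2, e2, L) == (start, end)

    def test_bounds_violation_raises(self):
        with pytest.raises(ValueError):
            map_antisense_coordinates(0, 5, 10)
        with pytest.raises(ValueError):
            map_antisense_coordinates(2, 11, 10)


class TestBothStrands:
    def test_c_rich_motif_found_on_antisense(self):
        s = NucleotideSequence.from_string("s", "CCCTCCCTCCCTCCC")
        res = scan_both_strands(s)
        assert (res.n_sense, res.n_antisense, res.n_total) == (0, 1, 1)
        (hit,) = res.hits
        assert (hit.start, hit.end, hit.strand) == (1, 15, "antisense")
        assert hit.hit_seq == "GGGAGGGAGGGAGGG"  # as read on the hit strand

    def test_antisense_flag_respected(self):
        s = NucleotideSequence.from_string("s", "GGGAGGGAGGGAGGGCCCTCCCTCCCTCCC")
        res = scan_both_strands(s, PQSParams(scan_antisense=False))
        assert res.n_antisense == 0 and res.n_sense == 1

    def test_counts_consistent_and_sorted(self):
        rng = np.random.default_rng(77)
        s = NucleotideSequence.from_string("s", random_dna(rng, 800, gc=0.6))
        res = scan_both_strands(s)
        assert res.n_total == res.n_sense + res.n_antisense == len(res.hits)
        strands = [h.strand for h in res.hits]
        assert strands == sorted(strands, key=lambda x: x != "sense")
        for strand in ("sense", "antisense"):
            sub = [h for h in res.hits if h.strand == strand]
            assert all(a.end < b.start for a, b in zip(sub, sub[1:]))
            assert sum(h.strand == strand for h in res.hits) == (
                res.n_sense if strand == "sense" else res.n_antisense
            )

    def test_strand_symmetry_under_reverse_complement(self):
        rng = np.random.default_rng(88)
        for _ in range(40):
            s = NucleotideSequence.from_string("s", random_dna(rng, 300, gc=0.6))
            fwd = scan_both_strands(s)
            rev = scan_both_strands(reverse_complement(s))
            L = len(s)
            mirrored = {
                (L - h.end + 1, L - h.start + 1,
                 "sense" if h.strand == "antisense" else "antisense",
                 h.tract_lengths, h.loop_lengths)
                for h in rev.hits
            }
            original = {
                (h.start, h.end, h.strand, h.tract_lengths, h.loop_lengths)
                for h in fwd.hits
            }
            assert mirrored == original

    def test_rna_hits_report_u(self):
        s = NucleotideSequence.from_string("r", "GGGUAGGGUAGGGUAGGG")
        res = scan_both_strands(s)
        assert res.hits[0].hit_seq == "GGGUAGGGUAGGGUAGGG"

    def test_hit_lengths_capped_by_max_span(self):
        rng = np.random.default_rng(99)
        for _ in range(200):
            s = NucleotideSequence.from_string("s", random_dna(rng, 200, gc=0.7))
            for h in scan_both_strands(s).hits:
                assert h.length <= max_motif_span(DEFAULTS)
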