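"""Evidence parsers and the built-in maximal exact match finder."""

import io

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from junctionscan.homology import (ExactMatch, ParseError,
                                   features_from_tsv, features_to_gff3,
                                   features_to_tsv, filter_score_equivalence,
                                   find_maximal_exact_matches,
                                   parse_blast_tabular, parse_crossmatch,
                                   parse_mummer_coords)
from oracles import brute_maximal_pairs, matches_to_keyset, revcomp

BLAST_ROWS = "\n".join([
    # qid sid pident len mm go qs qe ss se evalue bits
    "q1\tCRM2_LTR\t98.00\t500\t10\t0\t101\t600\t1\t500\t1e-50\t900",
    "q1\tCentC_sat\t95.00\t150\t7\t0\t700\t849\t156\t7\t1e-5\t250",   # minus strand
    "q1\tgene1\t90.00\t200\t20\t0\t900\t1099\t1\t200\t0.5\t120",      # weak
    "q2\tCRM1_LTR\t99.00\t300\t3\t0\t1\t300\t1\t300\t1e-80\t550",
]) + "\n"


class TestBlastParser:
    def test_evalue_filter_and_normalization(self):
        feats = parse_blast_tabular(io.StringIO(BLAST_ROWS), "crm", 1e-10)
        assert [f.subject_id for f in feats] == ["CRM2_LTR", "CRM1_LTR"]
        f = feats[0]
        assert (f.q_start, f.q_end) == (100, 600)  # 0-based half-open
        assert f.strand == "+" and f.db_name == "crm" and f.score == 900

    def test_reversed_subject_coords_mean_minus_strand(self):
        feats = parse_blast_tabular(io.StringIO(BLAST_ROWS), "crm", 1.0)
        minus = next(f for f in feats if f.subject_id == "CentC_sat")
        assert minus.strand == "-"
        assert (minus.s_start, minus.s_end) == (7, 156)  # stored ascending

    def test_query_id_restriction(self):
        feats = parse_blast_tabular(io.StringIO(BLAST_ROWS), "crm", 1.0,
                                    query_id="q2")
        assert len(feats) == 1 and feats[0].query_id == "q2"

    def test_malformed_row_reports_line_number(self):
        with pytest.raises(ParseError, match="line 2"):
            parse_blast_tabular(
                io.StringIO("q\ts\t90\t10\t0\t0\t1\t10\t1\t10\t0.0\t20\nbroken row\n"),
                "db", 1.0,
            )

    def test_score_equivalence_filter(self):
        feats = parse_blast_tabular(io.StringIO(BLAST_ROWS), "crm", 1.0)
        # perfect complete match to CRM2_LTR (len 1000) scores 1000
        kept = filter_score_equivalence(
            feats, {"CRM2_LTR": 1000, "CentC_sat": 156, "gene1": 200,
                    "CRM1_LTR": 300}, fraction=0.9)
        # 900 >= 0.9*1000; 250 >= 0.9*156; 120 < 0.9*200; 550 >= 0.9*300
        assert {f.subject_id for f in kept} == {"CRM2_LTR", "CentC_sat", "CRM1_LTR"}
        strict = filter_score_equivalence(
            feats, {"CRM2_LTR": 1001, "CentC_sat": 500, "gene1": 200,
                    "CRM1_LTR": 300}, fraction=0.9)
        # raising the subject lengths drops CRM2 (900 < 900.9) and CentC
        assert {f.subject_id for f in strict} == {"CRM1_LTR"}


CROSSMATCH = """\
  2334  7.16 0.85 1.03  q1 101 800 (200)  CentC_sat 1 696 (4)
   877 12.00 0.00 0.00  q1 900 1100 (0)  C CRM2_LTR (4) 696 496
"""


class TestCrossmatchParser:
    def test_forward_and_complement_lines(self):
        feats = parse_crossmatch(io.StringIO(CROSSMATCH), "masklib")
        assert len(feats) == 2
        fwd, rev = feats
        assert fwd.strand == "+" and (fwd.q_start, fwd.q_end) == (100, 800)
        assert fwd.evidence == "crossmatch" and fwd.score == 2334
        assert rev.strand == "-" and rev.subject_id == "CRM2_LTR"
        assert (rev.s_start, rev.s_end) == (496, 696)

    def test_empty_stream(self):
        assert parse_crossmatch(io.StringIO("")) == []

    def test_garbled_alignment_line_raises(self):
        with pytest.raises(ParseError, match="line 1"):
            parse_crossmatch(io.StringIO("999 1.0 q1 oops\n"))


MUMMER = """\
NUCMER
    [S1]     [E1]  |     [S2]     [E2]  |  [LEN 1]  [LEN 2]  |  [% IDY]  | [TAGS]
       1     5000  |        1     5000  |     5000     5000  |   100.00  | q q
     201      350  |     1201     1350  |      150      150  |   100.00  | q q
    1201     1350  |      201      350  |      150      150  |   100.00  | q q
     400      499  |     2400     2499  |      100      100  |   100.00  | q q
     600      698  |     2600     2698  |       99       99  |   100.00  | q q
     800      920  |     3920     3800  |      121      121  |   100.00  | q q
"""


class TestMummerParser:
    def test_self_hit_mirrors_and_min_len(self):
        matches = parse_mummer_coords(io.StringIO(MUMMER), min_len=100)
        keys = {m.key() for m in matches}
        assert (200, 1200, 150, "direct") in keys  # canonical, deduplicated
        assert (399, 2399, 100, "direct") in keys
        assert (799, 3799, 121, "inverted") in keys  # E2 < S2
        assert len(matches) == 3  # 99 nt dropped; full self-hit dropped

    def test_sorted_longest_first(self):
        matches = parse_mummer_coords(io.StringIO(MUMMER), min_len=100)
        lengths = [m.length for m in matches]
        assert lengths == sorted(lengths, reverse=True)


class TestExactMatchFinder:
    def test_adjacent_direct_repeat(self):
        matches = find_maximal_exact_matches("ACGTACGT", 4,
                                             include_inverted=False)
        assert matches_to_keyset(matches) == {(0, 4, 4, "direct")}

    def test_inverted_repeat_found(self):
        core = "AGGCTAGCATCGATCGAAT"
        seq = core + "TTTTTTTTTT" + revcomp(core)
        matches = find_maximal_exact_matches(seq, len(core))
        inv = [m for m in matches if m.orientation == "inverted"]
        assert (0, len(core) + 10, len(core), "inverted") in {
            m.key() for m in inv
        }

    def test_random_sequence_has_no_long_matches(self):
        rng = np.random.default_rng(99)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 1000))
        assert find_maximal_exact_matches(seq, 100) == []

    def test_matches_never_span_ns(self):
        block = "ACGTTGCACCGGTTAAGGCC"
        seq = block + "N" * 5 + block
        for m in find_maximal_exact_matches(seq, 8):
            assert "N" not in seq[m.a_start : m.a_end]
            assert "N" not in seq[m.b_start : m.b_end]

    def test_non_nucleotide_input_rejected(self):
        with pytest.raises(ValueError, match="non-ACGTN"):
            find_maximal_exact_matches("ACGTXACGT", 4)

    def test_maximality_cannot_extend(self):
        rng = np.random.default_rng(5)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 400))
        seq = seq[:150] + seq[20:80] + seq[150:]  # planted 60 nt repeat
        for m in find_maximal_exact_matches(seq, 10):
            if m.orientation != "direct":
                continue
            a, b, L = m.a_start, m.b_start, m.length
            if a > 0 and b > 0:
                assert not (seq[a - 1] == seq[b - 1] and seq[a - 1] != "N")
            if a + L < len(seq) and b + L < len(seq):
                assert not (seq[a + L] == seq[b + L] and seq[a + L] != "N")

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 10_000), min_len=st.sampled_from([4, 8, 15]))
    def test_agrees_with_bruteforce_on_random_sequences(self, seed, min_len):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(40, 500))
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, n))
        if seed % 2 and n > 100:  # plant a repeat half the time
            seq = seq[: n // 2] + seq[5:45] + seq[n // 2 + 40 :]
        got = matches_to_keyset(find_maximal_exact_matches(seq, min_len))
        assert got == brute_maximal_pairs(seq, min_len)


class TestSerialization:
    def test_tsv_round_trip_identity(self):
        feats = parse_blast_tabular(io.StringIO(BLAST_ROWS), "crm", 1.0)
        back = features_from_tsv(io.StringIO(features_to_tsv(feats)))
        assert back == feats

    def test_gff3_export_is_one_based(self):
        feats = parse_blast_tabular(io.StringIO(BLAST_ROWS), "crm", 1e-10)
        gff = features_to_gff3(feats)
        lines = gff.splitlines()
        assert lines[0] == "##gff-version 3"
        assert "\t101\t600\t" in lines[1]
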