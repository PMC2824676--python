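"""Junction detection, marker pairing, LTR identification and K2P dating."""

import math

import numpy as np
import pytest

from junctionscan.competition import (ClassifiedSegment, CompetitionParams,
                                      RepeatClass, compete)
from junctionscan.homology import ExactMatch, HomologyFeature
from junctionscan.junctions import (UndefinedDistanceError, age_order,
                                    date_ltr_pair, detect_junctions,
                                    find_marker_candidates,
                                    identify_ltr_pairs, kimura2p)


def seg(q_start, q_end, family, part="", db=None, subject=None):
    f = HomologyFeature(
        query_id="q", q_start=q_start, q_end=q_end, strand="+",
        db_name=db or family, subject_id=subject or f"{family}_{part or 'x'}",
        s_start=1, s_end=q_end - q_start, score=float(q_end - q_start),
        evidence="blast",
    )
    return ClassifiedSegment(feature=f, repeat_class=RepeatClass(family, part))


class TestDetectJunctions:
    def test_abutting_different_families_share_boundary(self):
        segs = [seg(0, 1000, "CentC", "sat"), seg(1000, 2500, "CRM1", "LTR")]
        juncs = detect_junctions(segs, gap_tolerance=0)
        assert len(juncs) == 1
        j = juncs[0]
        assert j.position == 1000 and j.gap_nt == 0
        assert (j.left_class.family, j.right_class.family) == ("CentC", "CRM1")

    def test_single_feature_yields_nothing(self):
        assert detect_junctions([seg(0, 1000, "CentC", "sat")]) == []

    def test_same_family_adjacency_is_not_a_junction(self):
        segs = [seg(0, 1000, "CRM1", "LTR"), seg(1000, 6000, "CRM1", "CDS")]
        assert detect_junctions(segs, gap_tolerance=0) == []

    def test_small_gap_places_junction_at_midpoint(self):
        segs = [seg(0, 1000, "CentC", "sat"), seg(1040, 2000, "CRM2", "LTR")]
        juncs = detect_junctions(segs, gap_tolerance=50)
        assert len(juncs) == 1
        assert juncs[0].position == 1020 and juncs[0].gap_nt == 40

    def test_gap_beyond_tolerance_suppresses_junction(self):
        segs = [seg(0, 1000, "CentC", "sat"), seg(1100, 2000, "CRM2", "LTR")]
        assert detect_junctions(segs, gap_tolerance=50) == []

    def test_tandem_stack_merges_into_one_flank(self):
        # overlapping same-family satellite hits followed by an element
        segs = [seg(0, 600, "CentC", "sat"), seg(400, 1000, "CentC", "sat"),
                seg(1000, 2400, "CRM3", "LTR")]
        juncs = detect_junctions(segs, gap_tolerance=0)
        assert len(juncs) == 1 and juncs[0].position == 1000

    def test_element_sandwich_yields_two_junctions(self):
        segs = [seg(0, 1000, "CentC", "sat"),
                seg(1000, 2400, "CRM1", "LTR"),
                seg(2400, 7000, "CRM1", "CDS"),
                seg(7000, 8400, "CRM1", "LTR"),
                seg(8400, 9000, "CentC", "sat")]
        juncs = detect_junctions(segs, gap_tolerance=0)
        assert [j.position for j in juncs] == [1000, 8400]


class TestMarkerCandidates:
    def _junctions(self, positions):
        out = []
        for p in positions:
            out.extend(detect_junctions(
                [seg(p - 500, p, "CentC", "sat"), seg(p, p + 500, "CRM1", "LTR")],
                gap_tolerance=0))
        return out

    def test_pair_within_span_limit(self):
        juncs = self._junctions([1000, 3200])
        cands = find_marker_candidates(juncs, max_span=2500)
        assert len(cands) == 1 and cands[0].span_nt == 2200

    def test_pair_beyond_limit_rejected(self):
        juncs = self._junctions([1000, 3700])  # span 2700 > 2500
        assert find_marker_candidates(juncs, max_span=2500) == []

    def test_three_mutually_close_junctions_make_three_pairs(self):
        juncs = self._junctions([1000, 2000, 3000])
        cands = find_marker_candidates(juncs, max_span=2500)
        assert len(cands) == 3
        assert [c.span_nt for c in cands] == [1000, 1000, 2000]  # span asc

    def test_equals_bruteforce_pair_enumeration(self):
        rng = np.random.default_rng(8)
        positions = sorted(int(p) for p in
                           rng.choice(np.arange(1000, 40000, 700), 18,
                                      replace=False))
        juncs = self._junctions(positions)
        cands = find_marker_candidates(juncs, max_span=2500)
        expected = {(a.position, b.position)
                    for i, a in enumerate(juncs) for b in juncs[i + 1:]
                    if 0 < abs(b.position - a.position) <= 2500}
        got = {(c.junction_a.position, c.junction_b.position) for c in cands}
        assert got == expected


class TestKimura2P:
    def test_identical_sequences(self):
        assert kimura2p("ACGTACGT", "ACGTACGT") == (0.0, 0.0, 0.0)

    def test_ten_percent_transitions_closed_form(self):
        # 100 columns, 10 transitions (A<->G), 0 transversions
        a = "A" * 100
        b = "G" * 10 + "A" * 90
        kappa, P, Q = kimura2p(a, b)
        assert (P, Q) == (0.10, 0.0)
        assert kappa == pytest.approx(-0.5 * math.log(0.8))  # ~0.11157

    def test_gap_columns_excluded_from_denominator(self):
        a, b = "A" * 100, "G" * 10 + "A" * 90
        kappa0 = kimura2p(a, b)[0]
        kappa1 = kimura2p(a + "----CC", b + "----NN")[0]
        assert kappa1 == pytest.approx(kappa0)

    def test_symmetric_in_arguments(self):
        a = "ACGTACGTAAGGCCTTACGT"
        b = "ACGTACGTAAGGCCTTACGA"
        assert kimura2p(a, b) == kimura2p(b, a)

    def test_exceeds_raw_mismatch_proportion(self):
        # multiple-hit correction inflates the distance (checked for p <= 0.3)
        rng = np.random.default_rng(17)
        bases = "ACGT"
        for _ in range(20):
            n = 400
            a = "".join(bases[i] for i in rng.integers(0, 4, n))
            b = list(a)
            k = int(rng.integers(1, int(0.3 * n)))
            for i in rng.choice(n, k, replace=False):
                b[i] = bases[(bases.index(b[i]) + int(rng.integers(1, 4))) % 4]
            b = "".join(b)
            kappa, P, Q = kimura2p(a, b)
            assert kappa >= P + Q - 1e-12

    def test_saturated_divergence_is_undefined(self):
        with pytest.raises(UndefinedDistanceError):
            kimura2p("A" * 60, "G" * 30 + "C" * 30)  # P=0.5, Q=0.5

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            kimura2p("ACGT", "ACG")


class TestLtrPairs:
    def test_clean_pair_from_single_long_match(self):
        # identical 1.5 kb LTRs flanking a 5 kb internal region
        m = ExactMatch(0, 1500, 6500, 8000, "direct")
        pairs = identify_ltr_pairs([m], min_ltr_len=300,
                                   min_internal=1000, max_internal=25000)
        assert len(pairs) == 1
        p = pairs[0]
        assert p.left_ltr == (0, 1500) and p.right_ltr == (6500, 8000)
        assert p.internal_length == 5000

    def test_short_periodic_satellite_matches_rejected(self):
        ms = [ExactMatch(i * 156, i * 156 + 150, (i + 1) * 156,
                         (i + 1) * 156 + 150, "direct") for i in range(5)]
        assert identify_ltr_pairs(ms, min_ltr_len=300) == []

    def test_inverted_matches_never_qualify(self):
        m = ExactMatch(0, 1500, 6500, 8000, "inverted")
        assert identify_ltr_pairs([m]) == []

    def test_fragmented_pair_chained_by_offset(self):
        # a diverged LTR pair seen as three exact fragments, same offset
        frags = [ExactMatch(0, 200, 7000, 7200, "direct"),
                 ExactMatch(260, 500, 7260, 7500, "direct"),
                 ExactMatch(600, 1400, 7600, 8400, "direct")]
        pairs = identify_ltr_pairs(frags, min_ltr_len=300, min_internal=1000)
        assert len(pairs) == 1
        assert pairs[0].left_ltr == (0, 1400)
        assert pairs[0].matched_nt == 200 + 240 + 800

    def test_internal_span_bounds_enforced(self):
        near = ExactMatch(0, 500, 800, 1300, "direct")  # internal 300 < 1000
        far = ExactMatch(0, 500, 30_000, 30_500, "direct")  # 29500 > 25000
        assert identify_ltr_pairs([near, far]) == []

    def test_cds_overlap_requirement(self):
        m = ExactMatch(0, 1500, 6500, 8000, "direct")
        cds = [seg(2000, 6000, "CRM1", "CDS")]
        with_cds = identify_ltr_pairs([m], cds, require_cds_overlap=True)
        without = identify_ltr_pairs([m], [seg(9000, 9500, "CRM1", "CDS")],
                                     require_cds_overlap=True)
        assert len(with_cds) == 1 and without == []


class TestAgeOrder:
    def _pair(self, kappa, longest):
        p = identify_ltr_pairs(
            [ExactMatch(0, longest, 6500, 6500 + longest, "direct")],
            min_ltr_len=100, min_internal=1000)[0]
        p.kappa = kappa
        return p

    def test_sorted_ascending_by_kappa(self):
        kappas = [0.0346, 0.0320, 0.0175, 0.0017]
        pairs = [self._pair(k, 1000) for k in kappas]
        ordered = age_order(pairs)
        assert [p.kappa for p in ordered] == sorted(kappas)

    def test_tie_broken_by_longer_match_first(self):
        a, b = self._pair(0.01, 500), self._pair(0.01, 1500)
        assert age_order([a, b]) == [b, a]

    def test_undated_pair_rejected(self):
        p = self._pair(None, 500)
        with pytest.raises(ValueError, match="dated"):
            age_order([p])

    def test_single_pair(self):
        p = self._pair(0.02, 500)
        assert age_order([p]) == [p]
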