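"""Display model assembly, level layout, and SVG/PostScript structure."""

import xml.etree.ElementTree as ET

import numpy as np
import pytest

from junctionscan.charts import ChartSets, ReadPlacement, assemble_chart_sets, build_coverage
from junctionscan.competition import (ClassifiedSegment, CompetitionParams,
                                      RepeatClass, compete)
from junctionscan.homology import ExactMatch, HomologyFeature
from junctionscan.render import (RenderParams, build_display,
                                 layout_match_levels, to_postscript, to_svg)
from junctionscan.seqio import QuerySequence, detect_gaps
from oracles import brute_level_layout

SVG_NS = "{http://www.w3.org/2000/svg}"


def seg(q_start, q_end, family="CentC", part="sat", evidence="blast", qid="q"):
    f = HomologyFeature(
        query_id=qid, q_start=q_start, q_end=q_end, strand="+",
        db_name=family, subject_id=f"{family}_{part}", s_start=1,
        s_end=q_end - q_start, score=float(q_end - q_start), evidence=evidence,
    )
    return ClassifiedSegment(feature=f, repeat_class=RepeatClass(family, part))


def svg_elems(svg_text, cls):
    root = ET.fromstring(svg_text)
    return [e for e in root.iter()
            if cls in (e.get("class") or "").split()]


class TestLevelLayout:
    def test_single_match_takes_top_level(self):
        placed, dropped = layout_match_levels(
            [ExactMatch(0, 100, 500, 600, "direct")], 30)
        assert placed[0].level == 0 and not dropped

    def test_non_overlapping_matches_share_top_level(self):
        ms = [ExactMatch(0, 100, 200, 300, "direct"),
              ExactMatch(1000, 1100, 1300, 1400, "direct")]
        placed, _ = layout_match_levels(ms, 30)
        assert [m.level for m in placed] == [0, 0]

    def test_pigeonhole_drops_beyond_max_levels(self):
        # 31 mutually overlapping matches, 30 levels -> 30 placed, 1 dropped
        ms = [ExactMatch(i, 200 + i, 300 + i, 500 + i, "direct")
              for i in range(31)]
        placed, dropped = layout_match_levels(ms, 30)
        assert len(placed) == 30 and len(dropped) == 1

    def test_longest_first_and_no_intra_level_overlap(self):
        rng = np.random.default_rng(6)
        ms = []
        for _ in range(40):
            a = int(rng.integers(0, 3000))
            L = int(rng.integers(20, 400))
            gap = int(rng.integers(0, 2000))
            ms.append(ExactMatch(a, a + L, a + L + gap, a + 2 * L + gap,
                                 "direct" if rng.random() < 0.5 else "inverted"))
        placed, _ = layout_match_levels(ms, 30)
        longest = max(ms, key=lambda m: m.length)
        assert next(m for m in placed if m.key() == longest.key()).level == 0
        by_level = {}
        for m in placed:
            for s, e in by_level.get(m.level, []):
                assert m.span[1] <= s or m.span[0] >= e
            by_level.setdefault(m.level, []).append(m.span)

    def test_agrees_with_bruteforce_placement(self):
        rng = np.random.default_rng(9)
        for _ in range(25):
            ms = []
            for _ in range(int(rng.integers(1, 20))):
                a = int(rng.integers(0, 1000))
                L = int(rng.integers(10, 150))
                gap = int(rng.integers(0, 500))
                ms.append(ExactMatch(a, a + L, a + L + gap, a + 2 * L + gap,
                                     "direct"))
            max_levels = int(rng.integers(1, 6))
            placed, dropped = layout_match_levels(ms, max_levels)
            exp_levels, exp_dropped = brute_level_layout(ms, max_levels)
            assert {m.key(): m.level for m in placed} == exp_levels
            assert {m.key() for m in dropped} == {m.key() for m in exp_dropped}


class TestBuildDisplay:
    def test_tick_every_kilobase(self):
        q = QuerySequence("q", "ACGT" * 52_500)  # 210,000 nt
        model = build_display(q, [])
        assert len(model.ticks) == 210
        assert model.ticks[0].pos_1based == 1000

    def test_thousand_n_gap_draws_ten_bars(self):
        residues = "ACGT" * 500 + "N" * 1000 + "ACGT" * 500
        q = QuerySequence("q", residues)
        model = build_display(q, detect_gaps(residues))
        assert len(model.gap_bars) == 10

    def test_gap_relative_labels_follow_last_gap(self):
        residues = "A" * 2000 + "N" * 1000 + "C" * 2000
        q = QuerySequence("q", residues)
        model = build_display(q, detect_gaps(residues))
        labels = {t.pos_1based: t.gap_relative for t in model.ticks}
        assert labels[2000] == 2000  # before the gap
        assert labels[4000] == 1000  # 1,000 nt past the gap end at 3,000
        assert labels[3000] == 0  # inside the gap

    def test_empty_evidence_gives_ruler_only_model(self):
        q = QuerySequence("q", "ACGT" * 1000)
        model = build_display(q, [])
        assert model.mask_segments == [] and model.placed_matches == []
        assert len(model.ticks) == 4

    def test_cross_query_mixing_rejected(self):
        q = QuerySequence("q", "ACGT" * 1000)
        with pytest.raises(ValueError, match="mixed"):
            build_display(q, [], hsp_track=[seg(0, 100, qid="other")])


class TestSvg:
    def _model(self):
        residues = "ACGT" * 1000 + "N" * 250 + "ACGT" * 1000
        q = QuerySequence("q", residues)
        hsps = [seg(0, 1200, "CentC", "sat"), seg(1200, 2600, "CRM1", "LTR")]
        masks = [seg(100, 900, "CentC", "sat", evidence="crossmatch"),
                 seg(1000, 3000, "CRM1", "LTR", evidence="crossmatch")]
        matches = [ExactMatch(0, 150, 400, 550, "direct"),
                   ExactMatch(10, 120, 600, 710, "inverted")]
        placements = [ReadPlacement(f"r{i}", "q", 40 * i, 40 * i + 200, 1, 1)
                      for i in range(10)]
        charts = assemble_chart_sets([
            build_coverage(placements, len(q), "unique", "u", "foreground", "red"),
            build_coverage(placements, len(q), "all", "a", "background", "grey"),
        ])
        return build_display(q, detect_gaps(residues), charts, masks, hsps,
                             matches)

    def test_element_counts_match_model(self):
        model = self._model()
        svg = to_svg(model)
        assert len(svg_elems(svg, "mask")) == len(model.mask_segments)
        assert len(svg_elems(svg, "hsp")) == len(model.hsp_segments)
        assert len(svg_elems(svg, "match")) == len(model.placed_matches)
        assert len(svg_elems(svg, "gap-bar")) == len(model.gap_bars) == 2
        assert len(svg_elems(svg, "tick")) == len(model.ticks)
        assert len(svg_elems(svg, "chart")) == 2

    def test_direct_red_inverted_blue(self):
        svg = to_svg(self._model())
        for g in svg_elems(svg, "match"):
            arms = [e for e in g
                    if "match-arm" in (e.get("class") or "").split()]
            color = {a.get("stroke") for a in arms}
            if "match-direct" in g.get("class"):
                assert color == {"red"}
            else:
                assert color == {"blue"}

    def test_arms_solid_connector_dashed(self):
        svg = to_svg(self._model())
        g = svg_elems(svg, "match")[0]
        conn = [e for e in g
                if "match-connector" in (e.get("class") or "").split()]
        assert conn and conn[0].get("stroke-dasharray")

    def test_hsp_labels_carry_query_and_subject_coordinates(self):
        svg = to_svg(self._model())
        hsp = svg_elems(svg, "hsp")[0]
        assert hsp.get("data-q") and hsp.get("data-s")

    def test_byte_identical_re_render(self):
        model = self._model()
        assert to_svg(model) == to_svg(model)
        assert to_postscript(model) == to_postscript(model)

    def test_postscript_header_and_primitives(self):
        ps = to_postscript(self._model())
        assert ps.startswith("%!PS-Adobe-3.0")
        assert "setrgbcolor" in ps and ps.rstrip().endswith("%%EOF")
        assert "setdash" in ps  # dashed connectors present
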