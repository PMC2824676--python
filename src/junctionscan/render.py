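"""Composite per-query display: ruler, charts, masks, HSP arrows,
leveled exact-match lines — serialized to SVG and PostScript.

The display model is renderer-independent and fully determines the
figure; both serializers are deterministic (no timestamps), so the same
model always renders to byte-identical output. The SVG carries
machine-readable ``class`` and ``data-*`` attributes so structure can be
asserted by parsing the document.

Panel order, top to bottom: ruler (1 kb ticks, gap bars, gap-relative
labels), charts (background set under foreground, independent y-axes),
cross_match mask boxes, BLAST HSP arrows, exact-match lines (direct red,
inverted blue; solid arms joined by a dashed connector) on up to
``max_levels`` levels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .charts import ChartSets, CoverageChart
from .competition import ClassifiedSegment, CompetedTrack
from .homology import ExactMatch, HomologyFeature
from .seqio import GapInterval, QuerySequence, gap_relative_coordinate

DEFAULT_MAX_LEVELS = 30
TICK_INTERVAL = 1000  # nt between ruler ticks

_DEFAULT_PALETTE = (
    "green", "maroon", "blue", "tan", "orange", "purple", "pink",
    "red", "grey", "yellow", "teal", "olive", "navy", "brown",
)


@dataclass(frozen=True)
class RenderParams:
    nt_per_pixel: float = 50.0
    max_levels: int = DEFAULT_MAX_LEVELS
    feature_colors: Dict[str, str] = field(default_factory=dict)  # subject/db -> color
    page_width_margin: float = 20.0

    def __post_init__(self) -> None:
        if self.max_levels < 1:
            raise ValueError("max_levels must be >= 1")
        if self.nt_per_pixel <= 0:
            raise ValueError("nt_per_pixel must be positive")


@dataclass(frozen=True)
class Tick:
    pos_1based: int
    gap_relative: int


@dataclass(frozen=True)
class GapBar:
    """One grey vertical bar; a gap run draws floor(run/100) of them
    (minimum one), evenly spread across the gap interval."""

    gap_index: int
    x_nt: float  # position along the query, in nucleotides


@dataclass
class DisplayModel:
    query_id: str
    length: int
    nt_per_pixel: float
    ticks: List[Tick]
    gaps: List[GapInterval]
    gap_bars: List[GapBar]
    chart_sets: ChartSets
    mask_segments: List[ClassifiedSegment]  # competed cross_match boxes
    hsp_segments: List[ClassifiedSegment]  # competed BLAST arrows
    placed_matches: List[ExactMatch]  # level assigned
    dropped_matches: List[ExactMatch]
    max_levels: int

    def validate(self) -> None:
        for t in self.ticks:
            if not (1 <= t.pos_1based <= self.length) or t.pos_1based % TICK_INTERVAL:
                raise AssertionError(f"bad tick at {t.pos_1based}")
        for seg in self.mask_segments + self.hsp_segments:
            if seg.q_start < 0 or seg.q_end > self.length:
                raise AssertionError("segment outside query bounds")
        for m in self.placed_matches:
            if m.level is None or not (0 <= m.level < self.max_levels):
                raise AssertionError("placed match without a valid level")


def layout_match_levels(
    matches: Sequence[ExactMatch], max_levels: int = DEFAULT_MAX_LEVELS
) -> Tuple[List[ExactMatch], List[ExactMatch]]:
    """Assign drawing levels: longest matches first on the top level
    (level 0); a match takes the highest level where its full horizontal
    extent (both arms plus the connector) collides with nothing already
    placed; matches that fit no level are dropped.

    Returns (placed, dropped).
    """
    if max_levels < 1:
        raise ValueError("max_levels must be >= 1")
    order = sorted(matches, key=lambda m: (-m.length, m.a_start, m.b_start))
    levels: List[List[Tuple[int, int]]] = [[] for _ in range(max_levels)]
    placed: List[ExactMatch] = []
    dropped: List[ExactMatch] = []
    for m in order:
        s, e = m.span
        target = None
        for lvl in range(max_levels):
            if all(e <= ps or s >= pe for ps, pe in levels[lvl]):
                target = lvl
                break
        if target is None:
            dropped.append(m)
        else:
            levels[target].append((s, e))
            placed.append(
                ExactMatch(m.a_start, m.a_end, m.b_start, m.b_end,
                           m.orientation, level=target)
            )
    return placed, dropped


def build_display(
    query: QuerySequence,
    gaps: Sequence[GapInterval],
    chart_sets: Optional[ChartSets] = None,
    mask_track: Optional[Sequence[ClassifiedSegment]] = None,
    hsp_track: Optional[Sequence[ClassifiedSegment]] = None,
    matches: Optional[Sequence[ExactMatch]] = None,
    params: Optional[RenderParams] = None,
) -> DisplayModel:
    """Assemble the renderer-independent display model for one query."""
    params = params or RenderParams()
    gaps = list(gaps)
    ticks = [
        Tick(pos, gap_relative_coordinate(pos, gaps, length=len(query)))
        for pos in range(TICK_INTERVAL, len(query) + 1, TICK_INTERVAL)
    ]
    gap_bars = []
    for gi, g in enumerate(gaps):
        k = g.n_bars
        step = g.run_length / k
        for b in range(k):
            gap_bars.append(GapBar(gap_index=gi, x_nt=g.start + (b + 0.5) * step))

    for seg in list(mask_track or []) + list(hsp_track or []):
        if seg.feature.query_id != query.id:
            raise ValueError(
                f"feature for query {seg.feature.query_id!r} mixed into "
                f"display of {query.id!r}"
            )
    placed, dropped = layout_match_levels(matches or [], params.max_levels)
    model = DisplayModel(
        query_id=query.id,
        length=len(query),
        nt_per_pixel=params.nt_per_pixel,
        ticks=ticks,
        gaps=gaps,
        gap_bars=gap_bars,
        chart_sets=chart_sets or ChartSets([], []),
        mask_segments=sorted(mask_track or [], key=lambda s: (s.q_start, s.q_end)),
        hsp_segments=sorted(hsp_track or [], key=lambda s: (s.q_start, s.q_end)),
        placed_matches=placed,
        dropped_matches=dropped,
        max_levels=params.max_levels,
    )
    model.validate()
    return model


# ---------------------------------------------------------------------------
# Geometry shared by both serializers

_RULER_H = 46.0
_CHART_H = 90.0
_MASK_H = 46.0
_HSP_H = 60.0
_LEVEL_H = 4.0
_MARGIN = 12.0


def _fmt(x: float) -> str:
    return f"{x:.2f}".rstrip("0").rstrip(".")


def _feature_color(seg: ClassifiedSegment, colors: Dict[str, str], default_cycle: Dict[str, str]) -> str:
    f = seg.feature
    for key in (f.subject_id, f.db_name):
        if key in colors:
            return colors[key]
    fam = seg.repeat_class.family
    if fam not in default_cycle:
        default_cycle[fam] = _DEFAULT_PALETTE[len(default_cycle) % len(_DEFAULT_PALETTE)]
    return default_cycle[fam]


def _panel_tops(model: DisplayModel) -> Dict[str, float]:
    tops = {}
    y = _MARGIN
    tops["ruler"] = y
    y += _RULER_H
    tops["charts"] = y
    y += _CHART_H
    tops["mask"] = y
    y += _MASK_H
    tops["hsp"] = y
    y += _HSP_H
    tops["matches"] = y
    y += model.max_levels * _LEVEL_H + _MARGIN
    tops["total"] = y
    return tops


def to_svg(model: DisplayModel, params: Optional[RenderParams] = None) -> str:
    """Serialize the display model to a deterministic SVG 1.1 document."""
    params = params or RenderParams(nt_per_pixel=model.nt_per_pixel,
                                    max_levels=model.max_levels)
    npp = model.nt_per_pixel
    x = lambda nt: _MARGIN + nt / npp
    tops = _panel_tops(model)
    width = _MARGIN * 2 + model.length / npp
    height = tops["total"]
    out: List[str] = []
    out.append('<?xml version="1.0" encoding="UTF-8"?>')
    out.append(
        f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
        f'width="{_fmt(width)}" height="{_fmt(height)}" '
        f'data-query="{model.query_id}" data-length="{model.length}" '
        f'data-nt-per-pixel="{_fmt(npp)}">'
    )

    # --- ruler ---
    y0 = tops["ruler"]
    out.append('<g class="ruler">')
    out.append(
        f'<line class="baseline" x1="{_fmt(x(0))}" y1="{_fmt(y0 + 20)}" '
        f'x2="{_fmt(x(model.length))}" y2="{_fmt(y0 + 20)}" stroke="black"/>'
    )
    for t in model.ticks:
        tx = x(t.pos_1based)
        out.append(
            f'<line class="tick" data-pos="{t.pos_1based}" '
            f'x1="{_fmt(tx)}" y1="{_fmt(y0 + 12)}" x2="{_fmt(tx)}" '
            f'y2="{_fmt(y0 + 20)}" stroke="black"/>'
        )
        out.append(
            f'<text class="tick-label" x="{_fmt(tx)}" y="{_fmt(y0 + 8)}" '
            f'font-size="6" text-anchor="middle">{t.pos_1based}</text>'
        )
        out.append(
            f'<text class="gap-relative-label" data-pos="{t.pos_1based}" '
            f'x="{_fmt(tx)}" y="{_fmt(y0 + 32)}" font-size="6" '
            f'text-anchor="middle">{t.gap_relative}</text>'
        )
    for bar in model.gap_bars:
        bx = x(bar.x_nt)
        out.append(
            f'<rect class="gap-bar" data-gap="{bar.gap_index}" '
            f'x="{_fmt(bx - 0.75)}" y="{_fmt(y0 + 10)}" width="1.5" '
            f'height="26" fill="grey"/>'
        )
    out.append("</g>")

    # --- charts: background first, then foreground, each set scaled to its own y_max ---
    y0 = tops["charts"]
    out.append('<g class="charts">')
    for set_name, charts, ymax in (
        ("background", model.chart_sets.background, model.chart_sets.background_y_max),
        ("foreground", model.chart_sets.foreground, model.chart_sets.foreground_y_max),
    ):
        for chart in charts:
            pts = []
            vals = chart.values
            n_bins = max(1, int(model.length / npp))
            scale = (_CHART_H - 10) / ymax if ymax else 0.0
            for b in range(n_bins):
                lo = int(b * npp)
                hi = min(len(vals), max(lo + 1, int((b + 1) * npp)))
                if lo >= len(vals):
                    break
                v = int(vals[lo:hi].max()) if hi > lo else 0
                pts.append(f"{_fmt(x(lo))},{_fmt(y0 + _CHART_H - 5 - v * scale)}")
            out.append(
                f'<polyline class="chart chart-{set_name}" '
                f'data-name="{chart.chart_name}" data-ymax="{chart.y_max}" '
                f'fill="none" stroke="{chart.color}" points="{" ".join(pts)}"/>'
            )
    out.append("</g>")

    # --- cross_match masks ---
    y0 = tops["mask"]
    cycle: Dict[str, str] = {}
    out.append('<g class="mask-panel">')
    for seg in model.mask_segments:
        f = seg.feature
        color = _feature_color(seg, params.feature_colors, cycle)
        out.append(
            f'<rect class="mask" data-q="{f.q_start + 1}-{f.q_end}" '
            f'data-subject="{f.subject_id}" x="{_fmt(x(f.q_start))}" '
            f'y="{_fmt(y0 + 8)}" width="{_fmt(max(0.5, f.length / npp))}" '
            f'height="14" fill="{color}"/>'
        )
        out.append(
            f'<text class="mask-label" x="{_fmt(x(f.q_start))}" '
            f'y="{_fmt(y0 + 30)}" font-size="5">{f.q_start + 1}-{f.q_end}</text>'
        )
    out.append("</g>")

    # --- BLAST HSP arrows (same-db stacked overlaps: shorter drawn over longer) ---
    y0 = tops["hsp"]
    out.append('<g class="hsp-panel">')
    for seg in sorted(model.hsp_segments, key=lambda s: (-s.feature.length,
                                                         s.q_start)):
        f = seg.feature
        color = _feature_color(seg, params.feature_colors, cycle)
        x1, x2 = x(f.q_start), x(f.q_end)
        head = min(6.0, (x2 - x1) / 3)
        ym = y0 + 16
        if f.strand == "+":
            pts = (f"{_fmt(x1)},{_fmt(ym - 6)} {_fmt(x2 - head)},{_fmt(ym - 6)} "
                   f"{_fmt(x2)},{_fmt(ym)} {_fmt(x2 - head)},{_fmt(ym + 6)} "
                   f"{_fmt(x1)},{_fmt(ym + 6)}")
        else:
            pts = (f"{_fmt(x2)},{_fmt(ym - 6)} {_fmt(x1 + head)},{_fmt(ym - 6)} "
                   f"{_fmt(x1)},{_fmt(ym)} {_fmt(x1 + head)},{_fmt(ym + 6)} "
                   f"{_fmt(x2)},{_fmt(ym + 6)}")
        out.append(
            f'<polygon class="hsp" data-strand="{f.strand}" '
            f'data-q="{f.q_start + 1}-{f.q_end}" data-s="{f.s_start}-{f.s_end}" '
            f'data-subject="{f.subject_id}" points="{pts}" fill="{color}"/>'
        )
        out.append(
            f'<text class="hsp-label" x="{_fmt(x1)}" y="{_fmt(y0 + 30)}" '
            f'font-size="5">q:{f.q_start + 1}-{f.q_end} s:{f.s_start}-{f.s_end}</text>'
        )
    out.append("</g>")

    # --- exact-match lines: level 0 on top ---
    y0 = tops["matches"]
    out.append('<g class="match-panel">')
    for m in model.placed_matches:
        color = "red" if m.orientation == "direct" else "blue"
        ym = y0 + (m.level or 0) * _LEVEL_H + 2
        out.append(
            f'<g class="match match-{m.orientation}" data-level="{m.level}" '
            f'data-a="{m.a_start + 1}-{m.a_end}" data-b="{m.b_start + 1}-{m.b_end}">'
        )
        out.append(
            f'<line class="match-arm" x1="{_fmt(x(m.a_start))}" y1="{_fmt(ym)}" '
            f'x2="{_fmt(x(m.a_end))}" y2="{_fmt(ym)}" stroke="{color}"/>'
        )
        out.append(
            f'<line class="match-arm" x1="{_fmt(x(m.b_start))}" y1="{_fmt(ym)}" '
            f'x2="{_fmt(x(m.b_end))}" y2="{_fmt(ym)}" stroke="{color}"/>'
        )
        out.append(
            f'<line class="match-connector" x1="{_fmt(x(m.a_end))}" '
            f'y1="{_fmt(ym)}" x2="{_fmt(x(m.b_start))}" y2="{_fmt(ym)}" '
            f'stroke="{color}" stroke-dasharray="2,2"/>'
        )
        out.append("</g>")
    out.append("</g>")
    out.append("</svg>")
    return "\n".join(out) + "\n"


def to_postscript(model: DisplayModel, params: Optional[RenderParams] = None) -> str:
    """Serialize the display model to PostScript Level 2 (deterministic)."""
    params = params or RenderParams(nt_per_pixel=model.nt_per_pixel,
                                    max_levels=model.max_levels)
    npp = model.nt_per_pixel
    tops = _panel_tops(model)
    width = _MARGIN * 2 + model.length / npp
    height = tops["total"]
    x = lambda nt: _MARGIN + nt / npp
    # PostScript y grows upward; flip against total height
    y = lambda yy: height - yy

    _RGB = {
        "black": (0, 0, 0), "grey": (0.5, 0.5, 0.5), "gray": (0.5, 0.5, 0.5),
        "red": (1, 0, 0), "blue": (0, 0, 1), "green": (0, 0.5, 0),
        "maroon": (0.5, 0, 0), "tan": (0.82, 0.71, 0.55),
        "orange": (1, 0.65, 0), "purple": (0.5, 0, 0.5), "pink": (1, 0.75, 0.8),
        "yellow": (1, 1, 0), "white": (1, 1, 1),
    }

    def rgb(color: str) -> str:
        if color.startswith("#") and len(color) == 7:
            r, g, b = (int(color[i : i + 2], 16) / 255 for i in (1, 3, 5))
        else:
            r, g, b = _RGB.get(color, (0.3, 0.3, 0.3))
        return f"{r:.3f} {g:.3f} {b:.3f} setrgbcolor"

    ps: List[str] = [
        "%!PS-Adobe-3.0 EPSF-3.0",
        f"%%BoundingBox: 0 0 {int(width + 1)} {int(height + 1)}",
        f"%%Title: {model.query_id}",
        "%%EndComments",
        "0.75 setlinewidth",
        "/Helvetica findfont 6 scalefont setfont",
    ]

    def line(x1, y1, x2, y2):
        ps.append(f"newpath {x1:.2f} {y(y1):.2f} moveto {x2:.2f} {y(y2):.2f} lineto stroke")

    def box(x1, yy, w, h):
        ps.append(
            f"newpath {x1:.2f} {y(yy + h):.2f} moveto {w:.2f} 0 rlineto "
            f"0 {h:.2f} rlineto {-w:.2f} 0 rlineto closepath fill"
        )

    def text(x1, yy, s):
        ps.append(f"{x1:.2f} {y(yy):.2f} moveto ({s}) show")

    y0 = tops["ruler"]
    ps.append(rgb("black"))
    line(x(0), y0 + 20, x(model.length), y0 + 20)
    for t in model.ticks:
        tx = x(t.pos_1based)
        line(tx, y0 + 12, tx, y0 + 20)
        text(tx - 5, y0 + 6, str(t.pos_1based))
        text(tx - 5, y0 + 32, str(t.gap_relative))
    ps.append(rgb("grey"))
    for bar in model.gap_bars:
        box(x(bar.x_nt) - 0.75, y0 + 10, 1.5, 26)

    y0 = tops["charts"]
    for charts, ymax in ((model.chart_sets.background, model.chart_sets.background_y_max),
                         (model.chart_sets.foreground, model.chart_sets.foreground_y_max)):
        for chart in charts:
            ps.append(rgb(chart.color))
            scale = (_CHART_H - 10) / ymax if ymax else 0.0
            vals = chart.values
            n_bins = max(1, int(model.length / npp))
            started = False
            for b in range(n_bins):
                lo = int(b * npp)
                hi = min(len(vals), max(lo + 1, int((b + 1) * npp)))
                if lo >= len(vals):
                    break
                v = int(vals[lo:hi].max()) if hi > lo else 0
                px, py = x(lo), y(y0 + _CHART_H - 5 - v * scale)
                if not started:
                    ps.append(f"newpath {px:.2f} {py:.2f} moveto")
                    started = True
                else:
                    ps.append(f"{px:.2f} {py:.2f} lineto")
            if started:
                ps.append("stroke")

    cycle: Dict[str, str] = {}
    y0 = tops["mask"]
    for seg in model.mask_segments:
        f = seg.feature
        ps.append(rgb(_feature_color(seg, params.feature_colors, cycle)))
        box(x(f.q_start), y0 + 8, max(0.5, f.length / npp), 14)
        ps.append(rgb("black"))
        text(x(f.q_start), y0 + 30, f"{f.q_start + 1}-{f.q_end}")

    y0 = tops["hsp"]
    for seg in sorted(model.hsp_segments, key=lambda s: (-s.feature.length, s.q_start)):
        f = seg.feature
        ps.append(rgb(_feature_color(seg, params.feature_colors, cycle)))
        box(x(f.q_start), y0 + 10, max(0.5, f.length / npp), 12)
        ps.append(rgb("black"))
        text(x(f.q_start), y0 + 30, f"q:{f.q_start + 1}-{f.q_end} s:{f.s_start}-{f.s_end}")

    y0 = tops["matches"]
    for m in model.placed_matches:
        ps.append(rgb("red" if m.orientation == "direct" else "blue"))
        ym = y0 + (m.level or 0) * _LEVEL_H + 2
        line(x(m.a_start), ym, x(m.a_end), ym)
        line(x(m.b_start), ym, x(m.b_end), ym)
        ps.append("[2 2] 0 setdash")
        line(x(m.a_end), ym, x(m.b_start), ym)
        ps.append("[] 0 setdash")

    ps.append("showpage")
    ps.append("%%EOF")
    return "\n".join(ps) + "\n"
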