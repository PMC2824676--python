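"""Per-nucleotide coverage charts from read placements.

ChIP-Seq style read placements are turned into per-nucleotide coverage
values, stratified by mapping multiplicity (how often the read occurs in
the query and in the whole genome/sequence set). Charts are organized in
two sets — foreground and background — drawn with independent y-axes:
the background (typically all reads regardless of multiplicity) shows
the general association of a sequence class with the mark, while
foreground charts (unique or near-unique reads) highlight regions that
are specifically bound.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np


@dataclass(frozen=True)
class ReadPlacement:
    """One mapped read: interval on the query plus multiplicity counts."""

    read_id: str
    query_id: str
    q_start: int  # 0-based inclusive
    q_end: int  # 0-based exclusive
    hits_in_query: int
    hits_in_genome: int

    def __post_init__(self) -> None:
        if self.q_end <= self.q_start:
            raise ValueError("placement must have q_end > q_start")
        if not (self.hits_in_genome >= self.hits_in_query >= 1):
            raise ValueError(
                "multiplicities must satisfy hits_in_genome >= hits_in_query >= 1"
            )


CategoryFilter = Callable[[ReadPlacement], bool]

#: The three standard multiplicity categories. ``unique`` keeps reads
#: placed once in the query and at most twice genome-wide (a sequence
#: present in two overlapping clones is still effectively unique);
#: ``multi`` allows any within-query multiplicity but still near-unique
#: genome-wide; ``all`` is unrestricted. They are nested, so per-
#: nucleotide values are monotone non-decreasing from unique to all.
STANDARD_FILTERS: Dict[str, CategoryFilter] = {
    "unique": lambda p: p.hits_in_query == 1 and p.hits_in_genome <= 2,
    "multi": lambda p: p.hits_in_genome <= 2,
    "all": lambda p: True,
}


@dataclass
class CoverageChart:
    """One chart: a non-negative integer value per query nucleotide."""

    chart_name: str
    values: np.ndarray
    chart_set: str = "foreground"  # 'foreground' | 'background'
    color: str = "red"

    def __post_init__(self) -> None:
        if self.chart_set not in ("foreground", "background"):
            raise ValueError("chart_set must be foreground or background")
        self.values = np.asarray(self.values, dtype=np.int64)

    @property
    def y_max(self) -> int:
        """The y-axis is automatically extended to the largest value."""
        return int(self.values.max()) if self.values.size else 0


@dataclass
class ChartSets:
    """The two chart sets with their independent y-axes; the background
    set is drawn first (under the foreground)."""

    foreground: List[CoverageChart]
    background: List[CoverageChart]

    @property
    def foreground_y_max(self) -> int:
        return max((c.y_max for c in self.foreground), default=0)

    @property
    def background_y_max(self) -> int:
        return max((c.y_max for c in self.background), default=0)

    def all_charts(self) -> List[CoverageChart]:
        return self.background + self.foreground


def build_coverage(
    placements: Sequence[ReadPlacement],
    query_len: int,
    category_filter: Union[str, CategoryFilter] = "all",
    chart_name: str = "coverage",
    chart_set: str = "foreground",
    color: str = "red",
) -> CoverageChart:
    """Count, for each nucleotide, the placements covering it that pass
    the category filter (a nucleotide covered by two reads gets 2).
    """
    if isinstance(category_filter, str):
        try:
            category_filter = STANDARD_FILTERS[category_filter]
        except KeyError:
            raise ValueError(
                f"unknown category {category_filter!r}; "
                f"choose from {sorted(STANDARD_FILTERS)}"
            ) from None
    diff = np.zeros(query_len + 1, dtype=np.int64)
    for p in placements:
        if p.q_start < 0 or p.q_end > query_len:
            raise ValueError(
                f"placement {p.read_id} [{p.q_start},{p.q_end}) exceeds query "
                f"bounds [0,{query_len})"
            )
        if category_filter(p):
            diff[p.q_start] += 1
            diff[p.q_end] -= 1
    values = np.cumsum(diff[:-1])
    return CoverageChart(chart_name=chart_name, values=values,
                         chart_set=chart_set, color=color)


def assemble_chart_sets(charts: Iterable[CoverageChart]) -> ChartSets:
    fg = [c for c in charts if c.chart_set == "foreground"]
    bg = [c for c in charts if c.chart_set == "background"]
    return ChartSets(foreground=fg, background=bg)


# ---------------------------------------------------------------------------
# I/O

_TSV_HEADER = "read_id\tquery_id\tq_start\tq_end\thits_in_query\thits_in_genome"


def placements_to_tsv(placements: Iterable[ReadPlacement]) -> str:
    lines = [_TSV_HEADER]
    for p in placements:
        lines.append(
            f"{p.read_id}\t{p.query_id}\t{p.q_start}\t{p.q_end}\t"
            f"{p.hits_in_query}\t{p.hits_in_genome}"
        )
    return "\n".join(lines) + "\n"


def placements_from_tsv(path_or_text: Union[str, Path]) -> List[ReadPlacement]:
    """Read the 6-column placement TSV (header line optional)."""
    if isinstance(path_or_text, Path) or "\n" not in str(path_or_text):
        text = Path(path_or_text).read_text()
    else:
        text = str(path_or_text)
    out = []
    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("read_id") or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 6:
            raise ValueError(f"placements line {lineno}: expected 6 columns")
        out.append(
            ReadPlacement(
                read_id=cols[0], query_id=cols[1],
                q_start=int(cols[2]), q_end=int(cols[3]),
                hits_in_query=int(cols[4]), hits_in_genome=int(cols[5]),
            )
        )
    return out


def chart_to_bedgraph(chart: CoverageChart, query_id: str) -> str:
    """Run-length encode a chart as bedGraph lines (0-based half-open)."""
    lines = [f'track type=bedGraph name="{chart.chart_name}"']
    vals = chart.values
    if vals.size:
        boundaries = np.flatnonzero(np.diff(vals)) + 1
        starts = np.concatenate(([0], boundaries))
        ends = np.concatenate((boundaries, [vals.size]))
        for s, e in zip(starts, ends):
            lines.append(f"{query_id}\t{s}\t{e}\t{vals[s]}")
    return "\n".join(lines) + "\n"
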