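"""The six-section plain-text parameters file that drives the pipeline.

Sections:
  [general]               paths, display scale, overlap allowance, gap/tiling rules
  [ncbi-blast-databases]  one subject database per line, with an E-value filter
  [wu-blast-databases]    as above, plus a score-equivalence fraction
  [blast-colors]          subject (and subject sub-range) colors per database
  [crossmatch-databases]  masking databases with one color each
  [charts]                per-nucleotide data charts, assigned to the
                          foreground or background chart set

Dialect: ``[section]`` headers, ``key = value`` lines, ``#`` comments.
Multi-entry sections use one line per entry with comma-separated
``key=value`` attributes after the path.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Tuple, Union

SECTION_NAMES = (
    "general",
    "ncbi-blast-databases",
    "wu-blast-databases",
    "blast-colors",
    "crossmatch-databases",
    "charts",
)

_NAMED_COLORS = {
    "black", "white", "red", "blue", "green", "grey", "gray", "maroon",
    "pink", "tan", "orange", "purple", "yellow", "brown", "cyan", "magenta",
    "navy", "olive", "teal", "silver", "lime", "aqua", "fuchsia", "salmon",
    "darkred", "darkblue", "darkgreen", "lightblue", "lightgrey", "gold",
}
_HEX_RE = re.compile(r"^#[0-9a-fA-F]{6}$")


class ConfigError(ValueError):
    """A parameters-file problem, reported with section context."""


def _check_color(color: str, where: str) -> str:
    if color in _NAMED_COLORS or _HEX_RE.match(color):
        return color
    raise ConfigError(f"invalid color {color!r} in section [{where}]")


@dataclass
class GeneralParams:
    query_path: Path = Path("query.fasta")
    output_dir: Path = Path("junctionscan-out")
    nt_per_pixel: float = 50.0
    inter_db_overlap_allowance_nt: int = 0
    gap_run_threshold_nt: int = 100
    tile_window_nt: int = 210_000
    tile_overlap_nt: int = 10_000
    mummer_min_match_nt: int = 100
    max_levels: int = 30

    def validate(self) -> None:
        if self.nt_per_pixel <= 0:
            raise ConfigError("nt_per_pixel must be positive")
        if self.inter_db_overlap_allowance_nt < 0:
            raise ConfigError("inter_db_overlap_allowance must be >= 0")
        if self.gap_run_threshold_nt < 1:
            raise ConfigError("gap_run_threshold must be >= 1")
        if self.tile_window_nt < 1 or self.tile_overlap_nt < 0:
            raise ConfigError("tile window/overlap must be positive")
        if self.tile_overlap_nt >= self.tile_window_nt:
            raise ConfigError(
                f"tile_overlap ({self.tile_overlap_nt}) must be smaller than "
                f"tile_window ({self.tile_window_nt})"
            )
        if self.mummer_min_match_nt < 1 or self.max_levels < 1:
            raise ConfigError("mummer_min_match and max_levels must be >= 1")


@dataclass
class BlastDbParams:
    db_name: str
    db_path: Path
    engine: str  # "ncbi" | "wu"
    evalue_cutoff: float = 1e-10
    score_equivalence_fraction: float = 1.0
    priority_rank: int = 0

    def validate(self) -> None:
        if self.engine not in ("ncbi", "wu"):
            raise ConfigError(f"db {self.db_name}: engine must be ncbi or wu")
        if self.evalue_cutoff <= 0:
            raise ConfigError(f"db {self.db_name}: evalue cutoff must be > 0")
        if not (0 < self.score_equivalence_fraction <= 1):
            raise ConfigError(
                f"db {self.db_name}: score_equivalence must be in (0, 1]"
            )


@dataclass
class CrossmatchDbParams:
    db_name: str
    db_path: Path
    color: str = "grey"
    priority_rank: int = 0


@dataclass
class ColorScheme:
    """Colors for one BLAST database: per subject, and optionally per
    sub-range of a subject (so e.g. the LTR portion of a full-length
    element template can be drawn in its own color)."""

    db_name: str
    per_subject_colors: Dict[str, str] = field(default_factory=dict)
    # (subject_id, s_start_1based, s_end_1based, color)
    per_subrange_colors: List[Tuple[str, int, int, str]] = field(default_factory=list)

    def validate(self) -> None:
        for color in self.per_subject_colors.values():
            _check_color(color, "blast-colors")
        by_subject: Dict[str, List[Tuple[int, int]]] = {}
        for subj, s, e, color in self.per_subrange_colors:
            _check_color(color, "blast-colors")
            if e < s:
                raise ConfigError(f"subrange end < start for subject {subj}")
            by_subject.setdefault(subj, []).append((s, e))
        for subj, ranges in by_subject.items():
            ranges.sort()
            for (s1, e1), (s2, e2) in zip(ranges, ranges[1:]):
                if s2 <= e1:
                    raise ConfigError(
                        f"overlapping color subranges for subject {subj}"
                    )

    def color_for(self, subject_id: str, s_start: int, s_end: int) -> str | None:
        """Sub-range color wins when the subject midpoint falls inside it."""
        mid = (s_start + s_end) // 2
        for subj, s, e, color in self.per_subrange_colors:
            if subj == subject_id and s <= mid <= e:
                return color
        return self.per_subject_colors.get(subject_id)


@dataclass
class ChartParams:
    chart_name: str
    data_path: Path
    chart_set: str = "foreground"
    color: str = "red"

    def validate(self) -> None:
        if self.chart_set not in ("foreground", "background"):
            raise ConfigError(
                f"chart {self.chart_name}: set must be foreground or background"
            )
        _check_color(self.color, "charts")


@dataclass
class Configuration:
    general: GeneralParams
    ncbi_dbs: List[BlastDbParams]
    wu_dbs: List[BlastDbParams]
    blast_colors: List[ColorScheme]
    crossmatch_dbs: List[CrossmatchDbParams]
    charts: List[ChartParams]

    @property
    def blast_dbs(self) -> List[BlastDbParams]:
        return self.ncbi_dbs + self.wu_dbs

    def validate(self) -> None:
        self.general.validate()
        names = [d.db_name for d in self.blast_dbs]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise ConfigError(f"duplicate BLAST db_name(s): {sorted(dupes)}")
        for d in self.blast_dbs:
            d.validate()
        for cs in self.blast_colors:
            cs.validate()
        for cm in self.crossmatch_dbs:
            _check_color(cm.color, "crossmatch-databases")
        for ch in self.charts:
            ch.validate()


def _split_entry(value: str) -> Tuple[str, Dict[str, str]]:
    """``path, k1=v1, k2=v2`` -> (path, attributes)."""
    parts = [p.strip() for p in value.split(",")]
    attrs = {}
    for p in parts[1:]:
        if "=" not in p:
            raise ConfigError(f"malformed attribute {p!r} (expected key=value)")
        k, v = p.split("=", 1)
        attrs[k.strip()] = v.strip()
    return parts[0], attrs


_GENERAL_KEYS = {
    "query": ("query_path", Path),
    "output_dir": ("output_dir", Path),
    "nt_per_pixel": ("nt_per_pixel", float),
    "inter_db_overlap_allowance": ("inter_db_overlap_allowance_nt", int),
    "gap_run_threshold": ("gap_run_threshold_nt", int),
    "tile_window": ("tile_window_nt", int),
    "tile_overlap": ("tile_overlap_nt", int),
    "mummer_min_match": ("mummer_min_match_nt", int),
    "max_levels": ("max_levels", int),
}

_SUBRANGE_RE = re.compile(r"^(?P<subj>[^\[\].]+)\[(?P<s>\d+):(?P<e>\d+)\]$")


def parse_parameters(path: Union[str, Path]) -> Configuration:
    """Parse and validate the six-section parameters file.

    All six section headers must be present (a section body may be
    empty). Referenced file paths are recorded but not checked for
    existence here — consumers open them lazily.
    """
    path = Path(path)
    sections: Dict[str, List[Tuple[int, str, str]]] = {}
    current = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if line.startswith("[") and line.endswith("]"):
                current = line[1:-1].strip().lower()
                if current not in SECTION_NAMES:
                    raise ConfigError(
                        f"{path}:{lineno}: unknown section [{current}]"
                    )
                sections.setdefault(current, [])
                continue
            if current is None:
                raise ConfigError(f"{path}:{lineno}: entry before any section header")
            if "=" not in line:
                raise ConfigError(f"{path}:{lineno}: expected key = value")
            key, value = (s.strip() for s in line.split("=", 1))
            sections[current].append((lineno, key, value))

    missing = [s for s in SECTION_NAMES if s not in sections]
    if missing:
        raise ConfigError(
            f"{path}: missing mandatory section(s): " + ", ".join(f"[{m}]" for m in missing)
        )

    general = GeneralParams()
    for lineno, key, value in sections["general"]:
        if key not in _GENERAL_KEYS:
            raise ConfigError(f"{path}:{lineno}: unknown general key {key!r}")
        attr, conv = _GENERAL_KEYS[key]
        try:
            setattr(general, attr, conv(value))
        except ValueError as exc:
            raise ConfigError(f"{path}:{lineno}: bad value for {key}: {exc}") from exc

    def _parse_blast_section(name: str, engine: str) -> List[BlastDbParams]:
        dbs = []
        for lineno, key, value in sections[name]:
            db_path, attrs = _split_entry(value)
            try:
                dbs.append(
                    BlastDbParams(
                        db_name=key,
                        db_path=Path(db_path),
                        engine=engine,
                        evalue_cutoff=float(attrs.pop("evalue", 1e-10)),
                        score_equivalence_fraction=float(
                            attrs.pop("score_equivalence", 1.0)
                        ),
                        priority_rank=int(attrs.pop("priority", len(dbs))),
                    )
                )
            except ValueError as exc:
                raise ConfigError(f"{path}:{lineno}: {exc}") from exc
            if attrs:
                raise ConfigError(
                    f"{path}:{lineno}: unknown attribute(s) {sorted(attrs)}"
                )
        return dbs

    ncbi_dbs = _parse_blast_section("ncbi-blast-databases", "ncbi")
    wu_dbs = _parse_blast_section("wu-blast-databases", "wu")

    schemes: Dict[str, ColorScheme] = {}
    for lineno, key, value in sections["blast-colors"]:
        # key is db.subject or db.subject[start:end]
        if "." not in key:
            raise ConfigError(
                f"{path}:{lineno}: blast-colors key must be db.subject"
            )
        db_name, subject = key.split(".", 1)
        scheme = schemes.setdefault(db_name, ColorScheme(db_name=db_name))
        m = _SUBRANGE_RE.match(subject)
        if m:
            scheme.per_subrange_colors.append(
                (m.group("subj"), int(m.group("s")), int(m.group("e")), value)
            )
        else:
            scheme.per_subject_colors[subject] = value

    crossmatch_dbs = []
    for lineno, key, value in sections["crossmatch-databases"]:
        db_path, attrs = _split_entry(value)
        crossmatch_dbs.append(
            CrossmatchDbParams(
                db_name=key,
                db_path=Path(db_path),
                color=attrs.pop("color", "grey"),
                priority_rank=int(attrs.pop("priority", len(crossmatch_dbs))),
            )
        )
        if attrs:
            raise ConfigError(f"{path}:{lineno}: unknown attribute(s) {sorted(attrs)}")

    charts = []
    for lineno, key, value in sections["charts"]:
        data_path, attrs = _split_entry(value)
        charts.append(
            ChartParams(
                chart_name=key,
                data_path=Path(data_path),
                chart_set=attrs.pop("set", "foreground"),
                color=attrs.pop("color", "red"),
            )
        )
        if attrs:
            raise ConfigError(f"{path}:{lineno}: unknown attribute(s) {sorted(attrs)}")

    cfg = Configuration(
        general=general,
        ncbi_dbs=ncbi_dbs,
        wu_dbs=wu_dbs,
        blast_colors=list(schemes.values()),
        crossmatch_dbs=crossmatch_dbs,
        charts=charts,
    )
    cfg.validate()
    return cfg


_TEMPLATE = """\
# junctionscan parameters file.
# Six sections; '#' starts a comment. Multi-entry sections use one line
# per entry:  name = path, key=value, key=value

[general]
# path to the query FASTA (single- or multi-record)
query = query.fasta
# directory for all output artifacts
output_dir = junctionscan-out
# horizontal display scale: nucleotides represented by one pixel/point
nt_per_pixel = 50
# overlap (nt) tolerated between kept features from different databases
inter_db_overlap_allowance = 0
# minimum run of Ns that counts as an assembly gap (one grey bar per 100 Ns)
gap_run_threshold = 100
# long queries are cut into windows of this size ...
tile_window = 210000
# ... overlapping by this much, so features up to this size draw whole once
tile_overlap = 10000
# minimum exact-match length reported by the exact matcher
mummer_min_match = 100
# number of drawing levels for exact-match lines
max_levels = 30

[ncbi-blast-databases]
# one subject database per line:
#   name = path/to/db.fasta, evalue=1e-10, priority=0
# evalue: keep HSPs with E-value <= this; priority: competition tie-break rank
#centc = databases/centc.fasta, evalue=1e-10, priority=0

[wu-blast-databases]
# as above, plus a score-equivalence fraction: keep HSPs scoring at least
# this fraction of a perfect complete match to the subject
#crm_ltrs = databases/crm_ltrs.fasta, evalue=1e-10, score_equivalence=0.9, priority=1

[blast-colors]
# subject colors:           db.subject = color
# subject sub-range colors: db.subject[start:end] = color   (1-based, inclusive)
#crm_ltrs.CRM2_LTR = maroon
#crm_ltrs.CRM1_full[1:1500] = blue

[crossmatch-databases]
# masking databases, one color each:
#   name = path/to/library.fasta, color=grey, priority=0
#maize_repeats = databases/repeats.fasta, color=grey

[charts]
# per-nucleotide numeric charts from read placements:
#   name = placements.tsv, set=foreground|background, color=red
#unique_reads = placements.tsv, set=foreground, color=red
#all_reads = placements.tsv, set=background, color=grey
"""


def write_template(path: Union[str, Path]) -> None:
    """Write a commented parameters template that re-parses cleanly."""
    with open(path, "w") as fh:
        fh.write(_TEMPLATE)
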