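"""Query sequence input, assembly-gap detection and window tiling.

Coordinates are 0-based half-open internally; anything user-facing
(ruler labels, reports, GFF/BED exports) converts at the boundary.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, List, Union

from Bio import SeqIO

_VALID_RE = re.compile(r"^[ACGTNacgtn]*$")

#: minimum run of Ns that counts as an assembly gap
DEFAULT_GAP_THRESHOLD = 100
#: analysis window width used for long sequences
DEFAULT_TILE_WINDOW = 210_000
#: overlap between consecutive windows, so features up to this size are
#: drawn whole at least once
DEFAULT_TILE_OVERLAP = 10_000


@dataclass(frozen=True)
class QuerySequence:
    """One query record: an id and its nucleotide string (A/C/G/T/N)."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("query sequence id must be non-empty")
        if not _VALID_RE.match(self.residues):
            bad = sorted(set(re.sub(r"[ACGTNacgtn]", "", self.residues)))
            raise ValueError(
                f"query {self.id!r} contains non-ACGTN characters: {bad}"
            )
        object.__setattr__(self, "residues", self.residues.upper())

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def length(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class GapInterval:
    """A maximal run of >= threshold Ns; drawn as a stack of grey bars.

    ``n_bars`` is one bar per complete 100-N block (so a 1,000-N run is a
    stack of ten bars and a 100-N run a single bar); runs detected with a
    sub-100 threshold still get one bar so the gap stays visible.
    """

    start: int  # 0-based inclusive
    end: int  # 0-based exclusive

    @property
    def run_length(self) -> int:
        return self.end - self.start

    @property
    def n_bars(self) -> int:
        return max(1, self.run_length // 100)

    @property
    def end_1based(self) -> int:
        """1-based coordinate of the last N of the run."""
        return self.end


@dataclass(frozen=True)
class Tile:
    """One analysis window of a parent sequence (1-based inclusive)."""

    parent_id: str
    start_1based: int
    end_1based: int

    @property
    def length(self) -> int:
        return self.end_1based - self.start_1based + 1


def read_fasta(path: Union[str, Path]) -> List[QuerySequence]:
    """Read a (multi-record) FASTA file into QuerySequence objects."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(QuerySequence(id=rec.id, residues=str(rec.seq)))
    return records


def write_fasta(path: Union[str, Path], seqs: Iterable[QuerySequence], width: int = 70) -> None:
    with open(path, "w") as fh:
        for seq in seqs:
            fh.write(f">{seq.id}\n")
            for i in range(0, len(seq.residues), width):
                fh.write(seq.residues[i : i + width] + "\n")


def detect_gaps(
    seq: Union[QuerySequence, str], threshold: int = DEFAULT_GAP_THRESHOLD
) -> List[GapInterval]:
    """Find maximal runs of >= ``threshold`` consecutive Ns.

    Returns sorted, non-overlapping intervals. Runs shorter than the
    threshold are ignored; an empty sequence yields an empty list.
    """
    if threshold < 1:
        raise ValueError("gap run threshold must be >= 1")
    residues = seq.residues if isinstance(seq, QuerySequence) else seq.upper()
    gaps = []
    for m in re.finditer(r"N+", residues):
        if m.end() - m.start() >= threshold:
            gaps.append(GapInterval(start=m.start(), end=m.end()))
    return gaps


def gap_relative_coordinate(pos_1based: int, gaps: List[GapInterval], length: int | None = None) -> int:
    """Nucleotides from ``pos`` back to the end of the nearest preceding gap.

    This is the secondary ruler value printed under each tick: the
    distance from the 1-based position to the end coordinate of the last
    gap, or the position itself when no gap precedes it. Positions inside
    a gap report 0.
    """
    if pos_1based < 1 or (length is not None and pos_1based > length):
        raise IndexError(f"position {pos_1based} out of sequence range")
    best_end = 0
    for g in gaps:
        if g.end_1based <= pos_1based:
            best_end = max(best_end, g.end_1based)
        elif g.start < pos_1based <= g.end:  # inside the gap
            return 0
    return pos_1based - best_end


def tile_sequence(
    length: int,
    window: int = DEFAULT_TILE_WINDOW,
    overlap: int = DEFAULT_TILE_OVERLAP,
    origin_1based: int = 1,
    parent_id: str = "",
) -> List[Tile]:
    """Cut ``[origin, origin+length-1]`` into overlapping windows.

    Consecutive tiles advance by ``window - overlap``; the final tile is
    truncated at the region end. Any feature no longer than ``overlap``
    is fully contained in at least one tile.
    """
    if length < 1:
        raise ValueError("length must be positive")
    if overlap >= window:
        raise ValueError(f"tile overlap ({overlap}) must be smaller than window ({window})")
    region_end = origin_1based + length - 1
    tiles = []
    start = origin_1based
    while True:
        end = min(start + window - 1, region_end)
        tiles.append(Tile(parent_id=parent_id, start_1based=start, end_1based=end))
        if end >= region_end:
            break
        start += window - overlap
    return tiles


def tiles_to_bed(tiles: Iterable[Tile]) -> str:
    """Serialize tiles as BED (0-based half-open) lines."""
    lines = []
    for i, t in enumerate(tiles):
        lines.append(f"{t.parent_id}\t{t.start_1based - 1}\t{t.end_1based}\ttile{i}")
    return "\n".join(lines) + "\n" if lines else ""
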