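"""Homology evidence: aligner-output parsers and a built-in exact matcher.

Evidence enters either as pre-computed aligner output (NCBI/WU BLAST
tabular, cross_match alignment lines, MUMmer show-coords tables) or from
:func:`find_maximal_exact_matches`, a suffix-array based maximal
repeated-substring finder that makes the whole pipeline runnable with no
external binaries.

Query coordinates are normalized to 0-based half-open; subject
coordinates stay 1-based inclusive as aligners print them.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Iterable, List, Optional, TextIO, Tuple, Union

from . import _suffix

DEFAULT_MIN_MATCH = 100  # nt; minimum exact-match length reported

Stream = Union[str, Path, TextIO]


def _open(stream: Stream) -> Tuple[TextIO, bool]:
    if isinstance(stream, (str, Path)):
        return open(stream), True
    return stream, False


@dataclass(frozen=True)
class HomologyFeature:
    """One aligned segment on the query — the unit of competition."""

    query_id: str
    q_start: int  # 0-based inclusive
    q_end: int  # 0-based exclusive
    strand: str  # '+' or '-'
    db_name: str
    subject_id: str
    s_start: int  # 1-based inclusive, as printed by aligners
    s_end: int
    score: float
    evidence: str  # 'blast' | 'crossmatch'

    def __post_init__(self) -> None:
        if self.q_end <= self.q_start:
            raise ValueError(
                f"feature on {self.query_id}: q_end ({self.q_end}) must exceed "
                f"q_start ({self.q_start})"
            )
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.q_end - self.q_start

    def overlap_nt(self, other: "HomologyFeature") -> int:
        return max(0, min(self.q_end, other.q_end) - max(self.q_start, other.q_start))


@dataclass(frozen=True)
class ExactMatch:
    """A maximal repeated substring pair within one query.

    Direct: ``seq[a] == seq[b]``; inverted: ``seq[a] == revcomp(seq[b])``.
    Canonical order has ``a_start < b_start``. ``level`` is assigned by
    the renderer's level layout (None until then).
    """

    a_start: int
    a_end: int
    b_start: int
    b_end: int
    orientation: str  # 'direct' | 'inverted'
    level: Optional[int] = None

    def __post_init__(self) -> None:
        if self.a_end - self.a_start != self.b_end - self.b_start:
            raise ValueError("exact match intervals must have equal length")
        if self.orientation not in ("direct", "inverted"):
            raise ValueError(f"bad orientation {self.orientation!r}")
        if (self.a_start, self.b_start) > (self.b_start, self.a_start):
            raise ValueError("exact match not canonical (a_start must be <= b_start)")

    @property
    def length(self) -> int:
        return self.a_end - self.a_start

    @property
    def span(self) -> Tuple[int, int]:
        """Full horizontal extent: both intervals plus the connector."""
        return (self.a_start, self.b_end)

    def key(self) -> Tuple[int, int, int, str]:
        return (self.a_start, self.b_start, self.length, self.orientation)


class ParseError(ValueError):
    pass


# ---------------------------------------------------------------------------
# BLAST tabular (12-column outfmt-6 style)

def parse_blast_tabular(
    stream: Stream,
    db_name: str,
    evalue_cutoff: float = 10.0,
    query_id: Optional[str] = None,
) -> List[HomologyFeature]:
    """Parse 12-column BLAST tabular output, dropping rows above the
    E-value cutoff. Strand is inferred from subject coordinate order
    (s_start > s_end means minus strand) and subject coordinates are
    stored ascending. ``query_id`` restricts to one query if given.
    """
    fh, close = _open(stream)
    feats: List[HomologyFeature] = []
    try:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t") if "\t" in line else line.split()
            if len(cols) < 12:
                raise ParseError(
                    f"line {lineno}: expected 12 tabular columns, got {len(cols)}"
                )
            try:
                qid = cols[0]
                sid = cols[1]
                qstart, qend = int(cols[6]), int(cols[7])
                sstart, send = int(cols[8]), int(cols[9])
                evalue = float(cols[10])
                bitscore = float(cols[11])
            except ValueError as exc:
                raise ParseError(f"line {lineno}: {exc}") from exc
            if query_id is not None and qid != query_id:
                continue
            if evalue > evalue_cutoff:
                continue
            strand = "+"
            if sstart > send:
                strand = "-"
                sstart, send = send, sstart
            if qstart > qend:  # tolerated; some tools flip query instead
                strand = "-" if strand == "+" else "+"
                qstart, qend = qend, qstart
            feats.append(
                HomologyFeature(
                    query_id=qid,
                    q_start=qstart - 1,
                    q_end=qend,
                    strand=strand,
                    db_name=db_name,
                    subject_id=sid,
                    s_start=sstart,
                    s_end=send,
                    score=bitscore,
                    evidence="blast",
                )
            )
    finally:
        if close:
            fh.close()
    return feats


def filter_score_equivalence(
    features: Iterable[HomologyFeature],
    subject_lengths: Dict[str, int],
    fraction: float,
    match_reward: float = 1.0,
) -> List[HomologyFeature]:
    """Keep HSPs scoring at least ``fraction`` of a perfect complete match
    to their subject (subject length x match reward). This re-expresses
    the WU-BLAST score-equivalence (S) policy — e.g. 0.9 keeps hits no
    more than 10% below a perfect complete match, sharp enough to
    separate closely related repeat subfamilies — as a post-parse filter.
    """
    kept = []
    for f in features:
        slen = subject_lengths.get(f.subject_id)
        if slen is None:
            raise KeyError(f"no subject length for {f.subject_id!r}")
        if f.score >= fraction * slen * match_reward:
            kept.append(f)
    return kept


# ---------------------------------------------------------------------------
# cross_match alignment lines

def parse_crossmatch(
    stream: Stream,
    db_name: str = "crossmatch",
    subject_db_map: Optional[Dict[str, str]] = None,
) -> List[HomologyFeature]:
    """Parse cross_match alignment lines into features.

    Forward lines look like::

        2334 7.16 0.85 1.03  qid 101 800 (200)  subj 1 696 (4)

    and complement lines put a ``C`` before the subject with subject
    coordinates descending::

        2334 7.16 0.85 1.03  qid 101 800 (200)  C subj (4) 696 1

    ``subject_db_map`` may route individual subjects to named masking
    databases; otherwise all features carry ``db_name``.
    """
    fh, close = _open(stream)
    feats: List[HomologyFeature] = []
    try:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line:
                continue
            cols = line.split()
            if not cols[0].lstrip("-").isdigit():
                continue  # header/summary line
            try:
                score = float(cols[0])
                qid = cols[4]
                qstart, qend = int(cols[5]), int(cols[6])
                if cols[8] == "C":
                    strand = "-"
                    sid = cols[9]
                    # C lines: (left) end start
                    send, sstart = int(cols[11]), int(cols[12])
                else:
                    strand = "+"
                    sid = cols[8]
                    sstart, send = int(cols[9]), int(cols[10])
            except (IndexError, ValueError) as exc:
                raise ParseError(
                    f"line {lineno}: unrecognized cross_match layout: {line!r}"
                ) from exc
            db = (subject_db_map or {}).get(sid, db_name)
            feats.append(
                HomologyFeature(
                    query_id=qid,
                    q_start=qstart - 1,
                    q_end=qend,
                    strand=strand,
                    db_name=db,
                    subject_id=sid,
                    s_start=min(sstart, send),
                    s_end=max(sstart, send),
                    score=score,
                    evidence="crossmatch",
                )
            )
    finally:
        if close:
            fh.close()
    return feats


# ---------------------------------------------------------------------------
# MUMmer show-coords tables (self-comparison)

def _canonical_match(a_start: int, a_end: int, b_start: int, b_end: int,
                     orientation: str) -> Optional[ExactMatch]:
    if (a_start, a_end) == (b_start, b_end):
        return None  # self-hit / palindromic self-pair
    if a_start > b_start or (a_start == b_start and a_end > b_end):
        a_start, a_end, b_start, b_end = b_start, b_end, a_start, a_end
    return ExactMatch(a_start, a_end, b_start, b_end, orientation)


def parse_mummer_coords(stream: Stream, min_len: int = DEFAULT_MIN_MATCH) -> List[ExactMatch]:
    """Parse show-coords-style tables of a self-comparison.

    Rows are ``S1 E1 S2 E2 LEN1 LEN2 %IDY [tags]`` (pipes and headers
    tolerated). The trivial full-length self-hit and mirror duplicates
    are removed; ``E2 < S2`` marks an inverted match; matches shorter
    than ``min_len`` are dropped.
    """
    fh, close = _open(stream)
    seen = set()
    out: List[ExactMatch] = []
    try:
        for lineno, raw in enumerate(fh, 1):
            line = raw.replace("|", " ").strip()
            if not line:
                continue
            cols = line.split()
            if not cols[0].lstrip("-").isdigit():
                continue  # header lines (NUCMER, [S1] ... )
            if len(cols) < 5:
                raise ParseError(f"line {lineno}: too few coordinate columns")
            try:
                s1, e1, s2, e2 = (int(c) for c in cols[:4])
            except ValueError as exc:
                raise ParseError(f"line {lineno}: {exc}") from exc
            inverted = e2 < s2
            a_start, a_end = s1 - 1, e1
            if inverted:
                b_start, b_end = e2 - 1, s2
            else:
                b_start, b_end = s2 - 1, e2
            if a_end - a_start != b_end - b_start:
                continue  # not an exact (gapless) match
            m = _canonical_match(a_start, a_end, b_start, b_end,
                                 "inverted" if inverted else "direct")
            if m is None or m.length < min_len:
                continue
            if m.key() in seen:
                continue
            seen.add(m.key())
            out.append(m)
    finally:
        if close:
            fh.close()
    out.sort(key=lambda m: (-m.length, m.a_start, m.b_start))
    return out


# ---------------------------------------------------------------------------
# Built-in maximal exact match finder

def find_maximal_exact_matches(
    seq: str,
    min_len: int = DEFAULT_MIN_MATCH,
    include_inverted: bool = True,
) -> List[ExactMatch]:
    """All maximal repeated substring pairs of length >= ``min_len``.

    Direct and (optionally) inverted (reverse-complement) pairs are
    found on a suffix array of ``seq ⊕ revcomp(seq)``; maximality for an
    inverted pair means neither coordinated extension (right on one arm,
    left on the other) preserves the match. Ns never participate in a
    match. Palindromic pairs whose two intervals coincide are excluded.

    Results are canonicalized (``a_start < b_start``) and sorted longest
    first, matching what a show-coords parse of the same comparison
    yields.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    seq = seq.upper()
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"non-ACGTN characters in sequence: {sorted(bad)}")
    n = len(seq)
    if n < min_len:
        return []
    if include_inverted:
        codes, _ = _suffix.encode_with_revcomp(seq)
    else:
        codes = _suffix.encode(seq)
    sa = _suffix.suffix_array(codes)
    lcp = _suffix.lcp_kasai(codes, sa)
    pairs = _suffix.maximal_pairs(codes, sa, lcp, min_len)

    seen = set()
    out: List[ExactMatch] = []
    for p, q, length in pairs:
        if q < n:  # both in forward half: direct
            m = _canonical_match(p, p + length, q, q + length, "direct")
        elif p >= n:  # both in reverse half: mirror of a direct pair
            continue
        else:  # inverted
            if p + length > n:
                continue  # would span the separator (cannot happen)
            b_start = 2 * n + 1 - q - length
            m = _canonical_match(p, p + length, b_start, b_start + length, "inverted")
        if m is None or m.key() in seen:
            continue
        seen.add(m.key())
        out.append(m)
    out.sort(key=lambda m: (-m.length, m.a_start, m.b_start))
    return out


# ---------------------------------------------------------------------------
# Serialization

_TSV_HEADER = "query_id\tq_start\tq_end\tstrand\tdb_name\tsubject_id\ts_start\ts_end\tscore\tevidence"


def features_to_tsv(features: Iterable[HomologyFeature]) -> str:
    """Canonical internal tabular form (round-trips via features_from_tsv)."""
    lines = [_TSV_HEADER]
    for f in features:
        lines.append(
            f"{f.query_id}\t{f.q_start}\t{f.q_end}\t{f.strand}\t{f.db_name}\t"
            f"{f.subject_id}\t{f.s_start}\t{f.s_end}\t{f.score:g}\t{f.evidence}"
        )
    return "\n".join(lines) + "\n"


def features_from_tsv(stream: Stream) -> List[HomologyFeature]:
    fh, close = _open(stream)
    feats = []
    try:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith("query_id"):
                continue
            cols = line.split("\t")
            if len(cols) != 10:
                raise ParseError(f"line {lineno}: expected 10 columns")
            feats.append(
                HomologyFeature(
                    query_id=cols[0], q_start=int(cols[1]), q_end=int(cols[2]),
                    strand=cols[3], db_name=cols[4], subject_id=cols[5],
                    s_start=int(cols[6]), s_end=int(cols[7]),
                    score=float(cols[8]), evidence=cols[9],
                )
            )
    finally:
        if close:
            fh.close()
    return feats


def features_to_gff3(features: Iterable[HomologyFeature], source: str = "junctionscan") -> str:
    """Export features as GFF3 (1-based inclusive coordinates)."""
    lines = ["##gff-version 3"]
    for i, f in enumerate(sorted(features, key=lambda f: (f.query_id, f.q_start))):
        attrs = (
            f"ID=feat{i};db={f.db_name};subject={f.subject_id};"
            f"subject_start={f.s_start};subject_end={f.s_end}"
        )
        lines.append(
            f"{f.query_id}\t{source}\tmatch\t{f.q_start + 1}\t{f.q_end}\t"
            f"{f.score:g}\t{f.strand}\t.\t{attrs}"
        )
    return "\n".join(lines) + "\n"
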