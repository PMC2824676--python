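"""Repeat junctions, junction-pair markers, and LTR pair dating.

Every retroelement insertion creates two repeat junctions — boundaries
between the inserted element and its target — which are potentially
unique sequence even when both flanking repeats are high-copy. Two
junctions close enough together (default 2.5 kb) make a junction-pair
marker: a PCR amplicon across them is effectively single-copy.

The second half of this module identifies paired LTRs from exact-match
structure and dates them: the two LTRs of an element are identical at
insertion and diverge afterwards, so the Kimura 2-parameter distance
between them orders insertions from youngest (smallest distance, longest
surviving exact matches) to oldest.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from Bio import Align

from .competition import ClassifiedSegment, RepeatClass
from .homology import ExactMatch

DEFAULT_MAX_MARKER_SPAN = 2500  # nt between paired junctions
DEFAULT_JUNCTION_GAP_TOLERANCE = 50  # nt of unannotated sequence tolerated
DEFAULT_MIN_LTR_LEN = 300
DEFAULT_MIN_INTERNAL = 1000
DEFAULT_MAX_INTERNAL = 25000


@dataclass(frozen=True)
class Junction:
    """A class-change boundary between two adjacent annotated loci.

    ``position`` is the 1-based coordinate of the last nucleotide on the
    left side of the boundary (equivalently, the number of nucleotides
    preceding it).
    """

    query_id: str
    position: int
    left_class: RepeatClass
    right_class: RepeatClass
    left_segment: ClassifiedSegment
    right_segment: ClassifiedSegment
    gap_nt: int

    def __post_init__(self) -> None:
        if self.left_class.family == self.right_class.family:
            raise ValueError("a junction requires different families on each side")
        if self.gap_nt < 0:
            raise ValueError("gap_nt must be >= 0")


@dataclass(frozen=True)
class MarkerCandidate:
    """An ordered pair of nearby junctions usable as a single-copy marker."""

    junction_a: Junction
    junction_b: Junction

    @property
    def span_nt(self) -> int:
        return self.junction_b.position - self.junction_a.position


@dataclass
class LtrPair:
    """A putative retroelement: two directly repeated LTR intervals
    flanking an internal span, with K2P dating fields once computed."""

    left_ltr: Tuple[int, int]  # 0-based half-open
    right_ltr: Tuple[int, int]
    matched_nt: int  # summed exact-match length supporting the pair
    matches: Tuple[ExactMatch, ...]
    kappa: Optional[float] = None
    transitions_P: Optional[float] = None
    transversions_Q: Optional[float] = None

    @property
    def internal_span(self) -> Tuple[int, int]:
        return (self.left_ltr[1], self.right_ltr[0])

    @property
    def internal_length(self) -> int:
        return self.right_ltr[0] - self.left_ltr[1]

    @property
    def longest_match(self) -> int:
        return max(m.length for m in self.matches)


# ---------------------------------------------------------------------------
# Junction detection

def _merge_family_blocks(
    segments: Sequence[ClassifiedSegment], gap_tolerance: int
) -> List[Tuple[int, int, ClassifiedSegment]]:
    """Collapse runs of same-family segments (tandem stacks, LTR+CDS+LTR
    of one element) into blocks, keeping a representative segment whose
    class labels the block edge nearest a junction."""
    blocks: List[List] = []  # [start, end, first_seg, last_seg]
    for seg in sorted(segments, key=lambda s: (s.q_start, s.q_end)):
        if (
            blocks
            and seg.repeat_class.family == blocks[-1][3].repeat_class.family
            and seg.q_start - blocks[-1][1] <= gap_tolerance
        ):
            blocks[-1][1] = max(blocks[-1][1], seg.q_end)
            blocks[-1][3] = seg
        else:
            blocks.append([seg.q_start, seg.q_end, seg, seg])
    return blocks


def detect_junctions(
    segments: Sequence[ClassifiedSegment],
    gap_tolerance: int = DEFAULT_JUNCTION_GAP_TOLERANCE,
    query_id: str = "",
) -> List[Junction]:
    """One junction per adjacent pair of annotated loci from different
    element families, when the unannotated gap between them is at most
    ``gap_tolerance`` nt.

    Same-family segments (tandem stacks; the LTR/CDS/LTR parts of one
    element) are merged into blocks first, so only true class changes
    yield junctions. The junction position is the shared boundary when
    the blocks abut, otherwise the midpoint of the gap (or of the small
    allowed overlap).
    """
    if gap_tolerance < 0:
        raise ValueError("gap_tolerance must be >= 0")
    if not segments:
        return []
    qid = query_id or segments[0].feature.query_id
    blocks = _merge_family_blocks(segments, gap_tolerance)
    out: List[Junction] = []
    for (ls, le, lfirst, llast), (rs, re_, rfirst, rlast) in zip(blocks, blocks[1:]):
        gap = rs - le
        if gap > gap_tolerance:
            continue
        if llast.repeat_class.family == rfirst.repeat_class.family:
            continue
        position = (le + rs + 1) // 2  # == le when the blocks abut
        out.append(
            Junction(
                query_id=qid,
                position=position,
                left_class=llast.repeat_class,
                right_class=rfirst.repeat_class,
                left_segment=llast,
                right_segment=rfirst,
                gap_nt=max(0, gap),
            )
        )
    return out


def find_marker_candidates(
    junctions: Sequence[Junction],
    max_span: int = DEFAULT_MAX_MARKER_SPAN,
) -> List[MarkerCandidate]:
    """All junction pairs no more than ``max_span`` nt apart, each
    reported once, sorted by span ascending."""
    if max_span < 1:
        raise ValueError("max_span must be positive")
    ordered = sorted(junctions, key=lambda j: j.position)
    out: List[MarkerCandidate] = []
    for i, a in enumerate(ordered):
        for b in ordered[i + 1 :]:
            span = b.position - a.position
            if span > max_span:
                break
            if span > 0:
                out.append(MarkerCandidate(junction_a=a, junction_b=b))
    out.sort(key=lambda m: (m.span_nt, m.junction_a.position))
    return out


# ---------------------------------------------------------------------------
# LTR pair identification

def identify_ltr_pairs(
    matches: Sequence[ExactMatch],
    cds_segments: Optional[Sequence[ClassifiedSegment]] = None,
    *,
    min_ltr_len: int = DEFAULT_MIN_LTR_LEN,
    min_internal: int = DEFAULT_MIN_INTERNAL,
    max_internal: int = DEFAULT_MAX_INTERNAL,
    require_cds_overlap: bool = False,
    offset_tolerance: int = 30,
    max_fragment_gap: int = 500,
) -> List[LtrPair]:
    """Find putative paired LTRs among direct exact matches.

    Diverged LTR pairs appear not as one long exact match but as a chain
    of exact fragments sharing (nearly) the same offset between their
    two arms. Direct matches are therefore clustered by offset (within
    ``offset_tolerance``) and adjacency (fragment gaps up to
    ``max_fragment_gap``); a cluster qualifies when its summed matched
    length is at least ``min_ltr_len`` and the internal span between the
    two reconstructed arms lies in ``[min_internal, max_internal]``.
    Inverted matches never qualify. When ``require_cds_overlap`` is set,
    the internal span must additionally overlap a CDS-classified
    segment, which is how retroelements are separated from e.g. long
    satellite periodicities.
    """
    direct = [m for m in matches if m.orientation == "direct"]
    direct.sort(key=lambda m: (m.b_start - m.a_start, m.a_start))
    clusters: List[List[ExactMatch]] = []
    for m in direct:
        off = m.b_start - m.a_start
        if (
            clusters
            and off - (clusters[-1][-1].b_start - clusters[-1][-1].a_start)
            <= offset_tolerance
            and m.a_start - clusters[-1][-1].a_end <= max_fragment_gap
        ):
            clusters[-1].append(m)
        else:
            clusters.append([m])

    pairs: List[LtrPair] = []
    for cl in clusters:
        left = (min(m.a_start for m in cl), max(m.a_end for m in cl))
        right = (min(m.b_start for m in cl), max(m.b_end for m in cl))
        matched = sum(m.length for m in cl)
        if matched < min_ltr_len:
            continue
        internal = right[0] - left[1]
        if not (min_internal <= internal <= max_internal):
            continue
        if require_cds_overlap:
            if not cds_segments:
                continue
            span_s, span_e = left[1], right[0]
            hit = any(
                s.repeat_class.part.upper() == "CDS"
                and s.q_start < span_e
                and s.q_end > span_s
                for s in cds_segments
            )
            if not hit:
                continue
        pairs.append(
            LtrPair(
                left_ltr=left,
                right_ltr=right,
                matched_nt=matched,
                matches=tuple(cl),
            )
        )
    pairs.sort(key=lambda p: p.left_ltr)
    return pairs


# ---------------------------------------------------------------------------
# Kimura 2-parameter dating

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
_ACGT = set("ACGT")


class UndefinedDistanceError(ValueError):
    """K2P distance undefined: sequences too diverged (2P+Q >= 1 or Q >= 1/2)."""


def kimura2p(aligned_a: str, aligned_b: str) -> Tuple[float, float, float]:
    """Kimura 2-parameter distance from two equal-length gapped strings.

    Over ungapped, unambiguous (ACGT-only) columns, P is the transition
    proportion and Q the transversion proportion;

        kappa = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)

    Returns (kappa, P, Q). Columns containing gaps or ambiguity codes
    are excluded from the denominator.
    """
    if len(aligned_a) != len(aligned_b):
        raise ValueError("aligned sequences must have equal length")
    n = ts = tv = 0
    for x, y in zip(aligned_a.upper(), aligned_b.upper()):
        if x not in _ACGT or y not in _ACGT:
            continue
        n += 1
        if x != y:
            if (x, y) in _TRANSITIONS:
                ts += 1
            else:
                tv += 1
    if n == 0:
        raise ValueError("no ungapped, unambiguous columns to compare")
    P = ts / n
    Q = tv / n
    if 2 * P + Q >= 1 or 2 * Q >= 1:
        raise UndefinedDistanceError(
            f"K2P distance undefined for P={P:.3f}, Q={Q:.3f}"
        )
    kappa = -0.5 * math.log(1 - 2 * P - Q) - 0.25 * math.log(1 - 2 * Q)
    return kappa, P, Q


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -1
    return aligner


def align_ltrs(seq_a: str, seq_b: str) -> Tuple[str, str]:
    """Global alignment of the two LTR sequences (match +1, mismatch -1,
    gap open -5, gap extend -1), returned as gapped strings."""
    aligner = _make_aligner()
    aln = aligner.align(seq_a.upper(), seq_b.upper())[0]
    return str(aln[0]), str(aln[1])


def date_ltr_pair(query_seq: str, pair: LtrPair) -> LtrPair:
    """Fill in kappa/P/Q for one LTR pair by aligning its two arms."""
    a = query_seq[pair.left_ltr[0] : pair.left_ltr[1]]
    b = query_seq[pair.right_ltr[0] : pair.right_ltr[1]]
    ga, gb = align_ltrs(a, b)
    kappa, P, Q = kimura2p(ga, gb)
    pair.kappa = kappa
    pair.transitions_P = P
    pair.transversions_Q = Q
    return pair


def age_order(pairs: Sequence[LtrPair]) -> List[LtrPair]:
    """Youngest first: ascending kappa, ties broken by longer exact match
    first (longer surviving matches mean a younger element)."""
    undated = [p for p in pairs if p.kappa is None]
    if undated:
        raise ValueError("all LTR pairs must be dated before age ordering")
    return sorted(pairs, key=lambda p: (p.kappa, -p.longest_match))


# ---------------------------------------------------------------------------
# Exports

def junctions_to_bed(junctions: Sequence[Junction]) -> str:
    lines = []
    for i, j in enumerate(sorted(junctions, key=lambda j: j.position)):
        lines.append(
            f"{j.query_id}\t{j.position - 1}\t{j.position}\t"
            f"junction{i}:{j.left_class}|{j.right_class}"
        )
    return "\n".join(lines) + "\n" if lines else ""


def markers_to_tsv(markers: Sequence[MarkerCandidate]) -> str:
    lines = [
        "query_id\tjunction_a_pos\tjunction_b_pos\tspan_nt\t"
        "a_left_class\ta_right_class\tb_left_class\tb_right_class"
    ]
    for m in markers:
        a, b = m.junction_a, m.junction_b
        lines.append(
            f"{a.query_id}\t{a.position}\t{b.position}\t{m.span_nt}\t"
            f"{a.left_class}\t{a.right_class}\t{b.left_class}\t{b.right_class}"
        )
    return "\n".join(lines) + "\n"


def ltr_pairs_to_gff3(pairs: Sequence[LtrPair], query_id: str,
                      source: str = "junctionscan") -> str:
    lines = ["##gff-version 3"]
    for i, p in enumerate(pairs):
        kappa = f"{p.kappa:.4f}" if p.kappa is not None else "NA"
        lines.append(
            f"{query_id}\t{source}\tLTR_retrotransposon\t{p.left_ltr[0] + 1}\t"
            f"{p.right_ltr[1]}\t.\t+\t.\t"
            f"ID=ltrpair{i};kappa={kappa};matched_nt={p.matched_nt};"
            f"left_ltr={p.left_ltr[0] + 1}-{p.left_ltr[1]};"
            f"right_ltr={p.right_ltr[0] + 1}-{p.right_ltr[1]}"
        )
    return "\n".join(lines) + "\n"
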