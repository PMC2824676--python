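"""Annotation competition: one best-fitting repeat class per locus.

Repeat-rich sequence attracts stacks of overlapping homology evidence —
every CRM subfamily template aligns to every CRM element at some level.
Instead of drawing the stack, longer features eliminate shorter
overlapping ones, with two mode-specific rules:

* ``blast`` mode: only features from *different* databases compete;
  same-database features may overlap freely (so the many offset hits of
  a tandem satellite monomer all survive and the array stays visible).
* ``crossmatch`` mode: all features compete (longer contiguously masked
  segments are drawn over and eliminate shorter ones).

In both modes an overlap no larger than the configured allowance (in
nucleotides, per feature pair) is tolerated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, NamedTuple, Optional, Sequence, Tuple

from intervaltree import IntervalTree

from .homology import HomologyFeature


class RepeatClass(NamedTuple):
    """A repeat classification: element family plus part (LTR, CDS, ...).

    Two loci belong to the same element family when ``family`` matches;
    junction detection compares families, so the LTR/CDS seam inside one
    element is not mistaken for an insertion boundary.
    """

    family: str
    part: str = ""

    def __str__(self) -> str:
        return f"{self.family}/{self.part}" if self.part else self.family


OTHER_CLASS = RepeatClass("other", "")


@dataclass(frozen=True)
class CompetitionParams:
    allowance_nt: int = 0
    db_priority: Tuple[str, ...] = ()
    mode: str = "blast"  # 'blast' | 'crossmatch'

    def __post_init__(self) -> None:
        if self.allowance_nt < 0:
            raise ValueError("allowance must be >= 0")
        if self.mode not in ("blast", "crossmatch"):
            raise ValueError(f"mode must be blast or crossmatch, got {self.mode!r}")


@dataclass
class CompetedTrack:
    """Post-competition evidence for one query: every input feature is in
    exactly one of ``kept`` (sorted by q_start) or ``eliminated`` (with a
    reference to the feature that eliminated it)."""

    query_id: str
    kept: List[HomologyFeature]
    eliminated: List[Tuple[HomologyFeature, HomologyFeature]]
    params: CompetitionParams

    def validate(self) -> None:
        """Machine-check the overlap invariant among kept features."""
        for i, a in enumerate(self.kept):
            for b in self.kept[i + 1 :]:
                if b.q_start >= a.q_end:
                    break
                if self.params.mode == "crossmatch" or a.db_name != b.db_name:
                    ov = a.overlap_nt(b)
                    if ov > self.params.allowance_nt:
                        raise AssertionError(
                            f"kept features overlap by {ov} nt > allowance "
                            f"{self.params.allowance_nt}: {a} / {b}"
                        )


def competition_rank(params: CompetitionParams):
    """Sort key implementing 'longer eliminates shorter', with
    deterministic tie-breaks: length desc, score desc, db priority,
    q_start asc, subject id."""
    prio = {db: i for i, db in enumerate(params.db_priority)}

    def key(f: HomologyFeature):
        return (
            -f.length,
            -f.score,
            prio.get(f.db_name, len(prio)),
            f.q_start,
            f.subject_id,
        )

    return key


def compete(
    features: Sequence[HomologyFeature], params: CompetitionParams
) -> CompetedTrack:
    """Greedy ranked sweep: walk candidates from longest to shortest and
    keep each one unless it overlaps an already-kept *competing* feature
    by more than the allowance. Competing means a different database in
    blast mode, any feature in crossmatch mode. Elimination removes the
    whole feature (no trimming). Deterministic for a fixed input set.
    """
    if not features:
        return CompetedTrack("", [], [], params)
    qids = {f.query_id for f in features}
    if len(qids) > 1:
        raise ValueError(f"compete() requires a single query id, got {sorted(qids)}")
    query_id = next(iter(qids))

    ranked = sorted(features, key=competition_rank(params))
    tree = IntervalTree()
    kept: List[HomologyFeature] = []
    eliminated: List[Tuple[HomologyFeature, HomologyFeature]] = []
    for cand in ranked:
        eliminator: Optional[HomologyFeature] = None
        best_ov = params.allowance_nt
        for iv in tree.overlap(cand.q_start, cand.q_end):
            other: HomologyFeature = iv.data
            if params.mode == "blast" and other.db_name == cand.db_name:
                continue
            ov = cand.overlap_nt(other)
            if ov > best_ov:
                best_ov = ov
                eliminator = other
        if eliminator is None:
            kept.append(cand)
            tree.addi(cand.q_start, cand.q_end, cand)
        else:
            eliminated.append((cand, eliminator))
    kept.sort(key=lambda f: (f.q_start, f.q_end, f.db_name, f.subject_id))
    return CompetedTrack(query_id, kept, eliminated, params)


@dataclass(frozen=True)
class ClassifiedSegment:
    """A kept feature annotated with its repeat class."""

    feature: HomologyFeature
    repeat_class: RepeatClass

    @property
    def q_start(self) -> int:
        return self.feature.q_start

    @property
    def q_end(self) -> int:
        return self.feature.q_end


def classify_repeat_locus(
    track: CompetedTrack,
    class_map: Dict[str, RepeatClass],
    subrange_map: Optional[Sequence[Tuple[str, int, int, RepeatClass]]] = None,
) -> List[ClassifiedSegment]:
    """Attach a repeat class to every kept feature.

    ``class_map`` maps subject ids to classes. ``subrange_map`` entries
    ``(subject_id, s_start, s_end, class)`` override by subject
    coordinates (midpoint rule), mirroring per-sub-range display colors
    — this is how a hit inside the LTR portion of a full-length element
    template gets classified as that subfamily's LTR. Unknown subjects
    become class ``other``.
    """
    out = []
    for f in track.kept:
        cls = None
        if subrange_map:
            mid = (f.s_start + f.s_end) // 2
            for subj, s, e, c in subrange_map:
                if subj == f.subject_id and s <= mid <= e:
                    cls = c
                    break
        if cls is None:
            cls = class_map.get(f.subject_id, OTHER_CLASS)
        out.append(ClassifiedSegment(feature=f, repeat_class=cls))
    out.sort(key=lambda s: (s.q_start, s.q_end))
    return out


def default_class_map(subject_ids: Sequence[str]) -> Dict[str, RepeatClass]:
    """Derive classes from ``family_part`` subject naming (e.g.
    ``CRM2_LTR`` -> (CRM2, LTR)); ids without an underscore map to a
    family with no part."""
    cmap = {}
    for sid in subject_ids:
        if "_" in sid:
            family, part = sid.rsplit("_", 1)
            cmap[sid] = RepeatClass(family, part)
        else:
            cmap[sid] = RepeatClass(sid)
    return cmap


def elimination_audit_tsv(track: CompetedTrack) -> str:
    """TSV audit log of eliminations (who was removed, and by what)."""
    lines = ["eliminated_db\teliminated_subject\teliminated_start\teliminated_end\t"
             "eliminator_db\teliminator_subject\teliminator_start\teliminator_end\toverlap_nt"]
    for victim, eliminator in track.eliminated:
        lines.append(
            f"{victim.db_name}\t{victim.subject_id}\t{victim.q_start + 1}\t{victim.q_end}\t"
            f"{eliminator.db_name}\t{eliminator.subject_id}\t"
            f"{eliminator.q_start + 1}\t{eliminator.q_end}\t{victim.overlap_nt(eliminator)}"
        )
    return "\n".join(lines) + "\n"
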