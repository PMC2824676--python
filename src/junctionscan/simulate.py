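"""Synthetic centromere simulator with full ground truth.

Builds centromere-like sequence the way maize centromeres are organized:
a tandem satellite array (CentC-like), retroelement families with LTRs
flanking a CDS-bearing internal region (CRM-like, plus a non-centromeric
family), and nested insertions of elements into the satellite and into
each other. Every insertion is logged — element interval, the two
repeat junctions it creates, its LTR intervals and divergence — and the
log is kept consistent through all later insertions, so every pipeline
stage can be tested against exact ground truth with no downloads.

Evidence emission writes the same file formats the pipeline consumes
from real aligners (BLAST tabular per database, cross_match lines, read
placements), with exact coordinates at noise 0.

All randomness flows from one seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .charts import ReadPlacement, placements_to_tsv
from .competition import RepeatClass

_BASES = np.array(list("ACGT"))

DEFAULT_MONOMER_LEN = 156  # CentC-scale satellite monomer


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def random_sequence(length: int, rng) -> str:
    rng = _rng(rng)
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def mutate(seq: str, rate: float, rng) -> str:
    """Substitute each position independently with probability ``rate``,
    always to a different base (Ns are left untouched)."""
    if not (0 <= rate <= 1):
        raise ValueError("mutation rate must be in [0, 1]")
    if rate == 0:
        return seq
    rng = _rng(rng)
    arr = np.array(list(seq))
    hit = rng.random(len(arr)) < rate
    hit &= arr != "N"
    idx = np.flatnonzero(hit)
    for i in idx:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return "".join(arr)


@dataclass(frozen=True)
class ElementTemplate:
    """A retroelement family: LTR and internal (CDS-bearing) sequence."""

    family: str
    ltr: str
    internal: str

    def __post_init__(self) -> None:
        if len(self.ltr) < 100:
            raise ValueError("LTR template must be >= 100 nt")

    @property
    def length(self) -> int:
        return 2 * len(self.ltr) + len(self.internal)


def make_element_template(family: str, ltr_len: int, internal_len: int, rng) -> ElementTemplate:
    rng = _rng(rng)
    return ElementTemplate(
        family=family,
        ltr=random_sequence(ltr_len, rng),
        internal=random_sequence(internal_len, rng),
    )


def derive_subfamily(
    parent: ElementTemplate, family: str, divergence: float, rng
) -> ElementTemplate:
    """A subfamily variant: the parent mutated at the given rate
    (emulating parental variants that are ~80% identical at 0.2)."""
    if not (0 <= divergence <= 0.3):
        raise ValueError("subfamily divergence must be in [0, 0.3]")
    rng = _rng(rng)
    return ElementTemplate(
        family=family,
        ltr=mutate(parent.ltr, divergence, rng),
        internal=mutate(parent.internal, divergence, rng),
    )


def make_satellite_array(
    monomer_len: int = DEFAULT_MONOMER_LEN,
    copies: int = 10,
    divergence: float = 0.0,
    rng=0,
    monomer: Optional[str] = None,
) -> Tuple[str, str, List[int]]:
    """Head-to-tail monomer copies, each independently mutated at
    ``divergence``. Returns (array sequence, monomer, copy start offsets).
    """
    if copies < 1:
        raise ValueError("copies must be >= 1")
    rng = _rng(rng)
    if monomer is None:
        monomer = random_sequence(monomer_len, rng)
    parts, starts, off = [], [], 0
    for _ in range(copies):
        parts.append(mutate(monomer, divergence, rng))
        starts.append(off)
        off += len(monomer)
    return "".join(parts), monomer, starts


# ---------------------------------------------------------------------------
# Ground-truth bookkeeping

@dataclass
class Segment:
    """A surface segment: a visible stretch of one annotation class."""

    start: int  # 0-based half-open on the genome
    end: int
    family: str
    part: str  # 'LTR' | 'CDS' | 'sat'
    subject_id: str
    s_start: int  # 1-based inclusive within the subject
    s_end: int

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def repeat_class(self) -> RepeatClass:
        return RepeatClass(self.family, self.part)


@dataclass
class InsertionRecord:
    """One logged insertion and everything it created."""

    element_id: str
    family: str
    order_index: int  # 1-based insertion order (1 = oldest)
    start: int  # current element interval, 0-based half-open
    end: int
    ltr5: Tuple[int, int]
    ltr3: Tuple[int, int]
    junction_left: int  # boundary offsets (nt preceding the boundary)
    junction_right: int
    ltr_divergence: float
    target_family: str
    element_seq: str  # kept consistent through nested insertions


@dataclass
class GroundTruth:
    insertions: List[InsertionRecord] = field(default_factory=list)
    satellite: Optional[Tuple[int, int]] = None
    monomer: str = ""
    gap_runs: List[Tuple[int, int]] = field(default_factory=list)  # (start, length)

    @property
    def junction_positions(self) -> List[int]:
        out = []
        for rec in self.insertions:
            out.extend((rec.junction_left, rec.junction_right))
        return sorted(out)


@dataclass
class SimulatedGenome:
    seq: str
    segments: List[Segment]
    truth: GroundTruth
    templates: Dict[str, ElementTemplate] = field(default_factory=dict)

    @property
    def length(self) -> int:
        return len(self.seq)

    def check_consistency(self) -> None:
        """Logged coordinates must reproduce logged sequences exactly."""
        for rec in self.truth.insertions:
            if self.seq[rec.start : rec.end] != rec.element_seq:
                raise AssertionError(
                    f"{rec.element_id}: logged interval does not reproduce "
                    "the logged element sequence"
                )
        for seg in self.segments:
            if not (0 <= seg.start < seg.end <= len(self.seq)):
                raise AssertionError(f"segment out of bounds: {seg}")


def _shift(v: int, at: int, by: int) -> int:
    return v + by if v >= at else v


def insert_element(
    genome: SimulatedGenome,
    template: ElementTemplate,
    position: int,
    ltr_divergence: float = 0.0,
    rng=0,
) -> InsertionRecord:
    """Insert LTR–internal–LTR at ``position`` (0-based offset).

    The two LTRs are independently mutated at ``ltr_divergence / 2``
    each, so their pairwise divergence is approximately
    ``ltr_divergence`` — emulating post-insertion divergence used for
    dating. All prior ground truth (segments, element intervals, LTR
    intervals, junctions, satellite, gaps) is shifted; a segment or
    element containing the position is split/extended; the two new
    junctions are logged. No target-site duplication is modeled.
    """
    rng = _rng(rng)
    if not (0 <= position <= len(genome.seq)):
        raise IndexError(f"insertion position {position} outside genome")
    ltr5 = mutate(template.ltr, ltr_divergence / 2, rng)
    ltr3 = mutate(template.ltr, ltr_divergence / 2, rng)
    elem = ltr5 + template.internal + ltr3
    L = len(elem)
    llen, ilen = len(template.ltr), len(template.internal)

    target_family = ""
    new_segments: List[Segment] = []
    for seg in genome.segments:
        if seg.end <= position:
            new_segments.append(seg)
        elif seg.start >= position:
            new_segments.append(
                Segment(seg.start + L, seg.end + L, seg.family, seg.part,
                        seg.subject_id, seg.s_start, seg.s_end)
            )
        else:  # split
            target_family = seg.family
            off = position - seg.start
            new_segments.append(
                Segment(seg.start, position, seg.family, seg.part,
                        seg.subject_id, seg.s_start, seg.s_start + off - 1)
            )
            new_segments.append(
                Segment(position + L, seg.end + L, seg.family, seg.part,
                        seg.subject_id, seg.s_start + off, seg.s_end)
            )
    fam = template.family
    new_segments.extend([
        Segment(position, position + llen, fam, "LTR", f"{fam}_LTR", 1, llen),
        Segment(position + llen, position + llen + ilen, fam, "CDS",
                f"{fam}_CDS", 1, ilen),
        Segment(position + llen + ilen, position + L, fam, "LTR",
                f"{fam}_LTR", 1, llen),
    ])
    new_segments.sort(key=lambda s: s.start)
    genome.segments = new_segments

    for rec in genome.truth.insertions:
        if rec.start < position < rec.end:  # nested inside this element
            off = position - rec.start
            rec.element_seq = rec.element_seq[:off] + elem + rec.element_seq[off:]
            rec.end += L
        else:
            rec.start = _shift(rec.start, position, L)
            rec.end = _shift(rec.end, position, L)
        rec.ltr5 = tuple(_shift(v, position, L) for v in rec.ltr5)
        rec.ltr3 = tuple(_shift(v, position, L) for v in rec.ltr3)
        rec.junction_left = _shift(rec.junction_left, position, L)
        rec.junction_right = _shift(rec.junction_right, position, L)
    if genome.truth.satellite:
        s, e = genome.truth.satellite
        if s < position < e:
            genome.truth.satellite = (s, e + L)
        else:
            genome.truth.satellite = (_shift(s, position, L), _shift(e, position, L))
    genome.truth.gap_runs = [
        (_shift(s, position, L), ln) for s, ln in genome.truth.gap_runs
    ]

    order = len(genome.truth.insertions) + 1
    rec = InsertionRecord(
        element_id=f"{fam}.{order}",
        family=fam,
        order_index=order,
        start=position,
        end=position + L,
        ltr5=(position, position + llen),
        ltr3=(position + llen + ilen, position + L),
        junction_left=position,
        junction_right=position + L,
        ltr_divergence=ltr_divergence,
        target_family=target_family,
        element_seq=elem,
    )
    genome.truth.insertions.append(rec)
    genome.seq = genome.seq[:position] + elem + genome.seq[position:]
    genome.templates.setdefault(fam, template)
    return rec


def add_gap_run(genome: SimulatedGenome, start: int, length: int) -> None:
    """Overwrite an unannotated stretch with Ns (an assembly gap)."""
    end = start + length
    if not (0 <= start < end <= len(genome.seq)):
        raise IndexError("gap run outside genome")
    for seg in genome.segments:
        if seg.start < end and seg.end > start:
            raise ValueError("gap run would overwrite an annotated segment")
    genome.seq = genome.seq[:start] + "N" * length + genome.seq[end:]
    genome.truth.gap_runs.append((start, length))


def new_genome_with_satellite(
    rng=0,
    monomer_len: int = DEFAULT_MONOMER_LEN,
    copies: int = 100,
    divergence: float = 0.05,
    flank_len: int = 10_000,
) -> SimulatedGenome:
    """Unannotated flanks around one satellite array segment."""
    rng = _rng(rng)
    left = random_sequence(flank_len, rng)
    array, monomer, _ = make_satellite_array(monomer_len, copies, divergence, rng)
    right = random_sequence(flank_len, rng)
    sat_start, sat_end = len(left), len(left) + len(array)
    truth = GroundTruth(satellite=(sat_start, sat_end), monomer=monomer)
    segments = [
        Segment(sat_start, sat_end, "CentC", "sat", "CentC_sat", 1, len(array))
    ]
    return SimulatedGenome(seq=left + array + right, segments=segments, truth=truth)


_DEFAULT_FAMILIES = (
    # (family, ltr_len, internal_len) — LTR/element sizes bracketing CRM-like
    # retroelements plus one larger non-centromeric family
    ("CRM1", 1450, 5200),
    ("CRM2", 1300, 4800),
    ("CRM3", 1100, 4400),
    ("CentA", 900, 3800),
    ("RireX", 1600, 5600),
)


def simulate_centromere(
    seed: int = 0,
    n_insertions: int = 20,
    satellite_copies: int = 2000,
    monomer_len: int = DEFAULT_MONOMER_LEN,
    satellite_divergence: float = 0.05,
    flank_len: int = 20_000,
    families: Sequence[Tuple[str, int, int]] = _DEFAULT_FAMILIES,
    ltr_divergence_range: Tuple[float, float] = (0.0, 0.03),
    margin: int = 300,
    with_gaps: bool = True,
) -> SimulatedGenome:
    """A nested-insertion centromere scenario with ~0.5 Mb defaults.

    Starts from a diverged satellite array, then inserts ``n_insertions``
    elements at interior points of already-annotated segments (satellite
    or earlier elements), always choosing an element family different
    from the target segment's family — so every insertion creates two
    detectable class-change junctions, and both logged junctions of every
    insertion survive all later ones (interior points keep a ``margin``
    of the split segment on each side). Optionally overwrites one
    1,000-N and one 100-N gap run in the flanks.
    """
    rng = np.random.default_rng(seed)
    genome = new_genome_with_satellite(
        rng, monomer_len=monomer_len, copies=satellite_copies,
        divergence=satellite_divergence, flank_len=flank_len,
    )
    templates = {
        fam: make_element_template(fam, ltr_len, int_len, rng)
        for fam, ltr_len, int_len in families
    }
    genome.templates.update(templates)
    for _ in range(n_insertions):
        candidates = [
            s for s in genome.segments if s.length >= 2 * margin + 2
        ]
        if not candidates:
            raise RuntimeError("no segment large enough to accept an insertion")
        seg = candidates[rng.integers(0, len(candidates))]
        fams = [f for f in templates if f != seg.family]
        fam = fams[rng.integers(0, len(fams))]
        position = int(rng.integers(seg.start + margin, seg.end - margin))
        div = float(rng.uniform(*ltr_divergence_range))
        insert_element(genome, templates[fam], position, div, rng)
    if with_gaps and flank_len >= 5000:
        add_gap_run(genome, 2000, 1000)
        add_gap_run(genome, len(genome.seq) - 3000, 100)
    genome.check_consistency()
    return genome


# ---------------------------------------------------------------------------
# Evidence emission

@dataclass
class EvidenceBundle:
    """Synthetic aligner output mirroring what the pipeline parses."""

    query_id: str
    blast_by_db: Dict[str, str]  # db_name -> BLAST tabular text
    crossmatch_text: str
    placements_text: str
    class_map: Dict[str, RepeatClass]
    db_priority: Tuple[str, ...]


def emit_evidence(
    genome: SimulatedGenome,
    query_id: str = "sim",
    noise: int = 0,
    n_decoys: int = 0,
    n_reads: int = 0,
    read_len: int = 120,
    enriched: Optional[Tuple[int, int]] = None,
    excluded: Optional[Tuple[int, int]] = None,
    rng=0,
) -> EvidenceBundle:
    """One HSP (and one cross_match line) per surface segment.

    At ``noise`` 0 coordinates are exact; otherwise both ends are
    jittered by up to ``noise`` nt. ``n_decoys`` short HSPs from a
    separate decoy database are placed inside long true segments, where
    inter-database competition must eliminate them. Read placements are
    sampled uniformly; foreground-category reads (low multiplicity) come
    from the ``enriched`` interval minus ``excluded`` (a CENH3-depleted
    hole), background reads from anywhere.
    """
    rng = _rng(rng)
    blast_rows: Dict[str, List[str]] = {}
    cm_lines: List[str] = []
    glen = len(genome.seq)

    def jitter(s: int, e: int) -> Tuple[int, int]:
        if noise <= 0:
            return s, e
        s2 = max(0, s + int(rng.integers(-noise, noise + 1)))
        e2 = min(glen, e + int(rng.integers(-noise, noise + 1)))
        return (s2, e2) if e2 - s2 >= 10 else (s, e)

    for seg in genome.segments:
        qs, qe = jitter(seg.start, seg.end)
        db = f"{seg.family}db"
        length = qe - qs
        row = (
            f"{query_id}\t{seg.subject_id}\t100.00\t{length}\t0\t0\t"
            f"{qs + 1}\t{qe}\t{seg.s_start}\t{seg.s_end}\t0.0\t{2 * length}"
        )
        blast_rows.setdefault(db, []).append(row)
        cm_lines.append(
            f"{length} 0.00 0.00 0.00  {query_id} {qs + 1} {qe} ({glen - qe})  "
            f"{seg.subject_id} {seg.s_start} {seg.s_end} (0)"
        )

    decoy_db = "decoydb"
    hosts = [s for s in genome.segments if s.length >= 400]
    for i in range(n_decoys):
        if not hosts:
            break
        seg = hosts[rng.integers(0, len(hosts))]
        dlen = 120
        ds = int(rng.integers(seg.start, seg.end - dlen))
        row = (
            f"{query_id}\tdecoy_rep\t95.00\t{dlen}\t6\t0\t"
            f"{ds + 1}\t{ds + dlen}\t1\t{dlen}\t1e-30\t{dlen}"
        )
        blast_rows.setdefault(decoy_db, []).append(row)

    placements: List[ReadPlacement] = []
    if n_reads:
        lo, hi = enriched if enriched else (0, glen)
        hi = min(hi, glen)
        for i in range(n_reads):
            cat = rng.random()
            if cat < 0.5:
                hq, hg = 1, 1
                s = _sample_start(rng, lo, hi - read_len, excluded, read_len)
            elif cat < 0.75:
                hq, hg = 1, 2
                s = _sample_start(rng, lo, hi - read_len, excluded, read_len)
            else:
                hq, hg = 3, 12
                s = int(rng.integers(0, glen - read_len))
            placements.append(
                ReadPlacement(
                    read_id=f"read{i}", query_id=query_id,
                    q_start=s, q_end=s + read_len,
                    hits_in_query=hq, hits_in_genome=hg,
                )
            )

    subjects = sorted({s.subject_id for s in genome.segments} | {"decoy_rep"})
    class_map = {}
    for sid in subjects:
        fam, part = sid.rsplit("_", 1)
        class_map[sid] = RepeatClass(fam, part)
    db_priority = tuple(sorted(blast_rows))
    return EvidenceBundle(
        query_id=query_id,
        blast_by_db={db: "\n".join(rows) + "\n" for db, rows in blast_rows.items()},
        crossmatch_text="\n".join(cm_lines) + "\n" if cm_lines else "",
        placements_text=placements_to_tsv(placements),
        class_map=class_map,
        db_priority=db_priority,
    )


def _sample_start(rng, lo: int, hi: int, excluded: Optional[Tuple[int, int]],
                  read_len: int) -> int:
    for _ in range(1000):
        s = int(rng.integers(lo, max(lo + 1, hi)))
        if excluded and s < excluded[1] and s + read_len > excluded[0]:
            continue
        return s
    raise RuntimeError("could not sample a read outside the excluded interval")


def truth_to_gff3(genome: SimulatedGenome, query_id: str = "sim") -> str:
    """Ground truth as GFF3: elements, their junctions, the satellite."""
    t = genome.truth
    lines = ["##gff-version 3"]
    if t.satellite:
        s, e = t.satellite
        lines.append(
            f"{query_id}\tsimulate\tsatellite_DNA\t{s + 1}\t{e}\t.\t+\t.\tID=satellite"
        )
    for rec in t.insertions:
        lines.append(
            f"{query_id}\tsimulate\tmobile_genetic_element\t{rec.start + 1}\t"
            f"{rec.end}\t.\t+\t.\tID={rec.element_id};family={rec.family};"
            f"order={rec.order_index};ltr_divergence={rec.ltr_divergence:.4f}"
        )
        for tag, pos in (("left", rec.junction_left), ("right", rec.junction_right)):
            lines.append(
                f"{query_id}\tsimulate\tjunction\t{pos}\t{pos}\t.\t+\t.\t"
                f"ID={rec.element_id}.{tag};parent={rec.element_id}"
            )
    return "\n".join(lines) + "\n"
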