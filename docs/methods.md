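# Methods

## Problem setting

Centromere-scale repeat regions are mosaics of a tandem satellite and
several families of LTR retroelements that insert into the satellite and
into each other. Because the repeat copies are highly similar, homology
searches against family templates return deep stacks of overlapping
hits; the scientific questions (which family occupies this locus? where
are the insertion boundaries? how old is each insertion?) require
reducing that stack to one best-fitting annotation per locus and then
reading structure off the reduced track. `junctionscan` implements that
reduction (competition), the downstream junction/marker and LTR-dating
analyses, and a deterministic renderer, with a ground-truthed simulator
standing in for real genome data in all tests.

## Coordinates

Internal coordinates are 0-based half-open everywhere. User-facing
coordinates (ruler labels, GFF3, reports, drawn labels) are 1-based
inclusive; BED and bedGraph exports are 0-based half-open as those
formats require. A junction `position` is the 1-based coordinate of the
last nucleotide left of the boundary (equivalently the count of
preceding nucleotides), which makes the gap-0 case exact and testable.

## Gaps and tiling

A maximal run of ≥ `gap_run_threshold` (default 100) consecutive Ns is
an assembly gap. It is drawn as one grey bar per complete 100-N block
(`floor(run/100)`, minimum one bar when a sub-100 threshold is
configured): a 1,000-N reference gap is a ten-bar stack, a 100-N gap a
single bar. The two printed cases are also consistent with "one bar per
gap, scaled"; the floor rule was adopted because it matches both and
degrades gracefully for intermediate run lengths. Each 1 kb ruler tick
carries a secondary value: the distance to the end of the nearest gap at
or before it (the position itself if none; 0 inside a gap — ticks are
never meaningfully placed inside gaps, so the value is pinned rather
than negative).

Long queries are tiled into `tile_window` (default 210,000 nt) windows
advancing by window − overlap, with `tile_overlap` = 10,000 nt, so any
feature no longer than the overlap (an LTR, say) is drawn complete in at
least one window; the last window is truncated at the sequence end.

## Evidence and competition

Parsers accept 12-column BLAST tabular output (strand from subject
coordinate order), cross_match alignment lines (complement `C` layout
supported), and show-coords-style exact-match tables. The WU-BLAST
score-equivalence policy S is re-expressed as a post-parse filter: keep
HSPs scoring at least `fraction × subject_length × match_reward`, i.e. a
fraction of a perfect complete match to the subject (0.9 separates
closely related subfamilies such as two CRM LTR types). External
aligners are never required: pre-computed files plus the built-in exact
matcher give full function.

Competition is a greedy ranked sweep. Candidates are ordered by length
descending — "longer eliminates shorter" — with ties broken by score,
database priority rank, query start and subject id so the outcome is
deterministic and independent of input order. A candidate is kept iff
its overlap with every already-kept *competing* feature is within
`allowance` nt (competing = different database in blast mode; any
feature in crossmatch mode; same-database BLAST hits never compete, so
tandem-repeat hit stacks survive). Elimination removes the whole feature
— no trimming — and records the eliminating feature for the audit log.
The kept set provably satisfies the pairwise overlap invariant, and the
implementation re-checks it (`CompetedTrack.validate`). BLAST and
cross_match evidence are competed separately and drawn as separate
panels. One caveat documented here because it is easy to assume
otherwise: the *number* of kept features is not globally monotone in the
allowance — raising it can revive a mid-rank feature that then
eliminates two smaller ones. The pairwise case is monotone, and that is
what the test suite asserts.

Classification maps subject ids to `(family, part)` classes, with
optional subject-coordinate sub-range overrides (midpoint rule) so a hit
inside the LTR portion of a full-length template classifies as that
family's LTR — mirroring per-sub-range display colors.

## Junctions and markers

Adjacent kept features are first merged into same-family blocks
(tolerating gaps up to `gap_tolerance`, default 50 nt — enough to absorb
deliberately unannotated UTR stubs between an LTR and a CDS). A junction
is called between consecutive blocks of *different families* whose gap
is at most the tolerance; the LTR/CDS seam inside one element is not an
insertion boundary and never yields a junction. Junction position is the
shared boundary when blocks abut, otherwise the midpoint of the gap (or
of a small allowed overlap). Marker candidates are all junction pairs
with 0 < span ≤ `max_span` (default 2,500 nt), reported once, sorted by
span, with both flanking feature identities attached for downstream
primer design (out of scope here).

## Exact matches

`find_maximal_exact_matches` returns every maximal repeated substring
pair of length ≥ `min_len` (default 100), direct and inverted. It builds
a suffix array (numpy prefix-doubling, O(n log n)) over the integer-
coded concatenation `seq ⊕ revcomp(seq)`, computes the LCP array
(Kasai), and enumerates maximal pairs by a bottom-up traversal of the
LCP-interval structure: a pair is emitted at depth d exactly when the
two suffixes first co-occur in an interval of depth d (right-maximal)
and their preceding characters differ (left-maximal). Every N and the
separator get unique integer codes, so matches never include or span Ns.
Pairs with both members in the reverse half are mirrors and are skipped;
mixed pairs map back to inverted repeats, for which maximality means no
coordinated extension (right on one arm, left on the other) preserves
the match. Palindromic pairs whose two intervals coincide are excluded.
Sequences of at least 10 Mb are supported; the enumeration is
output-sensitive, so a perfect tandem array of c copies legitimately
yields O(c²) pairs.

## LTR pairs and K2P dating

A diverged LTR pair appears not as one long exact match but as a chain
of exact fragments whose two arms share a nearly constant offset.
Candidate pairs are therefore built by clustering direct matches on
(offset within `offset_tolerance`, default 30 nt; fragment gaps up to
`max_fragment_gap`, default 500 nt) and accepting clusters with summed
matched length ≥ `min_ltr_len` (default 300 nt) and an internal span in
[`min_internal`, `max_internal`] = [1, 25] kb — ranges bracketing known
LTR elements. Short periodic satellite matches fail the length test, and
long-range array self-matches fail the internal-span test; requiring CDS
overlap of the internal span is available as an additional filter.
Inverted matches never qualify.

Dating aligns the two reconstructed arms globally (match +1, mismatch
−1, gap open −5, gap extend −1; arms from substitution-only simulations
align trivially, and the penalties keep real small indels from
fragmenting the alignment) and computes the Kimura 2-parameter distance
over ungapped, unambiguous columns: P = transition proportion, Q =
transversion proportion, κ = −½·ln(1−2P−Q) − ¼·ln(1−2Q), undefined when
2P+Q ≥ 1 or Q ≥ ½ (an explicit error). Age ordering is ascending κ,
ties broken by longer exact-match support first (longer surviving
matches mean younger). Converting κ to years needs a mutation rate and
is out of scope.

## Coverage charts

Placements are (interval, hits-in-query, hits-in-genome) records; a
chart value is the count of passing placements covering each nucleotide
(difference-array accumulation). Three standard multiplicity filters —
unique (1 in query, ≤ 2 genome-wide: a sequence shared by two
overlapping clones is still effectively unique), near-unique (≤ 2
genome-wide), unrestricted — are nested, so values are pointwise
monotone across them; generalized (hits_in_query, hits_in_genome)
thresholds express both clone-set and whole-chromosome configurations.
Charts belong to a foreground or background set; each set's y-axis
extends automatically to its largest member value, and the background
set is drawn first so abundant multi-mapping coverage underlays the
specific signal.

## Rendering

The `DisplayModel` fully determines a figure; both serializers are
deterministic (no timestamps), so identical models render byte-
identically. SVG is the primary, testable serialization (machine-
readable `class`/`data-*` attributes; tests parse it); PostScript
Level 2 mirrors the geometry for print-scale output. Panel order top to
bottom: ruler, charts, cross_match masks, BLAST arrows (same-database
stacked overlaps drawn shorter-over-longer), exact-match lines. Match
lines take up to `max_levels` (default 30) levels: longest first on the
top level, each match on the highest level where its full extent (both
arms plus the dashed connector) collides with nothing; matches that fit
nowhere are dropped and logged. Direct matches are red, inverted blue;
arms solid, connector dashed. Glyph geometry (arrowhead proportions,
font sizes, panel heights) is fixed by constants in `render.py`; the
horizontal scale is `nt_per_pixel` (default 50).

## Simulator

The generator emulates the organization the pipeline targets: a
satellite array (156 nt monomer by default — a CentC-scale choice,
configurable) of independently mutated copies; element families with a
random LTR and CDS-bearing internal sequence (subfamily variants derived
by mutation, e.g. 0.2 divergence ≈ the ~80% identity of parental
variants); and nested insertions of LTR–internal–LTR at interior points
of annotated segments, each logged with its interval, its two junctions,
its LTR intervals and its LTR divergence. The two LTRs are mutated
independently at half the nominal divergence each, so their pairwise
divergence has binomial expectation ≈ the nominal value — the basis of
the dating-recovery tests. All bookkeeping (segments, earlier elements'
intervals and stored sequences, junctions, satellite, gap runs) is kept
exact through later insertions and re-checked against the emitted
sequence. The default scenario inserts elements of a family different
from the target segment's family at points leaving ≥ 300 nt of the
split segment on each side, so every insertion creates two detectable
junctions that survive the whole history; the ~0.5 Mb default (2,000
satellite copies, 20 insertions, 20 kb unannotated flanks carrying a
1,000-N and a 100-N gap) is the size used in the end-to-end tests —
large enough for dozens of nested junctions while keeping the suite
fast. Evidence emission writes one exact HSP and one cross_match line
per surface segment (optionally jittered; optional short decoy HSPs
that competition must eliminate) and multiplicity-stratified read
placements, with low-multiplicity reads drawn from an enrichment
interval minus an optional excluded hole (a CENH3-depleted region).

What the simulator does *not* model — and hence what passing tests do
not show about real data: target-site duplications, indels and
rearrangements (mutations are substitutions only, which is why LTR-pair
arm offsets are exactly constant), solo-LTR recombination products,
recombinant subfamily mosaics, sequencing error in reads, and alignment
ambiguity (emitted evidence is one clean HSP per segment, whereas real
aligners fragment and overlap). Competition, junction logic, dating and
rendering are exercised exactly; robustness to messy real alignments is
only partially covered by the jitter and decoy options.

## Numerical and design choices

* Defaults: allowance 0 nt; gap threshold 100; tiling 210,000/10,000;
  min exact match 100; 30 levels; marker span 2,500; junction gap
  tolerance 50. All overridable in the six-section parameters file,
  whose dialect (`[section]` headers, `key = value`, `#` comments) is
  this package's own human-editable format; `write_template` emits a
  fully commented template that re-parses cleanly.
* Tie-breaks everywhere are total and documented (competition rank;
  level layout longest-first then leftmost; age order κ then match
  length), so every pipeline stage is deterministic and re-runs are
  byte-identical.
* Degenerate inputs: empty evidence renders a ruler-only figure; empty
  sequences yield no gaps; a single junction yields no markers;
  saturated K2P divergence raises rather than returning NaN; features
  crossing query bounds, mixed query ids and non-ACGTN residues are
  input errors.
* The CLI is a thin layer over the library; `annotate` output naming is
  `<query>.tile<k>.svg/.ps` in input order. Clone-project (FPC-style)
  naming and ordering, GUI interaction, primer design and running the
  external aligners themselves are out of scope (pre-computed outputs
  are consumed instead; the built-in matcher replaces the exact-match
  step).
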