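# junctionscan

Repeat-rich genomic regions — centromeres above all — are stacks of
closely related repeats: tandem satellite arrays interrupted by
retroelements that insert into each other and into the satellite.
Conventional browser-style annotation shows every homology hit stacked,
which is unreadable exactly where it matters. `junctionscan` takes the
opposite approach, built for scientists mapping and characterizing such
regions:

* **Competition**: homology evidence from multiple subject databases
  (BLAST-style HSPs, cross_match masks) is *competed* — a longer feature
  eliminates shorter overlapping features from other databases unless the
  overlap is within a configured allowance (nt). Same-database hits stack
  freely so tandem repeats stay visible. The result is one best-fitting
  repeat class per locus.
* **Repeat junctions and markers**: every element insertion creates two
  repeat junctions — boundaries between element and target — which are
  potentially unique sequence even when both flanks are high-copy.
  Junctions are called at class changes in the competed track, and pairs
  of junctions no more than 2.5 kb apart become single-copy PCR marker
  candidates.
* **LTR identification and dating**: a built-in suffix-array maximal
  exact match finder (direct and inverted pairs, no external binaries
  needed) reveals paired LTRs; each pair is dated with the Kimura
  2-parameter distance κ = −½·ln(1−2P−Q) − ¼·ln(1−2Q) over its aligned
  arms (P transitions, Q transversions). Smaller κ = younger insertion.
* **Coverage charts**: per-nucleotide read coverage (e.g. CENH3
  ChIP-Seq) stratified by mapping multiplicity, in foreground/background
  chart sets with independent y-axes.
* **Rendering**: a composite per-query figure — 1 kb-tick ruler with
  grey gap bars (one per complete 100-N block) and gap-relative
  coordinates, charts, mask boxes, HSP arrows with query+subject
  coordinates, and exact-match lines (direct red, inverted blue) laid
  out longest-first on up to 30 levels — serialized deterministically to
  SVG and PostScript. Long queries are tiled into 210 kb windows
  overlapping by 10 kb so features ≤ 10 kb draw whole at least once.
* **Simulation**: a synthetic-centromere generator (satellite array,
  element families, nested insertions, read placements) with an exact
  ground-truth log, so the entire pipeline is testable offline.

## Worked example

`examples/04_junction_markers.py` simulates a small centromere (six
nested element insertions into a CentC-like array), emits noise-free
evidence, competes and classifies it, and calls junctions and markers:

```
6 insertions -> 12 junctions (logged: 12)
  junction at 11,938: CentC/sat | RireX/LTR
  junction at 12,599: RireX/LTR | CRM1/LTR
  junction at 20,699: CRM1/LTR | RireX/LTR
  junction at 24,651: RireX/CDS | CRM2/LTR
4 marker candidate(s) with junctions <= 2.5 kb apart
  span 422 nt: 34,449 + 34,871
  span 486 nt: 48,365 + 48,851
  span 661 nt: 11,938 + 12,599
```

Every insertion produced its two junctions (12 called, 12 logged by the
simulator), each labeled with the repeat classes on either side; the
four junction pairs within 2.5 kb are the loci where a single-copy PCR
marker could be designed. The other examples cover gaps/tiling, the
exact matcher, competition, LTR dating (`05` prints the four simulated
elements in correct youngest-to-oldest κ order), coverage charts, and
SVG/PostScript rendering.

There is also a thin CLI: `junctionscan template | simulate | annotate |
junctions | tile | render` (see `junctionscan --help`). `annotate` runs
the whole pipeline per query and writes one SVG + PostScript per tile,
GFF3 of kept features, junction BED, marker TSV and a JSON-lines audit
of eliminations and dropped matches.

## Layout

```
src/junctionscan/   config, seqio, homology (+_suffix), competition,
                    junctions, charts, render, simulate, cli
docs/methods.md     models, parameters, numerical choices, limitations
examples/           one short narrative script per capability
tests/              pytest suite (unit, property, end-to-end)
```
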