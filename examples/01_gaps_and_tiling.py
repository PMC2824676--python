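"""Assembly gaps and window tiling.

Builds a query with two N runs, detects the gaps, shows the gap-bar and
gap-relative ruler rules, then tiles a long region into overlapping
analysis windows.
"""

from junctionscan.seqio import detect_gaps, gap_relative_coordinate, tile_sequence

seq = "ACGT" * 500 + "N" * 1000 + "ACGT" * 2000 + "N" * 100 + "ACGT" * 500
gaps = detect_gaps(seq)  # default threshold: 100 consecutive Ns

for g in gaps:
    print(f"gap {g.start + 1:,}-{g.end:,} ({g.run_length} Ns) -> {g.n_bars} grey bar(s)")
# One bar per complete 100-N block: a reference-chromosome-scale gap
# (1,000 Ns) shows as a stack of 10 bars, a small assembly gap as 1.

pos = 5000
print(f"position {pos:,} is {gap_relative_coordinate(pos, gaps):,} nt past the last gap end")
# The ruler prints this secondary value under each 1 kb tick so distances
# can be read relative to assembly gaps rather than the contig start.

tiles = tile_sequence(410_000, window=210_000, overlap=10_000,
                      origin_1based=104_790_001)
for t in tiles:
    print(f"window {t.start_1based:,}-{t.end_1based:,}")
# 210 kb windows overlapping by 10 kb: any feature up to 10 kb (an LTR,
# say) is drawn complete in at least one window.
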