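"""Read-coverage charts in two sets with independent y-axes.

Builds per-nucleotide coverage from mapped-read placements, stratified
by mapping multiplicity: near-unique reads in the foreground (specific
signal), everything in the background (general association).
"""

from junctionscan.charts import (ReadPlacement, assemble_chart_sets,
                                 build_coverage, chart_to_bedgraph)

placements = (
    # ten near-unique reads over an enriched island
    [ReadPlacement(f"u{i}", "q", 1000 + 50 * i, 1400 + 50 * i, 1, 1)
     for i in range(10)]
    # high-multiplicity reads spread widely
    + [ReadPlacement(f"m{i}", "q", 300 * i, 300 * i + 400, 4, 40)
       for i in range(15)]
)

fg = build_coverage(placements, 5000, "unique", "unique-reads",
                    "foreground", "red")
bg = build_coverage(placements, 5000, "all", "all-reads", "background", "grey")
sets = assemble_chart_sets([fg, bg])

print(f"foreground y-max {sets.foreground_y_max} (unique reads only), "
      f"background y-max {sets.background_y_max} (all reads)")
print(f"coverage at 1,600: unique={fg.values[1600]}, all={bg.values[1600]}")
print(chart_to_bedgraph(fg, "q").splitlines()[1])
# A nucleotide covered by two passing reads gets the value 2. The two
# chart sets get separate y-axes so abundant multi-mapping coverage
# does not flatten the specific (unique-read) signal drawn over it.
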