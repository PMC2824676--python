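"""Built-in maximal exact match finder.

Plants a direct repeat, an inverted repeat and a small tandem array in
a random sequence and lists every maximal repeated pair >= 40 nt, the
same information an external exact matcher would supply.
"""

import numpy as np

from junctionscan.homology import find_maximal_exact_matches
from junctionscan.simulate import random_sequence

rng = np.random.default_rng(4)
background = random_sequence(3000, rng)
unit = background[100:160]  # 60 nt

rc = unit[::-1].translate(str.maketrans("ACGT", "TGCA"))
seq = (background[:1000] + unit + background[1000:1800] + rc
       + background[1800:2200] + unit * 3 + background[2200:])

for m in find_maximal_exact_matches(seq, min_len=40):
    print(f"{m.orientation:8s} {m.a_start + 1:>6,}-{m.a_end:<6,} == "
          f"{m.b_start + 1:>6,}-{m.b_end:<6,} ({m.length} nt)")
# 'direct' pairs (drawn red) reveal repeated sequence such as LTR pairs
# and tandem arrays; 'inverted' pairs (drawn blue) reverse-complement
# repeats. Overlapping pairs at monomer offsets are the signature of a
# tandem array even when the repeat itself is unknown.
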