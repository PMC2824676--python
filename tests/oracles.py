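"""Independent brute-force oracles used by the test suite.

These deliberately use different algorithm families from the package
(k-mer anchoring + extension instead of suffix arrays; quadratic pair
scans instead of interval trees) so agreement is meaningful.
"""

from __future__ import annotations

from typing import Dict, List, Sequence, Set, Tuple

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def _eq(a: str, b: str) -> bool:
    # N never matches anything, including another N
    return a == b and a != "N"


def revcomp(s: str) -> str:
    return "".join(_COMP[c] for c in reversed(s))


def brute_maximal_pairs(seq: str, min_len: int,
                        include_inverted: bool = True) -> Set[Tuple[int, int, int, str]]:
    """All maximal repeated pairs as (a_start, b_start, length, orientation),
    canonical (a_start <= b_start, identical-interval pairs excluded).

    Anchors every min_len-mer and extends; every maximal pair of length
    >= min_len contains such an anchor, and extension from any anchor of
    a pair reaches the same maximal pair.
    """
    n = len(seq)
    k = min_len
    out: Set[Tuple[int, int, int, str]] = set()
    index: Dict[str, List[int]] = {}
    for i in range(n - k + 1):
        kmer = seq[i : i + k]
        if "N" in kmer:
            continue
        index.setdefault(kmer, []).append(i)

    # direct pairs
    for kmer, positions in index.items():
        for ai in range(len(positions)):
            for bi in range(ai + 1, len(positions)):
                p, q = positions[ai], positions[bi]
                # extend left
                while p > 0 and q > 0 and _eq(seq[p - 1], seq[q - 1]):
                    p -= 1
                    q -= 1
                # extend right
                length = k + (positions[ai] - p)
                while p + length < n and q + length < n and _eq(
                    seq[p + length], seq[q + length]
                ):
                    length += 1
                out.add((p, q, length, "direct"))

    if include_inverted:
        for kmer, positions in index.items():
            rc_positions = index.get(revcomp(kmer), [])
            for p0 in positions:
                for q0 in rc_positions:
                    # seq[p0:p0+k] == revcomp(seq[q0:q0+k])
                    a, b, length = p0, q0, k
                    # coordinated extension: left of a with right of b
                    while a > 0 and b + length < n and _eq(
                        seq[a - 1], _COMP[seq[b + length]]
                    ):
                        a -= 1
                        length += 1
                    # right of a with left of b
                    while a + length < n and b > 0 and _eq(
                        seq[a + length], _COMP[seq[b - 1]]
                    ):
                        b -= 1
                        length += 1
                    if (a, a + length) == (b, b + length):
                        continue  # palindromic self-pair
                    key = (min(a, b), max(a, b), length, "inverted")
                    out.add(key)
    return out


def matches_to_keyset(matches) -> Set[Tuple[int, int, int, str]]:
    return {(m.a_start, m.b_start, m.length, m.orientation) for m in matches}


def brute_compete(features, allowance: int, mode: str, db_priority=()):
    """Straightforward re-statement of the ranked sweep with explicit
    pairwise overlap checks (no interval tree). Returns (kept, eliminated)
    feature lists."""
    prio = {db: i for i, db in enumerate(db_priority)}
    ranked = sorted(
        features,
        key=lambda f: (-f.length, -f.score, prio.get(f.db_name, len(prio)),
                       f.q_start, f.subject_id),
    )
    kept, eliminated = [], []
    for cand in ranked:
        ok = True
        for other in kept:
            if mode == "blast" and other.db_name == cand.db_name:
                continue
            ov = max(0, min(cand.q_end, other.q_end) - max(cand.q_start, other.q_start))
            if ov > allowance:
                ok = False
                break
        (kept if ok else eliminated).append(cand)
    return kept, eliminated


def brute_level_layout(matches, max_levels: int):
    """Greedy level placement re-stated with explicit interval scans."""
    order = sorted(matches, key=lambda m: (-m.length, m.a_start, m.b_start))
    placed = {}  # match key -> level
    levels = [[] for _ in range(max_levels)]
    dropped = []
    for m in order:
        s, e = m.a_start, m.b_end
        for lvl in range(max_levels):
            if not any(s < pe and e > ps for ps, pe in levels[lvl]):
                levels[lvl].append((s, e))
                placed[m.key()] = lvl
                break
        else:
            dropped.append(m)
    return placed, dropped


def brute_coverage(placements, query_len: int, predicate) -> List[int]:
    vals = [0] * query_len
    for p in placements:
        if predicate(p):
            for i in range(p.q_start, p.q_end):
                vals[i] += 1
    return vals
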