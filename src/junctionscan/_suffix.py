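"""Suffix-array machinery for the built-in maximal exact match finder.

The finder works on an integer-coded text: A/C/G/T get small codes and
every N (and the separator between a sequence and its reverse
complement) gets a unique large code, so no match can ever include or
span an N. Maximal pairs are enumerated by a bottom-up traversal of the
LCP-interval structure: a pair is emitted at depth d exactly when the
two suffixes share a prefix of exactly d (right-maximal, because they
first meet in an interval of depth d) and their preceding characters
differ (left-maximal).
"""

from __future__ import annotations

from typing import Iterator, List, Tuple

import numpy as np


def suffix_array(codes: np.ndarray) -> np.ndarray:
    """Suffix array by prefix doubling (O(n log n) numpy sorts)."""
    n = len(codes)
    if n == 0:
        return np.empty(0, dtype=np.int64)
    rank = np.asarray(codes, dtype=np.int64)
    # compact ranks
    order = np.argsort(rank, kind="stable")
    sorted_r = rank[order]
    comp = np.empty(n, dtype=np.int64)
    comp[order] = np.cumsum(np.concatenate(([0], (np.diff(sorted_r) != 0).astype(np.int64))))
    rank = comp
    k = 1
    sa = order
    while k < n:
        key2 = np.full(n, -1, dtype=np.int64)
        key2[: n - k] = rank[k:]
        sa = np.lexsort((key2, rank))
        r1 = rank[sa]
        r2 = key2[sa]
        changed = np.concatenate(
            ([0], ((np.diff(r1) != 0) | (np.diff(r2) != 0)).astype(np.int64))
        )
        new_rank = np.empty(n, dtype=np.int64)
        new_rank[sa] = np.cumsum(changed)
        rank = new_rank
        if rank[sa[-1]] == n - 1:
            break
        k *= 2
    return sa


def lcp_kasai(codes: np.ndarray, sa: np.ndarray) -> np.ndarray:
    """LCP array: lcp[i] = lcp(suffix sa[i-1], suffix sa[i]); lcp[0] = 0."""
    n = len(codes)
    lcp = np.zeros(n, dtype=np.int64)
    if n == 0:
        return lcp
    rank = np.empty(n, dtype=np.int64)
    rank[sa] = np.arange(n)
    h = 0
    c = codes
    for i in range(n):
        r = rank[i]
        if r > 0:
            j = sa[r - 1]
            limit = n - max(i, j)
            while h < limit and c[i + h] == c[j + h]:
                h += 1
            lcp[r] = h
            if h > 0:
                h -= 1
        else:
            h = 0
    return lcp


def maximal_pairs(
    codes: np.ndarray, sa: np.ndarray, lcp: np.ndarray, min_len: int
) -> List[Tuple[int, int, int]]:
    """All maximal repeated pairs (pos_a, pos_b, length) with length >= min_len.

    Maximal means the match cannot be extended by one character on
    either side. Unordered pairs are reported once; positions with a
    unique left character (text start, after an N/separator) are always
    left-maximal.
    """
    n = len(sa)
    out: List[Tuple[int, int, int]] = []
    if n == 0:
        return out

    def emit(acc: dict, new: dict, depth: int) -> None:
        if depth < min_len:
            return
        for ca, pa in acc.items():
            for cb, pb in new.items():
                if ca == cb:
                    continue  # same left char: not left-maximal
                for x in pa:
                    for y in pb:
                        out.append((x, y, depth) if x < y else (y, x, depth))

    def merge(acc: dict, new: dict) -> None:
        for c, p in new.items():
            if c in acc:
                acc[c].extend(p)
            else:
                acc[c] = p

    def leaf(pos: int) -> dict:
        # unique negative code at text start / after an N or separator
        # (those positions are always left-maximal)
        if pos == 0 or codes[pos - 1] >= 4:
            return {-(pos + 1): [pos]}
        return {int(codes[pos - 1]): [pos]}

    # A leaf belongs to the deeper of its two adjacent lcp boundaries, so
    # each leaf stays pending until the boundary to its right is known.
    # Invariant: after processing boundary i, the stack top has depth
    # lcp[i], and it holds exactly the earlier suffixes whose lcp with
    # the next suffix equals that depth — so pairs are always emitted at
    # the exact length of their shared prefix.
    stack: List[list] = [[0, {}]]  # [depth, groups: left-char -> positions]
    pending = leaf(int(sa[0]))
    for i in range(1, n + 1):
        h = int(lcp[i]) if i < n else 0
        if h > stack[-1][0]:
            stack.append([h, pending])
        else:
            top = stack[-1]
            emit(top[1], pending, top[0])
            merge(top[1], pending)
            while stack[-1][0] > h:
                d, g = stack.pop()
                if stack[-1][0] < h:
                    stack.append([h, {}])
                top = stack[-1]
                emit(top[1], g, top[0])
                merge(top[1], g)
        if i < n:
            pending = leaf(int(sa[i]))
    return out


_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def encode_with_revcomp(seq: str) -> Tuple[np.ndarray, int]:
    """Integer-code ``seq + sep + revcomp(seq)``.

    Ns and the separator get unique codes >= 4 so they never match
    anything (including other Ns). Returns (codes, n) where n is the
    length of the forward sequence; the reverse-complement half starts
    at offset n + 1.
    """
    n = len(seq)
    codes = np.empty(2 * n + 1, dtype=np.int64)
    nxt = 4  # next unique code
    for i, ch in enumerate(seq):
        c = _CODE.get(ch)
        if c is None:
            codes[i] = nxt
            nxt += 1
        else:
            codes[i] = c
    codes[n] = nxt
    nxt += 1
    for i in range(n):
        ch = _COMP[seq[n - 1 - i]] if seq[n - 1 - i] in _COMP else "N"
        c = _CODE.get(ch)
        if c is None:
            codes[n + 1 + i] = nxt
            nxt += 1
        else:
            codes[n + 1 + i] = c
    return codes, n


def encode(seq: str) -> np.ndarray:
    """Integer-code a single sequence (unique codes for Ns)."""
    n = len(seq)
    codes = np.empty(n, dtype=np.int64)
    nxt = 4
    for i, ch in enumerate(seq):
        c = _CODE.get(ch)
        if c is None:
            codes[i] = nxt
            nxt += 1
        else:
            codes[i] = c
    return codes
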