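"""Brute-force reference implementations used only to cross-check the package.

These stay deliberately independent of the code paths they verify: the repeat
oracle enumerates match runs on every diagonal of the comparison matrix, and
the effect oracle translates whole mutated coding sequences.
"""

from __future__ import annotations

import numpy as np
from Bio.Seq import Seq


def maximal_matches_oracle(left: str, right: str, min_len: int
                           ) -> set[tuple[int, int, int]]:
    """All maximal exact matches >= min_len between two strings.

    Returns (left_start, right_start, length), 0-based within each string.
    N never matches. Dynamic program over match-run lengths, row by row.
    """
    n, m = len(left), len(right)
    if n == 0 or m == 0:
        return set()
    la = np.frombuffer(left.encode(), dtype=np.uint8)
    ra = np.frombuffer(right.encode(), dtype=np.uint8)
    is_n_l = la == ord("N")
    is_n_r = ra == ord("N")
    out: set[tuple[int, int, int]] = set()
    prev = np.zeros(m, dtype=np.int32)
    for i in range(n):
        eq = (la[i] == ra) & ~is_n_r & ~is_n_l[i]
        run = np.zeros(m, dtype=np.int32)
        run[0] = 1 if eq[0] else 0
        run[1:] = np.where(eq[1:], prev[:-1] + 1, 0)
        # a run ending at (i, j) is maximal if (i+1, j+1) does not extend it
        if i + 1 < n:
            nxt_eq = (la[i + 1] == ra) & ~is_n_r & ~is_n_l[i + 1]
            ends = (run >= min_len) & ~np.concatenate(
                (nxt_eq[1:], [False]))
        else:
            ends = run >= min_len
        for j in np.nonzero(ends)[0]:
            length = int(run[j])
            out.add((i - length + 1, int(j) - length + 1, length))
        prev = run
    return out


def translate_cds(seq: str) -> str:
    return str(Seq(seq).translate())


def effect_oracle(cds: str, pos: int, alt: str) -> str:
    """synonymous/nonsynonymous by translating the full mutated CDS.

    pos is 1-based on the coding strand.
    """
    mutated = cds[: pos - 1] + alt + cds[pos:]
    return ("synonymous" if translate_cds(mutated) == translate_cds(cds)
            else "nonsynonymous")


def binomial_tail(k: int, n: int, p: float) -> float:
    """P(X >= k) by direct summation (small n only)."""
    from math import comb

    return sum(comb(n, i) * p**i * (1 - p) ** (n - i) for i in range(k, n + 1))
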