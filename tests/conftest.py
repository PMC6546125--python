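"""Shared fixtures and brute-force oracles.

The oracles deliberately avoid the library's index machinery: suffix arrays
by explicit string sorting with character-by-character neighbour comparison,
and match factors by scanning every other position for the longest match.
Non-ACGT symbols (and record separators, when emulating multi-record inputs)
map to characters that sort above 'T' and are unique per occurrence, matching
the library's convention that such symbols never participate in a match.
"""

from __future__ import annotations

import numpy as np
import pytest

from matchcomp import SequenceSet, build_esa


def brute_sa_lcp_isa(s: str) -> tuple[list[int], list[int], list[int]]:
    """1-based suffix array, LCP array (lcp[rank 1] = -1) and inverse."""
    n = len(s)
    order = sorted(range(n), key=lambda i: s[i:])
    sa = [i + 1 for i in order]
    lcp = [-1]
    for r in range(1, n):
        a, b = s[order[r - 1]:], s[order[r]:]
        h = 0
        while h < min(len(a), len(b)) and a[h] == b[h]:
            h += 1
        lcp.append(h)
    isa = [0] * n
    for r, p in enumerate(sa):
        isa[p - 1] = r + 1
    return sa, lcp, isa


def uniquify_non_acgt(s: str) -> str:
    """Replace every non-ACGT character with a distinct symbol above 'T'."""
    out = []
    code = ord("U")
    for ch in s:
        if ch in "ACGT":
            out.append(ch)
        else:
            out.append(chr(code))
            code += 1
    return "".join(out)


def brute_match_length(s: str, i: int) -> int:
    """Longest k such that s[i:i+k] occurs at some position j != i (0-based)."""
    n = len(s)
    best = 0
    for k in range(1, n - i + 1):
        sub = s[i : i + k]
        found = False
        start = 0
        while True:
            j = s.find(sub, start)
            if j == -1:
                break
            if j != i:
                found = True
                break
            start = j + 1
        if not found:
            break
        best = k
    return best


def brute_factor_ends(s: str) -> list[int]:
    """Greedy match-factor ends (1-based): longest match elsewhere, else 1 base."""
    n = len(s)
    ends = []
    i = 0
    while i < n:
        i += max(brute_match_length(s, i), 1)
        ends.append(i)
    return ends


def random_string(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    p = gc / 2.0
    codes = rng.choice(4, size=length, p=[0.5 - p, p, p, 0.5 - p])
    return "".join("ACGT"[c] for c in codes)


@pytest.fixture(scope="session")
def worked_esa():
    """The enhanced suffix array of the worked 10-mer example."""
    return build_esa(SequenceSet([("S", "CGGGCGGGCT")]))
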