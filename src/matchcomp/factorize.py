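"""Match-factor decomposition and the associated renewal counting process.

A match factor starting at position i is the longest prefix of the remaining
sequence that also occurs at some other position in the match space (or a
single base when there is no such match).  Factors tile the record without
gaps; their count per base is the raw ingredient of the match complexity Cm.
The factor end positions form a renewal-like counting process N_i (number of
factor ends at or before position i), which lets a sliding-window scan read
off per-window factor counts in O(1) from one global decomposition instead of
re-factorising every window.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .esa import EnhancedSuffixArray


@dataclass(frozen=True)
class MatchFactorization:
    """Ordered factor end positions of one record, 1-based within the record.

    ``ends[k]`` is the last position of the (k+1)-th factor; the final end
    equals the record length, so factors tile [1, L] without gaps or overlap.
    """

    identifier: str
    ends: np.ndarray  # int64, strictly increasing, last == length
    length: int

    @property
    def n_factors(self) -> int:
        return int(self.ends.size)

    @property
    def starts(self) -> np.ndarray:
        return np.concatenate([[1], self.ends[:-1] + 1]).astype(np.int64)

    def to_tsv(self, path: str | Path) -> None:
        """Dump factors as TSV: record, factor index, start, end, length."""
        starts = self.starts
        with open(path, "w") as fh:
            fh.write("record\tfactor\tstart\tend\tlength\n")
            for k, (s, e) in enumerate(zip(starts, self.ends), start=1):
                fh.write(f"{self.identifier}\t{k}\t{s}\t{e}\t{e - s + 1}\n")


@dataclass(frozen=True)
class RenewalCounts:
    """Cumulative factor count N_i for i = 0..L (N_0 = 0).

    A nondecreasing step function that jumps by one at each factor end, so
    the factor count of any window falls out by subtraction.
    """

    identifier: str
    counts: np.ndarray  # int64, length L+1

    @property
    def length(self) -> int:
        return int(self.counts.size - 1)

    @property
    def n_factors(self) -> int:
        return int(self.counts[-1])


def factorize(esa: EnhancedSuffixArray, identifier: str) -> MatchFactorization:
    """Decompose one record into match factors.

    Greedy left-to-right: at position i the factor length is
    ``max(lcp[isa[i]], lcp[isa[i]+1], 1)`` — the longest match elsewhere, or a
    single base when none exists (with the out-of-bounds guard treating the
    rank past the end as LCP 0).  Separator and ambiguity symbols are unique
    in the match space, so a factor never crosses a record boundary or an
    ambiguous base.
    """
    lam = esa.match_lengths(identifier)
    n = lam.size
    ends = []
    i = 0  # 0-based within record
    while i < n:
        step = int(lam[i])
        if step < 1:
            step = 1
        i += step
        ends.append(i)
    assert ends[-1] == n, "factor overran record end"
    return MatchFactorization(
        identifier=identifier, ends=np.asarray(ends, dtype=np.int64), length=n
    )


def renewal_counts(f: MatchFactorization) -> RenewalCounts:
    """Cumulative factor counts: N_i = number of factor ends <= i."""
    counts = np.zeros(f.length + 1, dtype=np.int64)
    counts[f.ends] = 1
    np.cumsum(counts, out=counts)
    return RenewalCounts(identifier=f.identifier, counts=counts)


def window_factor_count(counts: RenewalCounts, start: int, end: int) -> int:
    """Number of factors whose END lies in [start, end], 1-based inclusive.

    A factor belongs to the window containing its end position; a factor
    spanning a window boundary is counted once, in the later window.
    """
    if not (1 <= start <= end <= counts.length):
        raise ValueError(
            f"window [{start}, {end}] out of range for record of length {counts.length}"
        )
    return int(counts.counts[end] - counts.counts[start - 1])
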