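"""Enhanced suffix arrays over nucleotide sequence sets.

The enhanced suffix array (ESA) is the index behind every match-complexity
computation: the suffix array ``sa`` lists the 1-based start positions of the
lexicographically sorted suffixes, ``lcp`` holds the longest-common-prefix
length between each suffix and its predecessor in sort order (with
``lcp[rank 1] = -1``), and the inverse suffix array ``isa`` maps a sequence
position back to its rank.  Index construction is the expensive one-off step;
querying (factorisation, window scans) is cheap and can be repeated against a
persisted index.

Multi-record inputs are concatenated with per-gap unique separator symbols,
and every non-ACGT base is likewise treated as a unique symbol, so no match
ever crosses a record boundary or an ambiguous base.  Unique symbols sort
above the A<C<G<T alphabet in order of appearance; the conceptual end-of-text
terminator sorts below everything (so a suffix that is a prefix of another
ranks first).  The reported arrays contain only the true sequence positions,
never separators.
"""

from __future__ import annotations

import gzip
import json
import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from numba import njit

_MAGIC = b"MCMPIDX\x01"
_VERSION = 1

_ALPHABET = "ACGT"
_COMPLEMENT = {0: 3, 1: 2, 2: 1, 3: 0}


# ---------------------------------------------------------------------------
# Sequence sets
# ---------------------------------------------------------------------------

@dataclass
class SequenceSet:
    """An ordered collection of named uppercase nucleotide sequences.

    ``records`` is a list of ``(identifier, residues)`` pairs.  Residues are
    stored uppercase; anything outside {A, C, G, T} counts as ambiguous and is
    flagged in :attr:`ambiguity_mask`.  Positions are 1-based across the
    concatenation of the records (record boundaries tracked separately).
    """

    records: list[tuple[str, str]]

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("SequenceSet requires at least one record")
        ids = [r[0] for r in self.records]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate record identifiers: {dup}")
        self.records = [(i, s.upper()) for i, s in self.records]
        if self.total_length == 0:
            raise ValueError("SequenceSet has zero total length")

    @property
    def identifiers(self) -> list[str]:
        return [r[0] for r in self.records]

    @property
    def total_length(self) -> int:
        """L: the summed length of all records, in bases."""
        return sum(len(r[1]) for r in self.records)

    @property
    def ambiguity_mask(self) -> np.ndarray:
        """Boolean mask over the 1..L concatenated coordinates; True = non-ACGT."""
        return _encode_bases(self.concatenated) < 0

    @property
    def concatenated(self) -> str:
        return "".join(r[1] for r in self.records)

    def gc_content(self) -> float:
        """Fraction of C+G among unambiguous bases."""
        codes = _encode_bases(self.concatenated)
        n_ok = int((codes >= 0).sum())
        if n_ok == 0:
            return float("nan")
        n_gc = int(((codes == 1) | (codes == 2)).sum())
        return n_gc / n_ok

    @classmethod
    def from_fasta(cls, path: str | Path) -> "SequenceSet":
        """Read a (possibly gzipped) multi-record FASTA file."""
        from Bio import SeqIO

        path = Path(path)
        opener = gzip.open if path.suffix == ".gz" else open
        with opener(path, "rt") as fh:
            records = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(fh, "fasta")]
        return cls(records)


def _encode_bases(seq: str) -> np.ndarray:
    """Map a string to int8 codes: A,C,G,T -> 0..3, anything else -> -1."""
    table = np.full(256, -1, dtype=np.int8)
    for i, b in enumerate(_ALPHABET):
        table[ord(b)] = i
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return table[raw]


# ---------------------------------------------------------------------------
# Suffix sorting (prefix doubling) and Kasai LCP
# ---------------------------------------------------------------------------

def _suffix_array(t: np.ndarray) -> np.ndarray:
    """Suffix array of an integer sequence by vectorised prefix doubling.

    Shorter suffixes that are prefixes of longer ones sort first (out-of-range
    positions compare below every symbol), matching plain string sorting.
    """
    n = t.size
    if n == 1:
        return np.zeros(1, dtype=np.int64)
    _, rank = np.unique(t, return_inverse=True)
    rank = rank.astype(np.int64)
    k = 1
    while True:
        key2 = np.full(n, -1, dtype=np.int64)
        key2[: n - k] = rank[k:]
        sa = np.lexsort((key2, rank))
        r1, r2 = rank[sa], key2[sa]
        changed = np.empty(n, dtype=np.int64)
        changed[0] = 0
        changed[1:] = (r1[1:] != r1[:-1]) | (r2[1:] != r2[:-1])
        new_rank_sorted = np.cumsum(changed)
        if new_rank_sorted[-1] == n - 1:
            return sa
        rank[sa] = new_rank_sorted
        k *= 2


@njit(cache=True)
def _kasai(t: np.ndarray, sa: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """LCP array (Kasai) and inverse suffix array, both 0-based; lcp[0] = -1."""
    n = t.size
    isa = np.empty(n, dtype=np.int64)
    for r in range(n):
        isa[sa[r]] = r
    lcp = np.zeros(n, dtype=np.int64)
    h = 0
    for i in range(n):
        r = isa[i]
        if r > 0:
            j = sa[r - 1]
            while i + h < n and j + h < n and t[i + h] == t[j + h]:
                h += 1
            lcp[r] = h
            if h > 0:
                h -= 1
        else:
            h = 0
    lcp[0] = -1
    return lcp, isa


# ---------------------------------------------------------------------------
# The enhanced suffix array
# ---------------------------------------------------------------------------

@dataclass
class EnhancedSuffixArray:
    """Suffix array + LCP array + inverse suffix array of a sequence set.

    Public arrays cover the L true sequence positions in 1-based concatenated
    coordinates: ``sa[r-1]`` is the start position of the rank-r suffix,
    ``lcp[r-1]`` its common-prefix length with the rank-(r-1) suffix
    (``lcp[0] == -1``), and ``isa[p-1]`` the rank of the suffix starting at
    position p.  When ``both_strands`` is set the reverse complement is part
    of the match space (it influences match lengths) but the reported arrays
    still describe only the forward positions.
    """

    sa: np.ndarray
    lcp: np.ndarray
    isa: np.ndarray
    offsets: dict[str, tuple[int, int]]  # identifier -> (start, end), 1-based incl.
    gc: float
    L: int
    both_strands: bool = False
    # internals over the full match space (records + separators [+ revcomp])
    _sa_full: np.ndarray = field(default=None, repr=False)
    _lcp_full: np.ndarray = field(default=None, repr=False)
    _isa_full: np.ndarray = field(default=None, repr=False)
    _t_of_pos: np.ndarray = field(default=None, repr=False)  # concat coord -> T index
    _ambig: np.ndarray = field(default=None, repr=False)  # bool over 1..L

    def record_range(self, identifier: str) -> tuple[int, int]:
        """1-based inclusive concatenated coordinates of a record."""
        try:
            return self.offsets[identifier]
        except KeyError:
            raise KeyError(f"record {identifier!r} not in index") from None

    def record_length(self, identifier: str) -> int:
        start, end = self.record_range(identifier)
        return end - start + 1

    @property
    def identifiers(self) -> list[str]:
        return list(self.offsets)

    def ambiguity_mask(self) -> np.ndarray:
        return self._ambig

    def match_lengths(self, identifier: str) -> np.ndarray:
        """Longest match elsewhere in the match space, per record position.

        Entry i (0-based within the record) is the length of the longest
        prefix of the suffix starting there that also occurs at some other
        position; it is the max of the LCP with the rank neighbours,
        ``max(lcp[isa[i]], lcp[isa[i]+1])``, with the end-of-array guard
        ``lcp[M+1] = 0``.  Separator and ambiguity symbols are unique, so
        these lengths never span a record boundary or an ambiguous base.
        """
        start, end = self.record_range(identifier)
        t_idx = self._t_of_pos[start - 1 : end]
        isa = self._isa_full[t_idx]
        lcp_ext = np.concatenate([self._lcp_full, [0]])
        lam = np.maximum(lcp_ext[isa], lcp_ext[isa + 1])
        return np.maximum(lam, 0)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EnhancedSuffixArray):
            return NotImplemented
        return (
            self.L == other.L
            and self.both_strands == other.both_strands
            and self.offsets == other.offsets
            and np.isclose(self.gc, other.gc, equal_nan=True)
            and np.array_equal(self.sa, other.sa)
            and np.array_equal(self.lcp, other.lcp)
            and np.array_equal(self.isa, other.isa)
            and np.array_equal(self._sa_full, other._sa_full)
            and np.array_equal(self._lcp_full, other._lcp_full)
        )


def _encode_match_space(
    seqs: SequenceSet, both_strands: bool
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Build the integer match-space sequence T.

    Returns ``(t, t_of_pos, pos_of_t)`` where ``t_of_pos[c-1]`` is the T index
    of concatenated coordinate c and ``pos_of_t[m]`` is the coordinate at T
    index m (0 for separators and reverse-complement positions).  A, C, G, T
    map to 0..3; separators and ambiguous bases get unique codes 4, 5, ... in
    order of appearance so they can never match anything.
    """
    parts = []
    for k, (_ident, seq) in enumerate(seqs.records):
        if k > 0:
            parts.append(None)  # separator placeholder
        parts.append(_encode_bases(seq).astype(np.int64))
    fwd = _join_with_separators(parts)
    if both_strands:
        rc = fwd[::-1].copy()
        acgt = (rc >= 0) & (rc <= 3)
        rc[acgt] = 3 - rc[acgt]
        rc[~acgt] = -1  # complements of ambiguity/separator stay unique
        t = np.concatenate([fwd, np.array([-1], dtype=np.int64), rc])
    else:
        t = fwd
    # assign unique codes to all negatives, in T order
    neg = np.flatnonzero(t < 0)
    t[neg] = 4 + np.arange(neg.size, dtype=np.int64)
    # coordinate maps over the forward part
    m = 0
    pos_of_t = np.zeros(t.size, dtype=np.int64)
    t_of_pos = np.empty(seqs.total_length, dtype=np.int64)
    c = 0
    for k, (_ident, seq) in enumerate(seqs.records):
        if k > 0:
            m += 1  # separator
        n = len(seq)
        t_of_pos[c : c + n] = np.arange(m, m + n)
        pos_of_t[m : m + n] = np.arange(c + 1, c + n + 1)
        c += n
        m += n
    return t, t_of_pos, pos_of_t


def _join_with_separators(parts: list) -> np.ndarray:
    out = []
    for p in parts:
        out.append(np.array([-1], dtype=np.int64) if p is None else p)
    return np.concatenate(out) if len(out) > 1 else out[0]


def build_esa(seqs: SequenceSet, both_strands: bool = False) -> EnhancedSuffixArray:
    """Build the enhanced suffix array of a sequence set.

    Parameters
    ----------
    seqs
        The sequences to index.
    both_strands
        When True the reverse complement is appended to the match space, so
        matches may come from either strand; the reported arrays still cover
        the forward positions only.
    """
    t, t_of_pos, pos_of_t = _encode_match_space(seqs, both_strands)
    sa_full = _suffix_array(t)
    lcp_full, isa_full = _kasai(t, sa_full)
    sa, lcp, isa = _project_public(sa_full, lcp_full, pos_of_t, seqs.total_length)
    offsets = {}
    c = 1
    for ident, seq in seqs.records:
        offsets[ident] = (c, c + len(seq) - 1)
        c += len(seq)
    return EnhancedSuffixArray(
        sa=sa,
        lcp=lcp,
        isa=isa,
        offsets=offsets,
        gc=seqs.gc_content(),
        L=seqs.total_length,
        both_strands=both_strands,
        _sa_full=sa_full,
        _lcp_full=lcp_full,
        _isa_full=isa_full,
        _t_of_pos=t_of_pos,
        _ambig=seqs.ambiguity_mask,
    )


def _project_public(
    sa_full: np.ndarray, lcp_full: np.ndarray, pos_of_t: np.ndarray, L: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Restrict full-match-space arrays to the L true sequence positions.

    The LCP between consecutive kept suffixes is the minimum of the full LCP
    values over the skipped ranks (the standard range-minimum property).
    """
    coords = pos_of_t[sa_full]
    idx = np.flatnonzero(coords > 0)
    sa = coords[idx]
    lcp = np.empty(L, dtype=np.int64)
    lcp[0] = -1
    if L > 1:
        starts = idx[:-1] + 1
        seg = lcp_full[: idx[-1] + 1]
        lcp[1:] = np.minimum.reduceat(seg, starts)
    isa = np.empty(L, dtype=np.int64)
    isa[sa - 1] = np.arange(1, L + 1)
    return sa, lcp, isa


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------

def save_index(esa: EnhancedSuffixArray, path: str | Path) -> None:
    """Write the index as a single versioned binary file.

    Layout: magic bytes, version, a JSON header (records, L, GC, strand flag,
    array sizes), then the ambiguity positions and the full-match-space
    sa/lcp arrays as little-endian int64.  Everything else is re-derived on
    load, so a round trip reproduces the index exactly.
    """
    path = Path(path)
    header = {
        "records": [[i, int(e - s + 1)] for i, (s, e) in esa.offsets.items()],
        "L": int(esa.L),
        "M": int(esa._sa_full.size),
        "gc": None if np.isnan(esa.gc) else float(esa.gc),
        "both_strands": bool(esa.both_strands),
        "n_ambig": int(esa._ambig.sum()),
    }
    hdr = json.dumps(header).encode()
    ambig_pos = np.flatnonzero(esa._ambig).astype("<i8")
    with open(path, "wb") as fh:
        fh.write(_MAGIC)
        fh.write(struct.pack("<I", _VERSION))
        fh.write(struct.pack("<Q", len(hdr)))
        fh.write(hdr)
        fh.write(ambig_pos.tobytes())
        fh.write(esa._sa_full.astype("<i8").tobytes())
        fh.write(esa._lcp_full.astype("<i8").tobytes())


def load_index(path: str | Path) -> EnhancedSuffixArray:
    """Load an index written by :func:`save_index`.

    Raises ``ValueError`` naming the file on magic/version mismatch or
    truncation; never returns a partial index.
    """
    path = Path(path)
    with open(path, "rb") as fh:
        data = fh.read()
    if data[: len(_MAGIC)] != _MAGIC:
        raise ValueError(f"{path}: not a matchcomp index (bad magic bytes)")
    off = len(_MAGIC)
    try:
        (version,) = struct.unpack_from("<I", data, off)
        off += 4
        if version != _VERSION:
            raise ValueError(f"{path}: unsupported index version {version}")
        (hlen,) = struct.unpack_from("<Q", data, off)
        off += 8
        header = json.loads(data[off : off + hlen].decode())
        off += hlen
        L, M, n_ambig = header["L"], header["M"], header["n_ambig"]
        expected = off + 8 * (n_ambig + 2 * M)
        if len(data) != expected:
            raise ValueError(
                f"{path}: truncated or corrupt index "
                f"({len(data)} bytes, expected {expected})"
            )
        ambig_pos = np.frombuffer(data, dtype="<i8", count=n_ambig, offset=off)
        off += 8 * n_ambig
        sa_full = np.frombuffer(data, dtype="<i8", count=M, offset=off).astype(np.int64)
        off += 8 * M
        lcp_full = np.frombuffer(data, dtype="<i8", count=M, offset=off).astype(np.int64)
    except (struct.error, json.JSONDecodeError, KeyError) as exc:
        raise ValueError(f"{path}: truncated or corrupt index ({exc})") from exc

    both_strands = header["both_strands"]
    ambig = np.zeros(L, dtype=bool)
    ambig[ambig_pos] = True
    # rebuild the deterministic T-layout coordinate maps from record lengths
    lengths = [int(n) for _ident, n in header["records"]]
    t_of_pos = np.empty(L, dtype=np.int64)
    pos_of_t = np.zeros(M, dtype=np.int64)
    c = m = 0
    offsets = {}
    for (ident, n), _ in zip(header["records"], lengths):
        if c > 0:
            m += 1
        t_of_pos[c : c + n] = np.arange(m, m + n)
        pos_of_t[m : m + n] = np.arange(c + 1, c + n + 1)
        offsets[ident] = (c + 1, c + n)
        c += n
        m += n
    isa_full = np.empty(M, dtype=np.int64)
    isa_full[sa_full] = np.arange(M)
    sa, lcp, isa = _project_public(sa_full, lcp_full, pos_of_t, L)
    return EnhancedSuffixArray(
        sa=sa,
        lcp=lcp,
        isa=isa,
        offsets=offsets,
        gc=float("nan") if header["gc"] is None else header["gc"],
        L=L,
        both_strands=both_strands,
        _sa_full=sa_full,
        _lcp_full=lcp_full,
        _isa_full=isa_full,
        _t_of_pos=t_of_pos,
        _ambig=ambig,
    )
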