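"""Sliding-window Cm scans and high-complexity interval calling.

One global match factorisation per record feeds every window through the
renewal counts, so a scan is a single pass: for a window of length W with
N_W factor ends inside it, Cm = (N_W/W - 2/W) / (Ca - 2/W).  Windows whose
ambiguous-base fraction is too high are reported as undefined (NA) rather
than as spuriously low Cm.  Windows at or above a null quantile merge into
maximal high-complexity intervals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .esa import EnhancedSuffixArray
from .factorize import factorize, renewal_counts
from .nullmodel import NullModel

logger = logging.getLogger("matchcomp")

DEFAULT_MAX_AMBIG_FRAC = 0.05


@dataclass
class WindowProfile:
    """Per-window Cm values for a scanned sequence set.

    ``windows`` has columns record, start, end, midpoint, cm (1-based
    inclusive coordinates on the per-record step grid; cm is NaN for
    undefined windows).  Scan metadata travels with the profile.
    """

    windows: pd.DataFrame
    W: int
    step: int
    gc: float
    L: int
    max_ambig_frac: float = DEFAULT_MAX_AMBIG_FRAC
    threshold: float | None = None

    def defined(self) -> pd.DataFrame:
        return self.windows[self.windows["cm"].notna()]

    def to_tsv(self, path: str | Path) -> None:
        """Write record, start, end, midpoint, Cm (6 decimals; NA if undefined)."""
        df = self.windows.copy()
        df["cm"] = df["cm"].map(lambda v: "NA" if pd.isna(v) else f"{v:.6f}")
        df.to_csv(path, sep="\t", index=False)

    def to_bedgraph(self, path: str | Path) -> None:
        """bedGraph (0-based half-open) of defined windows, for browser tracks."""
        df = self.defined()
        with open(path, "w") as fh:
            fh.write('track type=bedGraph name="Cm"\n')
            for rec, start, end, cm in zip(df["record"], df["start"], df["end"], df["cm"]):
                fh.write(f"{rec}\t{start - 1}\t{end}\t{cm:.6f}\n")


@dataclass(frozen=True)
class ComplexityInterval:
    """A maximal merged run of qualifying windows, 1-based inclusive."""

    record: str
    start: int
    end: int
    n_windows: int
    max_cm: float

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def scan_windows(
    esa: EnhancedSuffixArray,
    null: NullModel,
    W: int,
    step: int = 1,
    max_ambig_frac: float = DEFAULT_MAX_AMBIG_FRAC,
    records: list[str] | None = None,
) -> WindowProfile:
    """Scan records with windows of length W advancing by ``step`` bases.

    The window grid starts at position 1 of each record; a trailing partial
    window is not emitted.  Records shorter than W are skipped with a
    warning.  Cm uses Ci = 2/W and Ca = 1/mu from the null model.
    """
    if step < 1:
        raise ValueError("step must be >= 1")
    Ci = 2.0 / W
    if null.Ca <= Ci:
        raise ValueError(
            f"window length {W} too short for the null model (Ca <= 2/W)"
        )
    ambig_all = esa.ambiguity_mask()
    frames = []
    for ident in records if records is not None else esa.identifiers:
        lo, hi = esa.record_range(ident)
        Lr = hi - lo + 1
        if W > Lr:
            logger.warning(
                "record %s (length %d) shorter than window %d: skipped", ident, Lr, W
            )
            continue
        counts = renewal_counts(factorize(esa, ident)).counts
        ambig_cum = np.concatenate(
            [[0], np.cumsum(ambig_all[lo - 1 : hi].astype(np.int64))]
        )
        starts = np.arange(1, Lr - W + 2, step, dtype=np.int64)
        ends = starts + W - 1
        n_w = counts[ends] - counts[starts - 1]
        cm = (n_w / W - Ci) / (null.Ca - Ci)
        ambig_frac = (ambig_cum[ends] - ambig_cum[starts - 1]) / W
        cm = np.where(ambig_frac > max_ambig_frac, np.nan, cm)
        frames.append(
            pd.DataFrame(
                {
                    "record": ident,
                    "start": starts,
                    "end": ends,
                    "midpoint": (starts + ends) // 2,
                    "cm": cm,
                }
            )
        )
    windows = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["record", "start", "end", "midpoint", "cm"])
    )
    return WindowProfile(
        windows=windows, W=W, step=step, gc=null.gc, L=null.L,
        max_ambig_frac=max_ambig_frac,
    )


def record_cm(esa: EnhancedSuffixArray, null: NullModel, identifier: str) -> float:
    """Cm of one whole record (window = the record, Ci = 2/record length)."""
    f = factorize(esa, identifier)
    Lr = f.length
    Co = f.n_factors / Lr
    Ci = 2.0 / Lr
    from .nullmodel import cm_value

    return cm_value(Co, Ci, null.Ca)


def call_intervals(
    profile: WindowProfile, threshold: float
) -> list[ComplexityInterval]:
    """Merge windows with Cm >= threshold into maximal disjoint intervals.

    Overlapping or book-ended qualifying windows (next start <= current end
    + 1) join the same interval; undefined windows never qualify.
    """
    df = profile.defined()
    df = df[df["cm"] >= threshold]
    out: list[ComplexityInterval] = []
    for rec, grp in df.groupby("record", sort=False):
        grp = grp.sort_values("start")
        cur_start = cur_end = None
        cur_n = 0
        cur_max = -np.inf
        for start, end, cm in zip(grp["start"], grp["end"], grp["cm"]):
            if cur_start is None or start > cur_end + 1:
                if cur_start is not None:
                    out.append(
                        ComplexityInterval(rec, int(cur_start), int(cur_end), cur_n, float(cur_max))
                    )
                cur_start, cur_end, cur_n, cur_max = start, end, 1, cm
            else:
                cur_end = max(cur_end, end)
                cur_n += 1
                cur_max = max(cur_max, cm)
        if cur_start is not None:
            out.append(
                ComplexityInterval(rec, int(cur_start), int(cur_end), cur_n, float(cur_max))
            )
    profile.threshold = threshold
    n_win = sum(iv.n_windows for iv in out)
    logger.info(
        "%d qualifying windows merged into %d high-complexity intervals",
        n_win, len(out),
    )
    return out


def _as_triples(intervals) -> list[tuple[str, int, int]]:
    out = []
    for iv in intervals:
        if isinstance(iv, ComplexityInterval):
            out.append((iv.record, iv.start, iv.end))
        else:
            rec, start, end = iv[0], int(iv[1]), int(iv[2])
            out.append((rec, start, end))
    return out


def intersect_fraction(a, b) -> float:
    """Fraction of a-intervals sharing >= 1 base with some b-interval.

    Intervals are (record, start, end) triples or :class:`ComplexityInterval`
    objects, 1-based inclusive.  b-records absent from a's record set are
    simply never matched; a-records absent from b trigger a debug note and
    count as non-intersecting.
    """
    a = _as_triples(a)
    b = _as_triples(b)
    if not a:
        return 0.0
    by_rec: dict[str, list[tuple[int, int]]] = {}
    for rec, s, e in b:
        by_rec.setdefault(rec, []).append((s, e))
    a_recs = {rec for rec, _, _ in a}
    for rec in sorted(set(by_rec) - a_recs):
        logger.warning("record %s present only in b intervals: ignored", rec)
    hits = 0
    for rec, s, e in a:
        ivs = by_rec.get(rec)
        if not ivs:
            continue
        starts = np.array(sorted(x[0] for x in ivs))
        ends_sorted_by_start = np.array([x[1] for x in sorted(ivs)])
        cummax_end = np.maximum.accumulate(ends_sorted_by_start)
        k = np.searchsorted(starts, e, side="right")
        if k > 0 and cummax_end[k - 1] >= s:
            hits += 1
    return hits / len(a)


def intervals_to_bed(intervals: list[ComplexityInterval], path: str | Path) -> None:
    """BED6 (0-based half-open) of called intervals; score = 1000 * max Cm capped."""
    with open(path, "w") as fh:
        for k, iv in enumerate(intervals, start=1):
            score = int(min(1000, max(0, round(1000 * iv.max_cm))))
            fh.write(f"{iv.record}\t{iv.start - 1}\t{iv.end}\thcr_{k}\t{score}\t.\n")


def read_bed(path: str | Path) -> list[tuple[str, int, int]]:
    """Read BED intervals (0-based half-open) as 1-based inclusive triples."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("track", "browser", "#")):
                continue
            parts = line.split("\t")
            out.append((parts[0], int(parts[1]) + 1, int(parts[2])))
    return out
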