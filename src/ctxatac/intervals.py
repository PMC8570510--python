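"""Genomic interval algebra and BED/narrowPeak I/O.

All coordinates are 0-based half-open (BED convention) everywhere inside the
package; 1-based positions (GWAS catalog, VCF-style tables) are converted at
ingest and converted back on export.  Overlap rules are strand-agnostic:
strand, where present in a BED6/narrowPeak file, is carried as metadata only.

Book-ended intervals (end == start of the next) merge, matching the default
behaviour of ``bedtools merge``.
"""

from __future__ import annotations

import math
from bisect import bisect_left
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "ScoredInterval",
    "merge_intervals",
    "overlap_pairs",
    "overlap_fraction",
    "read_bed",
    "write_bed",
    "read_narrowpeak",
    "write_narrowpeak",
]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval ``[start, end)`` on ``chrom``.

    ``id`` is an optional stable label and does not participate in ordering.
    ``strand`` is metadata only and is ignored by every overlap rule.
    """

    chrom: str
    start: int
    end: int
    id: Optional[str] = field(default=None, compare=False)
    strand: Optional[str] = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError(f"interval {self.id or ''}: empty chromosome name")
        if self.start < 0:
            raise ValueError(
                f"interval {self.id or self.chrom}: negative start {self.start}"
            )
        if self.end <= self.start:
            raise ValueError(
                f"interval {self.id or self.chrom}:{self.start}-{self.end}: "
                "end must be greater than start"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlap_bp(self, other: "GenomicInterval") -> int:
        """Shared bases with ``other`` (0 if different chrom or disjoint)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains_position(self, chrom: str, pos: int) -> bool:
        """True if the 0-based position lies inside the interval."""
        return chrom == self.chrom and self.start <= pos < self.end


@dataclass(frozen=True)
class ScoredInterval:
    """An interval carrying a peak-calling p-value and its source replicate."""

    interval: GenomicInterval
    score: float
    source: Optional[str] = None

    def __post_init__(self) -> None:
        if not (0.0 < self.score <= 1.0) or math.isnan(self.score):
            raise ValueError(
                f"peak {self.interval.id or self.interval.chrom}: "
                f"p-value score {self.score} outside (0, 1]"
            )


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Merge overlapping or book-ended intervals into a minimal disjoint set.

    Output is sorted by (chrom, start).  Input ids are not propagated; merged
    regions are anonymous until relabelled by the caller.
    """
    ivs = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    merged: list[GenomicInterval] = []
    for iv in ivs:
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end:
            last = merged[-1]
            if iv.end > last.end:
                merged[-1] = GenomicInterval(last.chrom, last.start, iv.end)
        else:
            merged.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return merged


class _ChromIndex:
    """Per-chromosome start-sorted index supporting overlap scans."""

    def __init__(self, intervals: Sequence[GenomicInterval]):
        self.by_chrom: dict[str, tuple[list[int], list[GenomicInterval]]] = {}
        self.max_len: dict[str, int] = {}
        tmp: dict[str, list[GenomicInterval]] = {}
        for iv in intervals:
            tmp.setdefault(iv.chrom, []).append(iv)
        for chrom, ivs in tmp.items():
            ivs.sort(key=lambda iv: (iv.start, iv.end))
            self.by_chrom[chrom] = ([iv.start for iv in ivs], ivs)
            self.max_len[chrom] = max(len(iv) for iv in ivs)

    def overlapping(self, query: GenomicInterval) -> list[GenomicInterval]:
        entry = self.by_chrom.get(query.chrom)
        if entry is None:
            return []
        starts, ivs = entry
        lo = bisect_left(starts, query.start - self.max_len[query.chrom])
        hi = bisect_left(starts, query.end)
        return [iv for iv in ivs[lo:hi] if iv.end > query.start]


def overlap_pairs(
    query: Sequence[GenomicInterval],
    subject: Sequence[GenomicInterval],
    min_bases: int = 1,
) -> list[tuple[str, str, int]]:
    """All (query id, subject id, shared bp) pairs sharing >= ``min_bases``.

    Intervals without an explicit ``id`` are labelled by their position in the
    input list (``"q<i>"`` / ``"s<i>"``).
    """
    if min_bases < 1:
        raise ValueError("min_bases must be >= 1")
    subj = [
        iv if iv.id is not None else GenomicInterval(iv.chrom, iv.start, iv.end, f"s{i}")
        for i, iv in enumerate(subject)
    ]
    index = _ChromIndex(subj) if subj else None
    out: list[tuple[str, str, int]] = []
    for i, q in enumerate(query):
        qid = q.id if q.id is not None else f"q{i}"
        if index is None:
            continue
        for s in index.overlapping(q):
            bp = q.overlap_bp(s)
            if bp >= min_bases:
                out.append((qid, s.id, bp))
    return out


def overlap_fraction(
    set_a: Sequence[GenomicInterval], annotation: Sequence[GenomicInterval]
) -> float:
    """Percentage of ``set_a`` intervals sharing >= 1 base with the annotation."""
    if not set_a:
        raise ValueError("overlap_fraction undefined for an empty query set")
    index = _ChromIndex(list(annotation)) if annotation else None
    hit = 0
    for iv in set_a:
        if index is not None and index.overlapping(iv):
            hit += 1
    return 100.0 * hit / len(set_a)


# ---------------------------------------------------------------------------
# BED / narrowPeak I/O (tab-separated, headerless; outputs sorted)
# ---------------------------------------------------------------------------

def read_bed(path) -> list[GenomicInterval]:
    """Read BED3/BED6; extra columns beyond 6 are ignored."""
    df = pd.read_csv(path, sep="\t", header=None, dtype={0: str}, comment="#")
    out = []
    for row in df.itertuples(index=False):
        name = str(row[3]) if len(row) > 3 and not pd.isna(row[3]) else None
        strand = str(row[5]) if len(row) > 5 and row[5] in ("+", "-") else None
        out.append(GenomicInterval(str(row[0]), int(row[1]), int(row[2]), name, strand))
    return out


def write_bed(intervals: Sequence[GenomicInterval], path, scores=None) -> None:
    """Write BED3 (or BED6 when ids are present); sorted by (chrom, start)."""
    order = sorted(range(len(intervals)), key=lambda i: (intervals[i].chrom, intervals[i].start))
    with open(path, "w") as fh:
        for i in order:
            iv = intervals[i]
            if iv.id is None and scores is None:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
            else:
                score = 0 if scores is None else scores[i]
                strand = iv.strand or "."
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.id or '.'}\t{score}\t{strand}\n"
                )


def read_narrowpeak(path, source: Optional[str] = None) -> list[ScoredInterval]:
    """Read ENCODE narrowPeak; column 8 (-log10 p) is converted to a p-value."""
    df = pd.read_csv(path, sep="\t", header=None, dtype={0: str})
    if df.shape[1] < 8:
        raise ValueError(f"{path}: narrowPeak requires >= 8 columns")
    out = []
    for row in df.itertuples(index=False):
        iv = GenomicInterval(
            str(row[0]), int(row[1]), int(row[2]),
            str(row[3]) if not pd.isna(row[3]) else None,
            str(row[5]) if row[5] in ("+", "-") else None,
        )
        p = 10.0 ** (-float(row[7]))
        out.append(ScoredInterval(iv, min(p, 1.0), source))
    return out


def write_narrowpeak(peaks: Sequence[ScoredInterval], path) -> None:
    rows = sorted(peaks, key=lambda sp: (sp.interval.chrom, sp.interval.start))
    with open(path, "w") as fh:
        for sp in rows:
            iv = sp.interval
            neglog_p = -math.log10(sp.score) if sp.score > 0 else 999.0
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.id or '.'}\t0\t"
                f"{iv.strand or '.'}\t0.0\t{neglog_p:.6g}\t-1\t-1\n"
            )
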