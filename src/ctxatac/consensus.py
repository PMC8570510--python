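"""Consensus peak construction across replicates, days, and tissue samples.

Per-day consensus peaks are merged regions supported by strictly more than
half of the replicates (e.g. at least 3/5 or 6/10); they are ranked by the
median of per-replicate best peak p-values (replicates without an overlapping
peak contribute p = 1), truncated to the top K, and unioned across days into
the merged test set used for differential accessibility.  The multi-sample
tissue consensus keeps merged union peaks seen in at least ``min_samples``
distinct samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import median
from typing import Mapping, Sequence

from .intervals import (
    GenomicInterval,
    ScoredInterval,
    _ChromIndex,
    merge_intervals,
)

__all__ = [
    "ConsensusPeak",
    "per_day_consensus",
    "rank_by_median_p",
    "top_k",
    "cross_day_union",
    "tissue_consensus",
]


@dataclass
class ConsensusPeak:
    interval: GenomicInterval
    label: str  # day or cohort
    n_supporting: int
    median_p: float | None = None
    supporting: frozenset[str] = field(default_factory=frozenset)


def _support_counts(
    merged: Sequence[GenomicInterval],
    replicate_peaks: Mapping[str, Sequence[ScoredInterval]],
) -> list[frozenset[str]]:
    """For each merged region, the set of sources with >= 1 overlapping peak."""
    indexes = {
        rep: _ChromIndex([sp.interval for sp in peaks]) if peaks else None
        for rep, peaks in replicate_peaks.items()
    }
    out = []
    for region in merged:
        supp = frozenset(
            rep
            for rep, idx in indexes.items()
            if idx is not None and idx.overlapping(region)
        )
        out.append(supp)
    return out


def per_day_consensus(
    replicate_peaks: Mapping[str, Sequence[ScoredInterval]],
    min_frac: float = 0.5,
    label: str = "",
) -> list[ConsensusPeak]:
    """Merged union peaks supported by strictly > ``min_frac`` of replicates."""
    if len(replicate_peaks) < 2:
        raise ValueError("per-day consensus requires >= 2 replicates")
    n_reps = len(replicate_peaks)
    union = [sp.interval for peaks in replicate_peaks.values() for sp in peaks]
    merged = merge_intervals(union)
    out = []
    for region, supp in zip(merged, _support_counts(merged, replicate_peaks)):
        if len(supp) / n_reps > min_frac:
            out.append(ConsensusPeak(region, label, len(supp), supporting=supp))
    return out


def rank_by_median_p(
    consensus: Sequence[ConsensusPeak],
    replicate_peaks: Mapping[str, Sequence[ScoredInterval]],
    best_per_replicate: bool = True,
) -> list[ConsensusPeak]:
    """Rank consensus peaks ascending by median per-replicate peak p-value.

    Each replicate contributes its smallest p among peaks overlapping the
    consensus region (p = 1 when it has none); the median is taken over ALL
    replicates.  ``best_per_replicate=False`` instead pools every overlapping
    peak p-value from every replicate into the median (alternative reading).
    Ties are broken by (chrom, start) so ranking is deterministic.
    """
    indexes = {}
    pmaps = {}
    for rep, peaks in replicate_peaks.items():
        ivs = []
        pmap = {}
        for i, sp in enumerate(peaks):
            iv = sp.interval
            key = iv.id if iv.id is not None else f"{rep}:{i}"
            iv = GenomicInterval(iv.chrom, iv.start, iv.end, key)
            ivs.append(iv)
            pmap[key] = sp.score
        indexes[rep] = _ChromIndex(ivs) if ivs else None
        pmaps[rep] = pmap
    ranked = []
    for cp in consensus:
        values = []
        for rep in replicate_peaks:
            idx = indexes[rep]
            hits = idx.overlapping(cp.interval) if idx is not None else []
            ps = [pmaps[rep][iv.id] for iv in hits]
            if best_per_replicate:
                values.append(min(ps) if ps else 1.0)
            else:
                values.extend(ps if ps else [1.0])
        ranked.append(
            ConsensusPeak(
                cp.interval, cp.label, cp.n_supporting,
                float(median(values)), cp.supporting,
            )
        )
    ranked.sort(key=lambda cp: (cp.median_p, cp.interval.chrom, cp.interval.start))
    return ranked


def top_k(ranked: Sequence[ConsensusPeak], k: int = 100_000) -> list[ConsensusPeak]:
    """First min(k, n) peaks of an already-ranked list."""
    if k < 0:
        raise ValueError("k must be >= 0")
    return list(ranked[:k])


def cross_day_union(
    top_sets: Mapping[str, Sequence[ConsensusPeak]]
) -> list[ConsensusPeak]:
    """Merge the per-day top peaks into one test set, recording source days."""
    if not top_sets:
        raise ValueError("cross-day union requires >= 1 day")
    union = [cp.interval for peaks in top_sets.values() for cp in peaks]
    merged = merge_intervals(union)
    day_peaks = {
        day: [ScoredInterval(cp.interval, cp.median_p or 1.0) for cp in peaks]
        for day, peaks in top_sets.items()
    }
    out = []
    for i, (region, days) in enumerate(
        zip(merged, _support_counts(merged, day_peaks))
    ):
        region = GenomicInterval(region.chrom, region.start, region.end, f"mpeak{i:06d}")
        out.append(ConsensusPeak(region, "+".join(sorted(days)), len(days), supporting=days))
    return out


def tissue_consensus(
    sample_peaks: Mapping[str, Sequence[ScoredInterval]],
    min_samples: int = 3,
) -> list[ConsensusPeak]:
    """Merged union peaks present in >= ``min_samples`` distinct samples."""
    if len(sample_peaks) < min_samples:
        raise ValueError("fewer samples than min_samples")
    union = [sp.interval for peaks in sample_peaks.values() for sp in peaks]
    merged = merge_intervals(union)
    out = []
    for region, supp in zip(merged, _support_counts(merged, sample_peaks)):
        if len(supp) >= min_samples:
            out.append(ConsensusPeak(region, "tissue", len(supp), supporting=supp))
    return out
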