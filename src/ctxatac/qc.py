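"""ATAC-seq library quality control.

Implements the signal-to-noise metrics used to admit libraries into the
analysis: a TSS-enrichment statistic computed on 2,001-bp windows centred on
housekeeping transcription start sites, the fraction of reads in peaks (FRiP),
per-library pass/fail rules, and a PCA + hierarchical-clustering outlier
screen over a count matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .intervals import GenomicInterval, _ChromIndex

__all__ = [
    "LibraryQC",
    "tss_enrichment",
    "window_coverage",
    "frip",
    "qc_filter",
    "detect_outliers",
]

WINDOW_WIDTH = 2001  # TSS +/- 1 kb
_FLANK = 100  # flank positions per window end used as background


@dataclass
class LibraryQC:
    library: str
    frip: float
    tss_enrichment: float
    passed: bool | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.frip <= 1.0):
            raise ValueError(f"{self.library}: FRiP {self.frip} outside [0, 1]")


def tss_enrichment(cov: np.ndarray, flank_mode: str = "per_end") -> float:
    """Center-over-flank coverage ratio on TSS windows.

    ``cov`` is a (windows x 2001) matrix of per-base read coverage, each row a
    window centred on a TSS with 1 kb flanks.  Coverage is summed across
    windows per position; the value at the centre position (index 1000) is
    divided by the mean over the flank positions.

    ``flank_mode='per_end'`` (default) uses 100 positions at each end (200
    total); ``'total'`` uses 100 positions total, 50 at each end.  The
    statistic is invariant to scaling all coverage by a positive constant.
    """
    cov = np.asarray(cov, dtype=float)
    if cov.ndim != 2 or cov.shape[1] != WINDOW_WIDTH:
        raise ValueError(f"coverage matrix must be windows x {WINDOW_WIDTH}")
    if cov.shape[0] < 1:
        raise ValueError("need at least one TSS window")
    if (cov < 0).any():
        raise ValueError("coverage must be non-negative")
    v = cov.sum(axis=0)
    half = _FLANK if flank_mode == "per_end" else _FLANK // 2
    if flank_mode not in ("per_end", "total"):
        raise ValueError(f"unknown flank_mode {flank_mode!r}")
    flanks = np.concatenate([v[:half], v[-half:]])
    background = flanks.mean()
    if background <= 0:
        raise ValueError("all-zero flanks: TSS enrichment undefined")
    return float(v[WINDOW_WIDTH // 2] / background)


def window_coverage(
    reads: Sequence[GenomicInterval],
    tss: Sequence[tuple[str, int]],
    flank: int = 1000,
) -> np.ndarray:
    """Per-base read coverage on (2*flank+1)-bp windows centred on each TSS."""
    width = 2 * flank + 1
    cov = np.zeros((len(tss), width))
    index = _ChromIndex(list(reads)) if reads else None
    for w, (chrom, pos) in enumerate(tss):
        if index is None:
            continue
        window = GenomicInterval(chrom, max(0, pos - flank), pos + flank + 1)
        for r in index.overlapping(window):
            lo = max(r.start, window.start) - (pos - flank)
            hi = min(r.end, window.end) - (pos - flank)
            cov[w, max(lo, 0) : hi] += 1
    return cov


def frip(
    reads: Sequence[GenomicInterval], peaks: Sequence[GenomicInterval]
) -> float:
    """Fraction of reads sharing >= 1 base with any peak."""
    if not reads:
        raise ValueError("FRiP undefined for an empty read set")
    index = _ChromIndex(list(peaks)) if peaks else None
    if index is None:
        return 0.0
    hit = sum(1 for r in reads if index.overlapping(r))
    return hit / len(reads)


def qc_filter(libs: Sequence[LibraryQC], ruleset: str) -> list[LibraryQC]:
    """Apply the per-cohort pass rule and return libraries with flags set.

    ``sgbs``: FRiP > 0.20 AND TSS enrichment > 5 (both strict).
    ``tissue``: TSS enrichment >= 4 (weak inequality).
    """
    if ruleset == "sgbs":
        rule = lambda lib: lib.frip > 0.20 and lib.tss_enrichment > 5
    elif ruleset == "tissue":
        rule = lambda lib: lib.tss_enrichment >= 4
    else:
        raise ValueError(f"unknown QC ruleset {ruleset!r}")
    out = []
    for lib in libs:
        out.append(LibraryQC(lib.library, lib.frip, lib.tss_enrichment, rule(lib)))
    return out


def detect_outliers(
    counts: pd.DataFrame,
    n_pcs: int = 10,
    cut_height: float = 50.0,
) -> list[str]:
    """Flag outlier samples by hierarchical clustering in top-PC space.

    Counts (features x samples) are depth-normalised per sample, log2(x+1)
    transformed and feature-centred; samples are projected onto the top
    ``n_pcs`` principal components and clustered (Euclidean, complete
    linkage).  Cutting the dendrogram at ``cut_height`` partitions the
    samples; every sample outside the largest cluster is flagged.
    """
    if counts.shape[1] < 3:
        raise ValueError("outlier detection requires >= 3 samples")
    y = counts.to_numpy(dtype=float)
    depth = y.sum(axis=0)
    if (depth <= 0).any():
        raise ValueError("sample with zero total count")
    norm = np.log2(y / depth * np.median(depth) + 1.0)
    centered = (norm - norm.mean(axis=1, keepdims=True)).T  # samples x features
    max_pcs = min(centered.shape)
    if n_pcs > max_pcs:
        warnings.warn(
            f"n_pcs={n_pcs} exceeds min(samples, features)={max_pcs}; clipping"
        )
        n_pcs = max_pcs
    # PCA via SVD of the sample-centred matrix
    centered = centered - centered.mean(axis=0, keepdims=True)
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    scores = centered @ vt[:n_pcs].T
    z = linkage(pdist(scores), method="complete")
    labels = fcluster(z, t=cut_height, criterion="distance")
    sizes = np.bincount(labels)
    main = int(np.argmax(sizes))  # largest cluster; ties -> smallest label
    samples = list(counts.columns)
    return [samples[i] for i in range(len(samples)) if labels[i] != main]
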