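"""GWAS catalog filtering, trait-agnostic LD clumping, and EFO-term counting.

The catalog is reduced to genome-wide significant (p < 5e-8), single-SNV,
biallelic records.  Clumping is trait-agnostic: each variant keeps its single
most significant p across traits, and a variant is removed when another
variant with a strictly more significant p (ties broken by (chrom, pos) so
results are deterministic) lies within 1 Mb and in strong LD (r^2 > 0.8,
haplotype panel).  Survivors are the LD-distinct signal leads; each lead is
expanded to its proxy set (r^2 > 0.8, lead included).  EFO-term counts are
normalised per term as 100 * (signals overlapping peaks carrying the term) /
(all signals carrying the term), after removing traits mapped to >= 5 EFO
terms and counting each term at most once per signal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, _ChromIndex

__all__ = [
    "HaplotypePanel",
    "ClumpedSignal",
    "filter_catalog",
    "compute_r2",
    "ld_clump",
    "expand_proxies",
    "overlap_signals_with_peaks",
    "efo_normalized_counts",
    "GWAS_P_THRESHOLD",
]

logger = logging.getLogger(__name__)

GWAS_P_THRESHOLD = 5e-8
R2_THRESHOLD = 0.8
CLUMP_WINDOW = 1_000_000


class HaplotypePanel:
    """Phased 0/1 haplotypes for a variant set with genomic positions.

    ``haplotypes`` is variants x haplotypes; ``positions`` maps variant id to
    (chrom, 0-based pos).
    """

    def __init__(self, haplotypes: pd.DataFrame, positions: Mapping[str, tuple[str, int]]):
        arr = haplotypes.to_numpy()
        if not np.isin(arr, (0, 1)).all():
            raise ValueError("haplotype entries must be 0/1")
        if haplotypes.shape[1] < 2:
            raise ValueError("panel requires >= 2 haplotypes")
        self.haplotypes = haplotypes
        self.positions = dict(positions)

    def __contains__(self, variant: str) -> bool:
        return variant in self.haplotypes.index

    def alleles(self, variant: str) -> np.ndarray:
        return self.haplotypes.loc[variant].to_numpy(dtype=float)


@dataclass
class ClumpedSignal:
    lead: str
    chrom: str
    pos: int
    best_p: float
    # catalog rows (variant, trait, p) collapsed under this lead
    members: list[tuple[str, str, float]] = field(default_factory=list)
    proxies: list[tuple[str, float]] = field(default_factory=list)  # (variant, r2)

    @property
    def traits(self) -> set[str]:
        return {t for _, t, _ in self.members}


def filter_catalog(
    records: pd.DataFrame, allele_counts: Mapping[str, int] | None = None
) -> pd.DataFrame:
    """Keep single-SNV, biallelic, p < 5e-8 catalog rows.

    ``records`` needs columns rsid, chrom, pos, trait, p, ref, alt.  Rows
    whose rsid is not a single ``rs<digits>`` token (haplotype or
    variant-variant interaction entries) or whose alleles are not single
    bases are dropped; ``allele_counts`` (variant -> number of known alleles)
    drops multiallelic variants.  Unparseable positions are dropped and
    counted in the log.
    """
    df = records.copy()
    n0 = len(df)
    pos = pd.to_numeric(df["pos"], errors="coerce")
    bad_pos = pos.isna()
    if bad_pos.any():
        logger.info("dropped %d records with unparseable positions", bad_pos.sum())
    df = df[~bad_pos].assign(pos=pos[~bad_pos].astype(int))
    single = df["rsid"].astype(str).str.fullmatch(r"rs\d+")
    snv = df["ref"].astype(str).str.fullmatch("[ACGT]") & df["alt"].astype(str).str.fullmatch("[ACGT]")
    keep = single & snv & (df["p"] < GWAS_P_THRESHOLD)
    if allele_counts is not None:
        keep &= df["rsid"].map(lambda r: allele_counts.get(r, 2) == 2)
    out = df[keep].reset_index(drop=True)
    logger.info("catalog filter kept %d of %d records", len(out), n0)
    return out


def compute_r2(panel: HaplotypePanel, v1: str, v2: str) -> float:
    """Haplotype r^2 = (p11 - p1*q1)^2 / (p1(1-p1) q1(1-q1))."""
    a = panel.alleles(v1)
    b = panel.alleles(v2)
    p1, q1 = a.mean(), b.mean()
    if p1 in (0.0, 1.0) or q1 in (0.0, 1.0):
        raise ValueError(f"monomorphic variant in r^2({v1}, {v2})")
    p11 = (a * b).mean()
    return float((p11 - p1 * q1) ** 2 / (p1 * (1 - p1) * q1 * (1 - q1)))


def _r2_safe(panel: HaplotypePanel, v1: str, v2: str) -> float:
    """r^2 treating absent or monomorphic variants as unlinked (r^2 = 0)."""
    if v1 not in panel or v2 not in panel:
        return 0.0
    try:
        return compute_r2(panel, v1, v2)
    except ValueError:
        return 0.0


def ld_clump(
    records: pd.DataFrame,
    panel: HaplotypePanel,
    r2_thresh: float = R2_THRESHOLD,
    window: int = CLUMP_WINDOW,
) -> list[ClumpedSignal]:
    """Trait-agnostic pairwise LD clumping of a filtered catalog.

    Per variant the most significant p across traits is kept; a variant is
    removed iff some variant with a strictly smaller ordering key
    (p, chrom, pos) lies within ``window`` bp (inclusive, same chromosome)
    and has r^2 > ``r2_thresh`` with it.  Removed variants become members of
    the best-keyed surviving variant that removed them (following the
    removal chain when that remover itself was removed).  Variants absent
    from the panel are treated as unlinked to everything (logged).
    """
    per_variant = (
        records.sort_values(["p", "chrom", "pos"], kind="stable")
        .groupby("rsid", sort=False)
        .first()
        .reset_index()
    )
    absent = [r for r in per_variant["rsid"] if r not in panel]
    if absent:
        logger.info("%d clump variants absent from panel; treated as r^2=0", len(absent))
    rows = per_variant.sort_values(["p", "chrom", "pos"], kind="stable").reset_index(drop=True)
    n = len(rows)
    rsids = rows["rsid"].tolist()
    chroms = rows["chrom"].tolist()
    positions = rows["pos"].to_numpy()
    # best remover (smallest ordering key) for each removed variant
    removed_by = np.full(n, -1)
    for i in range(n):
        for j in range(i):  # j has strictly smaller key than i
            if chroms[j] != chroms[i] or abs(int(positions[j]) - int(positions[i])) > window:
                continue
            # equal-p ties: the (p, chrom, pos) ordering makes the earlier-
            # keyed variant the remover, so results are deterministic
            if _r2_safe(panel, rsids[i], rsids[j]) > r2_thresh:
                removed_by[i] = j
                break  # j iterates in ascending key order; first hit is best
    survives = removed_by < 0

    def resolve_lead(i: int) -> int:
        while removed_by[i] >= 0:
            i = removed_by[i]
        return i

    signals: dict[int, ClumpedSignal] = {}
    trait_rows = records.groupby("rsid")
    for i in range(n):
        if survives[i]:
            signals[i] = ClumpedSignal(
                rsids[i], chroms[i], int(positions[i]), float(rows.loc[i, "p"])
            )
    for i in range(n):
        lead_i = resolve_lead(i)
        sig = signals[lead_i]
        for _, row in trait_rows.get_group(rsids[i]).iterrows():
            sig.members.append((rsids[i], row["trait"], float(row["p"])))
    out = sorted(signals.values(), key=lambda s: (s.chrom, s.pos))
    for sig in out:
        if sig.lead in panel:
            try:
                sig.proxies = expand_proxies(sig.lead, panel, r2_thresh)
            except ValueError:
                sig.proxies = [(sig.lead, 1.0)]
        else:
            sig.proxies = [(sig.lead, 1.0)]
    return out


def expand_proxies(
    lead: str, panel: HaplotypePanel, r2_thresh: float = R2_THRESHOLD
) -> list[tuple[str, float]]:
    """All panel variants with r^2 > threshold to the lead; lead included."""
    if lead not in panel:
        raise ValueError(f"lead {lead} absent from panel")
    a = panel.alleles(lead)
    p1 = a.mean()
    if p1 in (0.0, 1.0):
        raise ValueError(f"monomorphic lead {lead}")
    hap = panel.haplotypes.to_numpy(dtype=float)
    q = hap.mean(axis=1)
    poly = (q > 0) & (q < 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        p11 = (hap * a).mean(axis=1)
        r2 = (p11 - p1 * q) ** 2 / (p1 * (1 - p1) * q * (1 - q))
    out = [(lead, 1.0)]
    for vid, ok, val in zip(panel.haplotypes.index, poly, r2):
        if vid != lead and ok and val > r2_thresh:
            out.append((vid, float(val)))
    return out


def overlap_signals_with_peaks(
    signals: Sequence[ClumpedSignal],
    peaks: Sequence[GenomicInterval],
    panel: HaplotypePanel,
) -> list[tuple[str, str, str]]:
    """(signal lead, peak id, proxy) hits: proxy position inside the peak."""
    index = _ChromIndex(list(peaks)) if peaks else None
    hits = []
    if index is None:
        return hits
    for sig in signals:
        for proxy, _ in sig.proxies:
            loc = panel.positions.get(proxy)
            if loc is None:
                continue
            probe = GenomicInterval(loc[0], loc[1], loc[1] + 1)
            for pk in index.overlapping(probe):
                hits.append((sig.lead, pk.id, proxy))
    return hits


def efo_normalized_counts(
    signals: Sequence[ClumpedSignal],
    overlapping_leads: set[str],
    trait_efo: Mapping[str, Sequence[str]],
    min_total: int = 100,
    top_n: int = 10,
) -> pd.DataFrame:
    """Normalised EFO-term counts: 100 * overlap / total per term.

    Traits mapping to >= 5 EFO terms are removed before counting; each term
    counts at most once per signal (across all member trait associations).
    The ranking column restricts to terms with total >= ``min_total``; the
    returned frame is sorted by normalised count with a ``top`` flag on the
    first ``top_n`` rank-eligible terms.
    """
    usable = {t: set(terms) for t, terms in trait_efo.items() if len(set(terms)) < 5}
    total: dict[str, int] = {}
    overlap: dict[str, int] = {}
    for sig in signals:
        terms: set[str] = set()
        for _, trait, _ in sig.members:
            terms |= usable.get(trait, set())
        for term in terms:
            total[term] = total.get(term, 0) + 1
            if sig.lead in overlapping_leads:
                overlap[term] = overlap.get(term, 0) + 1
    for term in overlap:
        assert term in total, "term in overlap subset but not catalog"
    rows = []
    for term, tot in total.items():
        ov = overlap.get(term, 0)
        rows.append(
            {
                "term": term,
                "total": tot,
                "overlap": ov,
                "normalized": 100.0 * ov / tot,
                "rank_eligible": tot >= min_total,
            }
        )
    df = pd.DataFrame(rows, columns=["term", "total", "overlap", "normalized", "rank_eligible"])
    df = df.sort_values(["normalized", "term"], ascending=[False, True]).reset_index(drop=True)
    df["top"] = False
    eligible_idx = df.index[df["rank_eligible"]][:top_n]
    df.loc[eligible_idx, "top"] = True
    return df
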