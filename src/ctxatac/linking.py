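"""Linking context-dependent peaks to candidate genes.

Three lines of evidence are combined per (peak, gene) pair: physical contact
(promoter-capture Hi-C fragments; a peak overlapping the non-bait "other end"
of a bait-other loop, or either end of a bait-bait loop, links to the gene(s)
promoted on the opposite end), genetic association (an eQTL proxy variant in
strong LD with a signal lead, r^2 > 0.8, falling inside the peak), and
differential expression of the linked gene (supporting evidence only - DE
never creates a link by itself).  Pairs supported by two or more lines are
the high-confidence set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .intervals import GenomicInterval, _ChromIndex

__all__ = [
    "HiCPair",
    "EQTLSignal",
    "PeakGeneLink",
    "classify_hic_pairs",
    "link_by_hic",
    "link_by_eqtl",
    "annotate_de_support",
    "integrate_links",
    "peak_tss_distance",
    "gwas_overlay",
]

logger = logging.getLogger(__name__)


@dataclass
class HiCPair:
    bait: GenomicInterval
    other_end: GenomicInterval
    bait_genes: tuple[str, ...]
    interaction_type: str | None = None  # "bait_bait" | "bait_other"
    opposite_end_genes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.bait_genes:
            raise ValueError("Hi-C pair with no bait gene")


@dataclass
class EQTLSignal:
    gene: str
    lead: str  # variant id
    rank: str  # "primary" | "conditional"
    # (variant id, chrom, 0-based pos, r^2 to lead); the lead is its own proxy
    proxies: tuple[tuple[str, str, int, float], ...] = ()

    def __post_init__(self) -> None:
        if self.rank not in ("primary", "conditional"):
            raise ValueError(f"eQTL signal rank {self.rank!r}")


@dataclass
class PeakGeneLink:
    peak: str
    gene: str
    methods: set[str] = field(default_factory=set)  # subset of {HiC, eQTL, DE}
    best_proxy: tuple[str, float] | None = None  # (variant, r^2)
    hic_types: set[str] = field(default_factory=set)
    in_peak_variants: list[tuple[str, float]] = field(default_factory=list)

    @property
    def n_methods(self) -> int:
        return len(self.methods)


def classify_hic_pairs(
    pairs: Sequence[HiCPair], bait_fragments: Sequence[GenomicInterval]
) -> list[HiCPair]:
    """Type each loop: bait_bait iff the other end covers any bait fragment."""
    index = _ChromIndex(list(bait_fragments)) if bait_fragments else None
    out = []
    for pair in pairs:
        is_bb = index is not None and bool(index.overlapping(pair.other_end))
        out.append(
            HiCPair(
                pair.bait,
                pair.other_end,
                pair.bait_genes,
                "bait_bait" if is_bb else "bait_other",
                pair.opposite_end_genes,
            )
        )
    return out


def link_by_hic(
    peaks: Sequence[GenomicInterval], pairs: Sequence[HiCPair]
) -> list[PeakGeneLink]:
    """Links from >= 1 bp peak/fragment overlap.

    bait-other loops: a peak on the other end links to each bait gene.
    bait-bait loops: a peak on either end links to the gene(s) on the
    opposite end only.
    """
    links: dict[tuple[str, str], PeakGeneLink] = {}
    index = _ChromIndex(list(peaks)) if peaks else None

    def add(peak_id: str, genes: Iterable[str], pair_type: str) -> None:
        for gene in genes:
            link = links.setdefault(
                (peak_id, gene), PeakGeneLink(peak_id, gene, {"HiC"})
            )
            link.hic_types.add(pair_type)

    for pair in pairs:
        if pair.interaction_type not in ("bait_bait", "bait_other"):
            raise ValueError("unclassified Hi-C pair; run classify_hic_pairs first")
        if index is None:
            continue
        if pair.interaction_type == "bait_other":
            for pk in index.overlapping(pair.other_end):
                add(pk.id, pair.bait_genes, "bait_other")
        else:
            for pk in index.overlapping(pair.bait):
                add(pk.id, pair.opposite_end_genes, "bait_bait")
            for pk in index.overlapping(pair.other_end):
                add(pk.id, pair.bait_genes, "bait_bait")
    return list(links.values())


def link_by_eqtl(
    peaks: Sequence[GenomicInterval], signals: Sequence[EQTLSignal]
) -> list[PeakGeneLink]:
    """Links from eQTL proxies (r^2 > 0.8 with the lead) inside a peak.

    The best proxy has the highest r^2; at an exact r^2 tie between a primary
    and a conditional signal of the same gene, the primary signal's proxy
    wins.  All in-peak proxy variants are retained as an annotation list.
    """
    links: dict[tuple[str, str], PeakGeneLink] = {}
    index = _ChromIndex(list(peaks)) if peaks else None
    if index is None:
        return []
    rank_order = {"primary": 0, "conditional": 1}
    for sig in signals:
        for variant, chrom, pos, r2 in sig.proxies:
            if not r2 > 0.8:
                continue
            probe = GenomicInterval(chrom, pos, pos + 1)
            for pk in index.overlapping(probe):
                key = (pk.id, sig.gene)
                link = links.setdefault(
                    key, PeakGeneLink(pk.id, sig.gene, {"eQTL"})
                )
                link.in_peak_variants.append((variant, r2))
                cand = (-r2, rank_order[sig.rank])
                if link.best_proxy is None or cand < link._best_key:
                    link.best_proxy = (variant, r2)
                    link._best_key = cand
    for link in links.values():
        if hasattr(link, "_best_key"):
            del link._best_key
    return list(links.values())


def annotate_de_support(
    links: Sequence[PeakGeneLink], de_genes: Mapping[str, bool] | set
) -> list[PeakGeneLink]:
    """Add the DE method to links whose gene is differential in any comparison.

    ``de_genes`` is either a set of differential gene ids or a gene -> bool
    mapping.  Genes absent from the expression table never gain DE support
    (logged).  DE is only ever added to an existing HiC/eQTL link.
    """
    if not isinstance(de_genes, (set, frozenset)):
        de_set = {g for g, flag in de_genes.items() if flag}
        known = set(de_genes.keys())
    else:
        de_set = set(de_genes)
        known = None
    out = []
    for link in links:
        methods = set(link.methods)
        if link.gene in de_set:
            methods.add("DE")
        elif known is not None and link.gene not in known:
            logger.info("gene %s absent from expression table; no DE support", link.gene)
        new = PeakGeneLink(
            link.peak, link.gene, methods, link.best_proxy,
            set(link.hic_types), list(link.in_peak_variants),
        )
        out.append(new)
    return out


def integrate_links(links: Sequence[PeakGeneLink]) -> dict:
    """Deduplicate to unique (peak, gene) pairs with unioned evidence.

    Returns the merged pair list plus tallies of unique pairs/peaks/genes at
    >= 2 methods and all 3 methods.
    """
    merged: dict[tuple[str, str], PeakGeneLink] = {}
    for link in links:
        key = (link.peak, link.gene)
        if key not in merged:
            merged[key] = PeakGeneLink(
                link.peak, link.gene, set(link.methods),
                link.best_proxy, set(link.hic_types), list(link.in_peak_variants),
            )
        else:
            tgt = merged[key]
            tgt.methods |= link.methods
            tgt.hic_types |= link.hic_types
            tgt.in_peak_variants.extend(link.in_peak_variants)
            if link.best_proxy is not None and (
                tgt.best_proxy is None or link.best_proxy[1] > tgt.best_proxy[1]
            ):
                tgt.best_proxy = link.best_proxy
    pairs = sorted(merged.values(), key=lambda l: (l.peak, l.gene))
    for link in pairs:
        if link.methods == {"DE"}:
            raise AssertionError("link supported by DE alone; invariant violated")
    ge2 = [l for l in pairs if l.n_methods >= 2]
    eq3 = [l for l in pairs if l.n_methods == 3]
    return {
        "pairs": pairs,
        "n_pairs": len(pairs),
        "n_pairs_ge2": len(ge2),
        "n_pairs_eq3": len(eq3),
        "n_peaks": len({l.peak for l in pairs}),
        "n_genes": len({l.gene for l in pairs}),
        "n_peaks_ge2": len({l.peak for l in ge2}),
        "n_genes_ge2": len({l.gene for l in ge2}),
        "n_peaks_eq3": len({l.peak for l in eq3}),
        "n_genes_eq3": len({l.gene for l in eq3}),
    }


def peak_tss_distance(
    links: Sequence[PeakGeneLink],
    peaks: Mapping[str, GenomicInterval],
    tss: Mapping[str, tuple[str, int]],
) -> dict[tuple[str, str], float]:
    """Distance (bp) from a peak's nearest edge to the linked gene's TSS.

    0 when the TSS lies inside the peak; edges are the half-open start and
    end coordinates.  Missing TSS or cross-chromosome pairs give NaN.
    """
    out = {}
    for link in links:
        pk = peaks.get(link.peak)
        entry = tss.get(link.gene)
        if pk is None or entry is None or entry[0] != pk.chrom:
            if entry is None:
                logger.info("no TSS for gene %s", link.gene)
            out[(link.peak, link.gene)] = float("nan")
            continue
        pos = entry[1]
        if pk.start <= pos < pk.end:
            d = 0
        elif pos >= pk.end:
            d = pos - pk.end
        else:
            d = pk.start - pos
        out[(link.peak, link.gene)] = float(d)
    return out


def gwas_overlay(
    links: Sequence[PeakGeneLink],
    gwas_peak_ids: set[str],
    context_class: Mapping[str, str] | None = None,
) -> dict:
    """Restrict pairs to peaks containing >= 1 proxy of a clumped GWAS signal.

    Returns the retained pairs, the >= 2-method subset, and per-context-class
    tallies of unique peaks when classes are supplied.
    """
    hit_pairs = [l for l in links if l.peak in gwas_peak_ids]
    ge2 = [l for l in hit_pairs if l.n_methods >= 2]
    by_class: dict[str, int] = {}
    if context_class is not None:
        for pk in {l.peak for l in ge2}:
            cls = context_class.get(pk, "unknown")
            by_class[cls] = by_class.get(cls, 0) + 1
    return {
        "pairs": hit_pairs,
        "n_pairs": len(hit_pairs),
        "pairs_ge2": ge2,
        "n_pairs_ge2": len(ge2),
        "n_peaks_ge2": len({l.peak for l in ge2}),
        "n_genes_ge2": len({l.gene for l in ge2}),
        "peaks_ge2_by_class": by_class,
    }
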