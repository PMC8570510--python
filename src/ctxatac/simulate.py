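"""Synthetic study generator with planted structure.

Emulates, at desk scale, every input the pipeline consumes: replicate-level
ATAC peak calls with jitter and dropout, NB count matrices with planted
day-dependent log2 fold changes and sample-specific GC bias, an RNA study
with planted differential genes, a phased haplotype panel with LD-block
structure, a GWAS catalog extract with planted LD-distinct leads and proxy
associations, promoter-capture Hi-C pairs and eQTL signals wired to known
peak-gene links, per-library QC read sets, and allele count tables with
planted allelic imbalance.  A GroundTruth object records everything planted
so downstream stages can be scored exactly.

One master seed drives independent child RNG streams per component (fixed
spawn order), so each stage is reproducible in isolation and a full run is
byte-deterministic.

Geometry notes.  True peaks are packed disjoint with a generous minimum gap,
so replicate-call jitter never merges two true peaks and every merged
test-set region maps to exactly one true peak.  Panel LD blocks either live
entirely inside a chosen target peak (planted eQTL / GWAS overlaps - the
block lead is the in-peak variant, so the overlap survives any sampled
r^2) or entirely inside peak-free gaps (no accidental overlaps).  Hi-C
other-end fragments are sub-intervals of their target peak; bait fragments
sit on TSSs placed clear of all peaks.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .gwas import HaplotypePanel, _r2_safe
from .intervals import GenomicInterval, ScoredInterval, write_narrowpeak
from .linking import EQTLSignal, HiCPair

__all__ = ["SimulationConfig", "GroundTruth", "StudyData", "simulate_study", "write_study"]

HIC_DISTANCE_CAP = 1_200_000  # bp; other ends stay within this of the bait TSS
EQTL_DISTANCE_CAP = 1_000_000


@dataclass
class SimulationConfig:
    """Stated world for the synthetic study.

    Defaults give a smoke study (2,000 peaks, 3 days x 5 ATAC replicates)
    that runs end-to-end in about a minute.
    """

    seed: int = 0
    # toy genome
    n_chroms: int = 2
    chrom_length: int = 10_000_000
    # ATAC
    n_peaks: int = 2000
    peak_width: int = 400
    min_gap: int = 800
    replicates_per_day: Mapping[str, int] = field(
        default_factory=lambda: {"D0": 5, "D4": 5, "D14": 5}
    )
    planted_lfc_fraction: float = 0.25
    planted_lfc_value: float = 2.0
    nb_dispersion: float = 0.05
    gc_bias_strength: float = 0.5
    atac_base_mean: float = 150.0
    peak_drop_prob: float = 0.1
    peak_jitter_sd: float = 20.0
    noise_peaks_per_replicate: int = 100
    noise_peak_width: int = 80
    # RNA
    n_genes: int = 200
    rna_replicates_per_day: Mapping[str, int] = field(
        default_factory=lambda: {"D0": 6, "D4": 6, "D14": 4}
    )
    rna_de_fraction: float = 0.2
    rna_lfc: float = 4.0
    rna_base_mean: float = 200.0
    # linking
    n_hic_pairs: int = 80
    bait_bait_fraction: float = 0.1
    link_overlap_fraction: float = 0.3  # intended pairs with both HiC and eQTL
    # haplotype panel / GWAS
    n_panel_blocks: int = 80
    ld_block_size: int = 8
    n_haplotypes: int = 200
    panel_mutation_prob: float = 0.05
    n_gwas_leads: int = 25
    efo_terms: int = 12
    # allelic imbalance
    n_ai_variants: int = 400
    ai_fraction: float = 0.1
    ai_pi: float = 0.8
    ai_depth_mean: float = 60.0
    # QC reads
    qc_reads_per_library: int = 3000

    def __post_init__(self) -> None:
        for name in ("n_chroms", "chrom_length", "n_peaks", "n_genes",
                     "n_haplotypes", "n_panel_blocks", "ld_block_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0.0 < self.ai_pi < 1.0):
            raise ValueError("ai_pi must be in (0, 1)")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        if self.n_haplotypes < 2:
            raise ValueError("panel requires >= 2 haplotypes")
        if self.ld_block_size > self.n_panel_blocks * self.ld_block_size:
            raise ValueError("ld_block_size larger than the variant set")


@dataclass
class GroundTruth:
    """Everything planted, keyed by the emitted identifiers."""

    peaks: pd.DataFrame  # peak_id, chrom, start, end, gc, class, lfc_D0/D4/D14
    de_genes: set[str]
    links: pd.DataFrame  # peak, gene, methods (comma-joined)
    gwas_leads: list[str]
    gwas_peak_ids: set[str]  # peaks intended to contain a GWAS proxy
    ai: pd.DataFrame  # variant, pi, planted, peak_id (or "")


@dataclass
class StudyData:
    config: SimulationConfig
    chrom_names: list[str]
    peaks: list[GenomicInterval]
    gc: pd.Series
    replicate_peaks: dict[str, list[ScoredInterval]]  # "D0_r1" -> peak calls
    atac_counts: pd.DataFrame
    atac_samples: pd.DataFrame
    rna_counts: pd.DataFrame
    rna_samples: pd.DataFrame
    tss: dict[str, tuple[str, int]]
    bait_fragments: list[GenomicInterval]
    hic_pairs: list[HiCPair]
    eqtl_signals: list[EQTLSignal]
    panel: HaplotypePanel
    gwas_catalog: pd.DataFrame
    allele_counts_catalog: dict[str, int]
    trait_efo: dict[str, list[str]]
    allele_counts: pd.DataFrame
    ai_variant_positions: dict[str, tuple[str, int]]
    qc_reads: dict[str, list[GenomicInterval]]
    truth: GroundTruth


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _place_disjoint(rng, n: int, width: int, gap: int, length: int) -> np.ndarray:
    """n sorted non-overlapping starts with >= gap spacing on [0, length)."""
    need = n * (width + gap)
    if need > length:
        raise ValueError(
            f"cannot pack {n} peaks of width {width} (gap {gap}) "
            f"into a {length} bp chromosome"
        )
    slack = length - need
    cuts = np.sort(rng.integers(0, slack + 1, size=n))
    return cuts + np.arange(n) * (width + gap) + gap // 2


class _GapSampler:
    """Sample positions on the toy genome at least ``margin`` from any peak."""

    def __init__(self, peaks: Sequence[GenomicInterval], chrom_names, chrom_length,
                 margin: int = 1500):
        self.margin = margin
        self.gaps: list[tuple[str, int, int]] = []
        by_chrom: dict[str, list[GenomicInterval]] = {c: [] for c in chrom_names}
        for pk in peaks:
            by_chrom[pk.chrom].append(pk)
        for chrom in chrom_names:
            prev = 0
            for pk in sorted(by_chrom[chrom], key=lambda p: p.start):
                lo, hi = prev + margin, pk.start - margin
                if hi > lo:
                    self.gaps.append((chrom, lo, hi))
                prev = pk.end
            lo, hi = prev + margin, chrom_length - margin
            if hi > lo:
                self.gaps.append((chrom, lo, hi))
        self.weights = np.array([hi - lo for _, lo, hi in self.gaps], dtype=float)
        self.weights /= self.weights.sum()

    def sample(self, rng) -> tuple[str, int]:
        i = rng.choice(len(self.gaps), p=self.weights)
        c, lo, hi = self.gaps[i]
        return c, int(rng.integers(lo, hi))


def _nb_draw(rng, mean: np.ndarray, alpha: float) -> np.ndarray:
    lam = rng.gamma(shape=1.0 / alpha, scale=alpha * np.maximum(mean, 1e-12))
    return rng.poisson(lam)


# ---------------------------------------------------------------------------
# component generators
# ---------------------------------------------------------------------------

_CLASS_EFFECTS = {
    # per-day log2 shift applied to the baseline mean
    "preadipocyte_dependent": {"D0": 1.0, "D4": 0.0, "D14": 0.0},
    "adipocyte_dependent": {"D0": 0.0, "D4": 1.0, "D14": 1.0},
    "mature_adipocyte_specific": {"D0": 0.0, "D4": 0.0, "D14": 1.0},
    "other_context_dependent": {"D0": 0.0, "D4": 1.0, "D14": 0.0},
    "non_differential": {"D0": 0.0, "D4": 0.0, "D14": 0.0},
}
_CLASS_SPLIT = (
    ("preadipocyte_dependent", 0.35),
    ("adipocyte_dependent", 0.35),
    ("mature_adipocyte_specific", 0.10),
    ("other_context_dependent", 0.20),
)


def simulate_atac_study(cfg: SimulationConfig, rng, chrom_names):
    """Peaks, per-replicate calls, count matrix, GC table, and peak truth."""
    per_chrom = np.full(cfg.n_chroms, cfg.n_peaks // cfg.n_chroms)
    per_chrom[: cfg.n_peaks % cfg.n_chroms] += 1
    peaks: list[GenomicInterval] = []
    for c, n_c in zip(chrom_names, per_chrom):
        starts = _place_disjoint(rng, int(n_c), cfg.peak_width, cfg.min_gap, cfg.chrom_length)
        for s in starts:
            peaks.append(GenomicInterval(c, int(s), int(s) + cfg.peak_width,
                                         f"peak{len(peaks):06d}"))
    gc = pd.Series(
        np.clip(rng.beta(4, 4, size=len(peaks)) * 0.6 + 0.2, 0.05, 0.95),
        index=pd.Index([p.id for p in peaks], name="peak_id"), name="gc",
    )

    classes = np.array(["non_differential"] * len(peaks), dtype=object)
    n_planted = int(round(cfg.planted_lfc_fraction * len(peaks)))
    planted_idx = rng.choice(len(peaks), size=n_planted, replace=False)
    offset = 0
    for cls, frac in _CLASS_SPLIT:
        k = int(round(frac * n_planted))
        classes[planted_idx[offset : offset + k]] = cls
        offset += k
    classes[planted_idx[offset:]] = _CLASS_SPLIT[-1][0]

    days = list(cfg.replicates_per_day)
    samples = [f"{d}_r{i+1}" for d in days for i in range(cfg.replicates_per_day[d])]
    base = np.exp(rng.normal(np.log(cfg.atac_base_mean), 0.6, size=len(peaks)))
    day_shift = np.array(
        [[_CLASS_EFFECTS[c][d] * cfg.planted_lfc_value for d in days] for c in classes]
    )
    depth = np.exp(rng.normal(0.0, 0.2, size=len(samples)))
    gc_coef = rng.normal(0.0, cfg.gc_bias_strength, size=len(samples))
    gc_dev = (gc.to_numpy() - 0.5) * 4.0
    counts = np.zeros((len(peaks), len(samples)), dtype=int)
    for j, s in enumerate(samples):
        d = days.index(s.split("_")[0])
        mean = base * 2.0 ** day_shift[:, d] * depth[j] * np.exp(gc_coef[j] * gc_dev)
        counts[:, j] = _nb_draw(rng, mean, cfg.nb_dispersion)
    atac_counts = pd.DataFrame(
        counts, index=pd.Index([p.id for p in peaks], name="peak_id"), columns=samples
    )
    atac_samples = pd.DataFrame(
        {"sample": samples, "day": [s.split("_")[0] for s in samples], "batch": "b1"}
    )

    # replicate-level peak calls: jitter +- N(0, 20 bp), dropout 0.1, noise
    replicate_peaks: dict[str, list[ScoredInterval]] = {}
    for d in days:
        for i in range(cfg.replicates_per_day[d]):
            rep = f"{d}_r{i+1}"
            calls = []
            keep = rng.random(len(peaks)) >= cfg.peak_drop_prob
            jit = rng.normal(0, cfg.peak_jitter_sd, size=(len(peaks), 2)).round().astype(int)
            neglog = rng.uniform(2, 10, size=len(peaks))
            for k, pk in enumerate(peaks):
                if not keep[k]:
                    continue
                start = max(0, pk.start + jit[k, 0])
                end = max(start + 50, pk.end + jit[k, 1])
                calls.append(
                    ScoredInterval(
                        GenomicInterval(pk.chrom, start, end, f"{rep}_{pk.id}"),
                        10.0 ** -neglog[k], rep,
                    )
                )
            for k in range(cfg.noise_peaks_per_replicate):
                c = chrom_names[rng.integers(cfg.n_chroms)]
                s0 = int(rng.integers(0, cfg.chrom_length - cfg.noise_peak_width))
                calls.append(
                    ScoredInterval(
                        GenomicInterval(c, s0, s0 + cfg.noise_peak_width, f"{rep}_noise{k}"),
                        10.0 ** -rng.uniform(2, 4), rep,
                    )
                )
            replicate_peaks[rep] = calls

    truth_peaks = pd.DataFrame(
        {
            "peak_id": [p.id for p in peaks],
            "chrom": [p.chrom for p in peaks],
            "start": [p.start for p in peaks],
            "end": [p.end for p in peaks],
            "gc": gc.to_numpy(),
            "class": classes,
            **{f"lfc_{d}": day_shift[:, di] for di, d in enumerate(days)},
        }
    )
    return peaks, gc, replicate_peaks, atac_counts, atac_samples, truth_peaks


def simulate_rna_study(cfg: SimulationConfig, rng):
    """Gene count matrix with planted differential genes (truth DE set)."""
    genes = [f"gene{i:04d}" for i in range(cfg.n_genes)]
    days = list(cfg.rna_replicates_per_day)
    samples = [f"{d}_rna{i+1}" for d in days for i in range(cfg.rna_replicates_per_day[d])]
    n_de = int(round(cfg.rna_de_fraction * cfg.n_genes))
    de_idx = rng.choice(cfg.n_genes, size=n_de, replace=False)
    shift = np.zeros((cfg.n_genes, len(days)))
    for k, gi in enumerate(de_idx):
        pattern = (
            {"D0": 0.0, "D4": 1.0, "D14": 1.0} if k % 2 == 0
            else {"D0": 1.0, "D4": 0.0, "D14": 0.0}
        )
        for di, d in enumerate(days):
            shift[gi, di] = pattern[d] * cfg.rna_lfc
    base = np.exp(rng.normal(np.log(cfg.rna_base_mean), 0.7, size=cfg.n_genes))
    depth = np.exp(rng.normal(0.0, 0.15, size=len(samples)))
    counts = np.zeros((cfg.n_genes, len(samples)), dtype=int)
    for j, s in enumerate(samples):
        d = days.index(s.split("_")[0])
        counts[:, j] = _nb_draw(rng, base * 2.0 ** shift[:, d] * depth[j], cfg.nb_dispersion)
    rna_counts = pd.DataFrame(
        counts, index=pd.Index(genes, name="gene"), columns=samples
    )
    rna_samples = pd.DataFrame(
        {"sample": samples, "day": [s.split("_")[0] for s in samples], "batch": "b1"}
    )
    return rna_counts, rna_samples, {genes[i] for i in de_idx}


def simulate_haplotype_panel(cfg: SimulationConfig, rng):
    """0/1 haplotypes with block-copy LD structure (positions assigned later).

    Within a block every variant copies a shared founder haplotype with a
    per-variant mutation probability, giving high within-block and ~zero
    between-block r^2; mutation probability 0 gives perfect within-block LD.
    """
    n_var = cfg.n_panel_blocks * cfg.ld_block_size
    variants = [f"rs{1000 + i}" for i in range(n_var)]
    hap = np.zeros((n_var, cfg.n_haplotypes), dtype=int)
    for b in range(cfg.n_panel_blocks):
        freq = rng.uniform(0.2, 0.8)
        founder = (rng.random(cfg.n_haplotypes) < freq).astype(int)
        for v in range(cfg.ld_block_size):
            flip = rng.random(cfg.n_haplotypes) < cfg.panel_mutation_prob
            hap[b * cfg.ld_block_size + v] = founder ^ flip
    return variants, hap


def simulate_allele_counts(cfg: SimulationConfig, rng, truth_peaks, gaps):
    """Allele count tables over all days with planted imbalance."""
    context = truth_peaks[truth_peaks["class"] != "non_differential"]
    context_peaks = {r.peak_id: (r.chrom, r.start, r.end) for r in context.itertuples()}
    ctx_ids = list(context_peaks)
    variants = [f"var{i:04d}" for i in range(cfg.n_ai_variants)]
    planted = rng.random(cfg.n_ai_variants) < cfg.ai_fraction
    positions: dict[str, tuple[str, int]] = {}
    in_peak: list[str] = []
    for v in variants:
        if ctx_ids and rng.random() < 0.6:
            pid = ctx_ids[int(rng.integers(len(ctx_ids)))]
            c, s, e = context_peaks[pid]
            positions[v] = (c, int(rng.integers(s + 10, e - 10)))
            in_peak.append(pid)
        else:
            positions[v] = gaps.sample(rng)
            in_peak.append("")
    pi = np.where(planted, cfg.ai_pi, 0.5)
    frames = []
    for day, n_rep in cfg.replicates_per_day.items():
        depth = _nb_draw(
            rng, np.full((len(variants), n_rep), cfg.ai_depth_mean), cfg.nb_dispersion
        )
        alt = rng.binomial(depth, pi[:, None])
        frames.append(
            pd.DataFrame(
                {
                    "variant": np.repeat(variants, n_rep),
                    "day": day,
                    "replicate": np.tile([f"{day}_r{r+1}" for r in range(n_rep)], len(variants)),
                    "ref_count": (depth - alt).ravel(),
                    "alt_count": alt.ravel(),
                }
            )
        )
    table = pd.concat(frames, ignore_index=True)
    truth_ai = pd.DataFrame(
        {
            "variant": variants,
            "pi": np.where(planted, cfg.ai_pi, 0.5),
            "planted": planted,
            "peak_id": in_peak,
        }
    )
    return table, positions, truth_ai


def _simulate_qc_reads(cfg: SimulationConfig, rng, peaks, tss, samples, chrom_names):
    """Small per-library read sets for FRiP / TSS-enrichment QC."""
    tss_list = list(tss.values())
    reads_by_lib: dict[str, list[GenomicInterval]] = {}
    for lib in samples:
        frip_true = rng.uniform(0.35, 0.6)
        reads = []
        for _ in range(cfg.qc_reads_per_library):
            u = rng.random()
            if u < frip_true:
                pk = peaks[int(rng.integers(len(peaks)))]
                s0 = int(rng.integers(pk.start, max(pk.start + 1, pk.end - 50)))
                c = pk.chrom
            elif u < frip_true + 0.15 and tss_list:
                c, pos = tss_list[int(rng.integers(len(tss_list)))]
                if rng.random() < 0.5:  # promoter pile-up at the TSS
                    s0 = max(0, int(pos + rng.normal(0, 60)) - 25)
                else:  # local background across (and slightly beyond) the window
                    s0 = max(0, int(pos + rng.integers(-1100, 1101)) - 25)
            else:
                c = chrom_names[int(rng.integers(cfg.n_chroms))]
                s0 = int(rng.integers(0, cfg.chrom_length - 50))
            reads.append(GenomicInterval(c, s0, s0 + 50))
        reads_by_lib[lib] = reads
    return reads_by_lib


# ---------------------------------------------------------------------------
# orchestrator
# ---------------------------------------------------------------------------

def _relocate_block_into_peak(positions, variants, block, block_size, peak):
    """Place every variant of a block inside the peak; the lead comes first."""
    spacing = max(1, (peak.end - peak.start - 40) // block_size)
    for v in range(block_size):
        vid = variants[block * block_size + v]
        positions[vid] = (peak.chrom, peak.start + 20 + v * spacing)


def simulate_study(config: SimulationConfig | None = None) -> StudyData:
    """Generate the full synthetic study from one master seed."""
    cfg = config or SimulationConfig()
    ss = np.random.SeedSequence(cfg.seed)
    streams = {name: np.random.default_rng(child) for name, child in zip(
        ["atac", "rna", "panel", "positions", "gwas", "hic_eqtl", "ai", "qc"],
        ss.spawn(8),
    )}
    chrom_names = [f"chr{i+1}" for i in range(cfg.n_chroms)]

    peaks, gc, replicate_peaks, atac_counts, atac_samples, truth_peaks = (
        simulate_atac_study(cfg, streams["atac"], chrom_names)
    )
    rna_counts, rna_samples, de_genes = simulate_rna_study(cfg, streams["rna"])
    genes = list(rna_counts.index)
    gaps = _GapSampler(peaks, chrom_names, cfg.chrom_length, margin=1500)

    rng_pos = streams["positions"]
    tss = {g: gaps.sample(rng_pos) for g in genes}

    # panel: blocks default to peak-free gap anchors (span << gap margin)
    variants, hap = simulate_haplotype_panel(cfg, streams["panel"])
    positions: dict[str, tuple[str, int]] = {}
    for b in range(cfg.n_panel_blocks):
        chrom, anchor = gaps.sample(rng_pos)
        for v in range(cfg.ld_block_size):
            positions[variants[b * cfg.ld_block_size + v]] = (chrom, anchor + v * 100)

    # ----- intended peak-gene links -----
    rng_link = streams["hic_eqtl"]
    context_ids = truth_peaks.loc[
        truth_peaks["class"] != "non_differential", "peak_id"
    ].tolist()
    peak_by_id = {p.id: p for p in peaks}
    tss_by_chrom: dict[str, list[tuple[int, str]]] = {}
    for g, (c, p) in tss.items():
        tss_by_chrom.setdefault(c, []).append((p, g))

    def pick_gene(pid: str, cap: int) -> str | None:
        pk = peak_by_id[pid]
        center = (pk.start + pk.end) // 2
        near = [g for p, g in tss_by_chrom.get(pk.chrom, []) if abs(p - center) <= cap]
        return near[int(rng_link.integers(len(near)))] if near else None

    bait_width = 600
    bait_frag = {
        g: GenomicInterval(c, max(0, p - bait_width // 2), p + bait_width // 2, f"bait_{g}")
        for g, (c, p) in tss.items()
    }

    n_bb = int(round(cfg.bait_bait_fraction * cfg.n_hic_pairs))
    n_pairs = cfg.n_hic_pairs - n_bb
    link_peaks = list(
        rng_link.choice(context_ids, size=min(n_pairs, len(context_ids)), replace=False)
    )
    patterns: list[set[str]] = []
    for i in range(len(link_peaks)):
        if i < int(cfg.link_overlap_fraction * len(link_peaks)):
            patterns.append({"HiC", "eQTL"})
        elif i % 2 == 0:
            patterns.append({"HiC"})
        else:
            patterns.append({"eQTL"})

    hap_df = pd.DataFrame(
        hap, index=variants, columns=[f"h{j}" for j in range(cfg.n_haplotypes)]
    )
    n_eqtl_capable = cfg.n_panel_blocks - cfg.n_gwas_leads
    hic_pairs: list[HiCPair] = []
    eqtl_signals: list[EQTLSignal] = []
    truth_links: dict[tuple[str, str], set[str]] = {}
    next_eqtl_block = 0
    for pid, methods in zip(link_peaks, patterns):
        pk = peak_by_id[pid]
        gene = pick_gene(pid, EQTL_DISTANCE_CAP if "eQTL" in methods else HIC_DISTANCE_CAP)
        if gene is None:
            continue  # no gene within the distance cap; skip this peak
        if "HiC" in methods:
            other = GenomicInterval(
                pk.chrom, pk.start + cfg.peak_width // 4,
                pk.end - cfg.peak_width // 4, f"oe_{pid}",
            )
            hic_pairs.append(HiCPair(bait_frag[gene], other, (gene,)))
            truth_links.setdefault((pid, gene), set()).add("HiC")
        if "eQTL" in methods and next_eqtl_block < n_eqtl_capable:
            b = next_eqtl_block
            next_eqtl_block += 1
            block_vars = variants[b * cfg.ld_block_size : (b + 1) * cfg.ld_block_size]
            _relocate_block_into_peak(positions, variants, b, cfg.ld_block_size, pk)
            lead = block_vars[0]
            panel_tmp = HaplotypePanel(hap_df, positions)
            proxies = [(lead, pk.chrom, positions[lead][1], 1.0)]
            for v in block_vars[1:]:
                r2 = _r2_safe(panel_tmp, lead, v)
                if r2 > 0.8:
                    proxies.append((v, positions[v][0], positions[v][1], r2))
            rank = "primary" if rng_link.random() < 0.8 else "conditional"
            eqtl_signals.append(EQTLSignal(gene, lead, rank, tuple(proxies)))
            truth_links.setdefault((pid, gene), set()).add("eQTL")

    # bait-bait pairs between two genes, both ends clear of peaks (no links)
    for _ in range(n_bb):
        g1, g2 = rng_link.choice(genes, size=2, replace=False)
        hic_pairs.append(HiCPair(bait_frag[g1], bait_frag[g2], (g1,), None, (g2,)))

    # ----- GWAS catalog on the last n_gwas_leads blocks -----
    # every second lead's block is relocated inside a linked peak, so the
    # overlay of links with GWAS signals has known truth
    rng_gwas = streams["gwas"]
    gwas_blocks = list(range(cfg.n_panel_blocks - cfg.n_gwas_leads, cfg.n_panel_blocks))
    target_peaks = list(link_peaks)
    rng_gwas.shuffle(target_peaks)
    gwas_peak_ids: set[str] = set()
    trait_pool = [f"trait_{i:02d}" for i in range(2 * cfg.n_gwas_leads)]
    efo_pool = [f"EFO_{i:04d}" for i in range(cfg.efo_terms)]
    trait_efo = {
        t: sorted(rng_gwas.choice(efo_pool, size=int(rng_gwas.integers(1, 7)),
                                  replace=False).tolist())
        for t in trait_pool
    }
    records = []
    leads = []
    for k, b in enumerate(gwas_blocks):
        block_vars = variants[b * cfg.ld_block_size : (b + 1) * cfg.ld_block_size]
        if k % 2 == 0 and k // 2 < len(target_peaks):
            pid = target_peaks[k // 2]
            _relocate_block_into_peak(positions, variants, b, cfg.ld_block_size,
                                      peak_by_id[pid])
            gwas_peak_ids.add(pid)
        lead = block_vars[0]
        leads.append(lead)
        lead_exp = rng_gwas.uniform(10, 30)
        trait = trait_pool[int(rng_gwas.integers(len(trait_pool)))]
        c, pos = positions[lead]
        records.append((lead, c, pos + 1, trait, 10.0 ** -lead_exp, "A", "G"))
        panel_now = HaplotypePanel(hap_df, positions)
        for v in block_vars[1:]:
            if _r2_safe(panel_now, lead, v) > 0.8 and rng_gwas.random() < 0.7:
                exp = 8.0 + (lead_exp - 8.0) * rng_gwas.uniform(0.1, 0.9)
                t2 = trait_pool[int(rng_gwas.integers(len(trait_pool)))]
                c2, pos2 = positions[v]
                records.append((v, c2, pos2 + 1, t2, 10.0 ** -exp, "C", "T"))
    # junk records exercising the catalog filter
    records.append(("rs999001", chrom_names[0], 100, "trait_junk", 1e-6, "A", "G"))
    records.append(("rs999002", chrom_names[0], 200, "trait_junk", 1e-12, "AT", "G"))
    records.append(("rs999003", chrom_names[0], 300, "trait_junk", 1e-12, "A", "G"))
    records.append(("rs1 x rs2", chrom_names[0], 400, "trait_junk", 1e-12, "A", "G"))
    gwas_catalog = pd.DataFrame(
        records, columns=["rsid", "chrom", "pos", "trait", "p", "ref", "alt"]
    )
    allele_counts_catalog = {r: 2 for r in gwas_catalog["rsid"]}
    allele_counts_catalog["rs999003"] = 3  # multiallelic
    trait_efo["trait_junk"] = [efo_pool[0]]

    panel = HaplotypePanel(hap_df, positions)

    # DE evidence on the truth links
    link_rows = [
        {"peak": pid, "gene": gene,
         "methods": ",".join(sorted(m | ({"DE"} if gene in de_genes else set())))}
        for (pid, gene), m in sorted(truth_links.items())
    ]
    truth_link_df = pd.DataFrame(link_rows, columns=["peak", "gene", "methods"])

    allele_table, ai_positions, truth_ai = simulate_allele_counts(
        cfg, streams["ai"], truth_peaks, gaps
    )
    qc_reads = _simulate_qc_reads(
        cfg, streams["qc"], peaks, tss, list(atac_counts.columns), chrom_names
    )

    truth = GroundTruth(
        peaks=truth_peaks,
        de_genes=de_genes,
        links=truth_link_df,
        gwas_leads=leads,
        gwas_peak_ids=gwas_peak_ids,
        ai=truth_ai,
    )
    return StudyData(
        config=cfg,
        chrom_names=chrom_names,
        peaks=peaks,
        gc=gc,
        replicate_peaks=replicate_peaks,
        atac_counts=atac_counts,
        atac_samples=atac_samples,
        rna_counts=rna_counts,
        rna_samples=rna_samples,
        tss=tss,
        bait_fragments=[bait_frag[g] for g in genes],
        hic_pairs=hic_pairs,
        eqtl_signals=eqtl_signals,
        panel=panel,
        gwas_catalog=gwas_catalog,
        allele_counts_catalog=allele_counts_catalog,
        trait_efo=trait_efo,
        allele_counts=allele_table,
        ai_variant_positions=ai_positions,
        qc_reads=qc_reads,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# file emission (the formats the pipeline stages read back)
# ---------------------------------------------------------------------------

def write_study(study: StudyData, outdir) -> None:
    """Write every synthetic input (and the ground truth) as plain TSV/BED."""
    out = Path(outdir)
    (out / "peaks").mkdir(parents=True, exist_ok=True)
    (out / "truth").mkdir(exist_ok=True)
    for rep, calls in study.replicate_peaks.items():
        write_narrowpeak(calls, out / "peaks" / f"{rep}.narrowPeak")
    study.atac_counts.rename_axis("peak_id").to_csv(out / "atac_counts.tsv", sep="\t")
    study.atac_samples.to_csv(out / "atac_samples.tsv", sep="\t", index=False)
    study.gc.rename_axis("peak_id").to_csv(out / "peak_gc.tsv", sep="\t")
    study.rna_counts.rename_axis("gene").to_csv(out / "rna_counts.tsv", sep="\t")
    study.rna_samples.to_csv(out / "rna_samples.tsv", sep="\t", index=False)
    pd.DataFrame(
        [(g, c, p) for g, (c, p) in study.tss.items()], columns=["gene", "chrom", "pos"]
    ).to_csv(out / "tss.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            (
                h.bait.chrom, h.bait.start, h.bait.end,
                h.other_end.chrom, h.other_end.start, h.other_end.end,
                ",".join(h.bait_genes), ",".join(h.opposite_end_genes),
            )
            for h in study.hic_pairs
        ],
        columns=["bait_chrom", "bait_start", "bait_end",
                 "oe_chrom", "oe_start", "oe_end", "bait_genes", "oe_genes"],
    ).to_csv(out / "hic_pairs.tsv", sep="\t", index=False)
    pd.DataFrame(
        [(b.chrom, b.start, b.end, b.id) for b in study.bait_fragments],
        columns=["chrom", "start", "end", "fragment"],
    ).to_csv(out / "bait_fragments.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            (s.gene, s.lead, s.rank, v, c, pos + 1, r2)
            for s in study.eqtl_signals
            for v, c, pos, r2 in s.proxies
        ],
        columns=["gene", "lead", "rank", "proxy", "chrom", "pos", "r2"],
    ).to_csv(out / "eqtl.tsv", sep="\t", index=False)
    hap = study.panel.haplotypes.copy()
    hap.insert(0, "chrom", [study.panel.positions[v][0] for v in hap.index])
    hap.insert(1, "pos", [study.panel.positions[v][1] + 1 for v in hap.index])
    hap.rename_axis("rsid").to_csv(out / "haplotype_panel.tsv", sep="\t")
    study.gwas_catalog.to_csv(out / "gwas_catalog.tsv", sep="\t", index=False)
    pd.DataFrame(
        sorted(study.allele_counts_catalog.items()), columns=["rsid", "n_alleles"]
    ).to_csv(out / "allele_table.tsv", sep="\t", index=False)
    pd.DataFrame(
        [(t, ",".join(terms)) for t, terms in sorted(study.trait_efo.items())],
        columns=["trait", "efo_terms"],
    ).to_csv(out / "efo_map.tsv", sep="\t", index=False)
    study.allele_counts.to_csv(out / "allele_counts.tsv", sep="\t", index=False)
    pd.DataFrame(
        [(v, c, p + 1) for v, (c, p) in study.ai_variant_positions.items()],
        columns=["variant", "chrom", "pos"],
    ).to_csv(out / "ai_variant_positions.tsv", sep="\t", index=False)
    (out / "qc_reads").mkdir(exist_ok=True)
    for lib, reads in study.qc_reads.items():
        with open(out / "qc_reads" / f"{lib}.bed", "w") as fh:
            for r in sorted(reads, key=lambda iv: (iv.chrom, iv.start)):
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\n")
    study.truth.peaks.to_csv(out / "truth" / "peaks.tsv", sep="\t", index=False)
    pd.Series(sorted(study.truth.de_genes), name="gene").to_csv(
        out / "truth" / "de_genes.tsv", sep="\t", index=False
    )
    study.truth.links.to_csv(out / "truth" / "links.tsv", sep="\t", index=False)
    pd.Series(study.truth.gwas_leads, name="lead").to_csv(
        out / "truth" / "gwas_leads.tsv", sep="\t", index=False
    )
    pd.Series(sorted(study.truth.gwas_peak_ids), name="peak_id").to_csv(
        out / "truth" / "gwas_peaks.tsv", sep="\t", index=False
    )
    study.truth.ai.to_csv(out / "truth" / "ai.tsv", sep="\t", index=False)
    with open(out / "config.json", "w") as fh:
        cfg_dict = dataclasses.asdict(study.config)
        cfg_dict["replicates_per_day"] = dict(cfg_dict["replicates_per_day"])
        cfg_dict["rna_replicates_per_day"] = dict(cfg_dict["rna_replicates_per_day"])
        json.dump(cfg_dict, fh, indent=1, sort_keys=True)
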