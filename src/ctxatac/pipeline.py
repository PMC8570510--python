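"""End-to-end pipeline: simulate -> qc -> consensus -> differential ->
classify -> link -> gwas -> ai -> report.

Each stage is a pure function over a :class:`~ctxatac.simulate.StudyData`
(plus upstream stage outputs) that also writes its outputs as plain TSV/BED
under the run directory.  ``run_all`` chains the stages and emits a
machine-readable JSON report of every headline tally; the report is
byte-identical across runs with the same seed and configuration.

Quantification note: read-level counting is out of scope, so the emitted
count matrix is keyed by true peak ids and the merged test-set regions
built from the replicate peak calls are mapped back to true peaks by
largest >= 1 bp overlap (the simulated peaks are disjoint, so the map is
one-to-one; unmapped noise regions are dropped and counted in the report).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import ai as ai_mod
from . import consensus as cons
from . import differential as diff
from . import gwas as gwas_mod
from . import linking as link_mod
from . import qc as qc_mod
from .intervals import GenomicInterval, ScoredInterval, overlap_pairs, read_bed, read_narrowpeak, write_bed
from .simulate import SimulationConfig, StudyData, simulate_study, write_study
from .gwas import HaplotypePanel
from .linking import EQTLSignal, HiCPair

logger = logging.getLogger(__name__)

COMPARISONS = (("D4", "D0"), ("D14", "D0"), ("D14", "D4"))


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class PipelineConfig:
    seed: int = 0
    outdir: str = "ctxatac_run"
    simulation: dict = dataclasses.field(default_factory=dict)
    lfc_thresh: float = 1.0
    fdr: float = 0.05
    r2_thresh: float = 0.8
    consensus_min_frac: float = 0.5
    top_k: int = 100_000
    ai_theta: float = ai_mod.AI_THETA
    efo_min_total: int = 100

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        for name, lo, hi in (
            ("fdr", 0.0, 1.0), ("r2_thresh", 0.0, 1.0), ("consensus_min_frac", 0.0, 1.0),
        ):
            v = getattr(cfg, name)
            if not (lo < v < hi):
                raise ValueError(f"config {name}={v} outside ({lo}, {hi})")
        if cfg.lfc_thresh < 0 or cfg.ai_theta < 0 or cfg.top_k < 0:
            raise ValueError("thresholds must be non-negative")
        return cfg

    def sim_config(self) -> SimulationConfig:
        return SimulationConfig(seed=self.seed, **self.simulation)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_qc(study: StudyData, outdir: Path) -> dict:
    """Per-library FRiP / TSS-enrichment metrics plus the PCA outlier screen."""
    tss_list = list(study.tss.values())
    libs = []
    for lib, reads in study.qc_reads.items():
        own_peaks = [sp.interval for sp in study.replicate_peaks.get(lib, [])]
        fr = qc_mod.frip(reads, own_peaks)
        cov = qc_mod.window_coverage(reads, tss_list)
        te = qc_mod.tss_enrichment(cov)
        libs.append(qc_mod.LibraryQC(lib, fr, te))
    flagged = qc_mod.qc_filter(libs, "sgbs")
    outliers = qc_mod.detect_outliers(study.atac_counts, n_pcs=10, cut_height=200.0)
    table = pd.DataFrame(
        [(l.library, l.frip, l.tss_enrichment, l.passed) for l in flagged],
        columns=["library", "frip", "tss_enrichment", "pass"],
    )
    table.to_csv(outdir / "qc.tsv", sep="\t", index=False)
    return {
        "n_libraries": len(flagged),
        "n_pass": int(table["pass"].sum()),
        "mean_frip": round(float(table["frip"].mean()), 6),
        "mean_tss_enrichment": round(float(table["tss_enrichment"].mean()), 6),
        "outlier_samples": sorted(outliers),
    }


def stage_consensus(study: StudyData, cfg: PipelineConfig, outdir: Path) -> dict:
    """Per-day consensus, top-K ranking, cross-day merged test set + mapping."""
    days = sorted({rep.split("_")[0] for rep in study.replicate_peaks})
    top_sets = {}
    per_day_counts = {}
    for day in days:
        reps = {r: p for r, p in study.replicate_peaks.items() if r.startswith(day + "_")}
        peaks = cons.per_day_consensus(reps, min_frac=cfg.consensus_min_frac, label=day)
        ranked = cons.rank_by_median_p(peaks, reps)
        top = cons.top_k(ranked, cfg.top_k)
        top_sets[day] = top
        per_day_counts[day] = len(top)
        pd.DataFrame(
            [
                (cp.interval.chrom, cp.interval.start, cp.interval.end,
                 cp.n_supporting, cp.median_p)
                for cp in top
            ],
            columns=["chrom", "start", "end", "n_supporting", "median_p"],
        ).to_csv(outdir / f"consensus_{day}.tsv", sep="\t", index=False)
    test_set = cons.cross_day_union(top_sets)
    write_bed([cp.interval for cp in test_set], outdir / "test_peaks.bed")

    # map merged test regions back to true count-matrix peaks (max overlap)
    true_peaks = study.peaks
    pairs = overlap_pairs([cp.interval for cp in test_set], true_peaks)
    best: dict[str, tuple[str, int]] = {}
    for qid, sid, bp in pairs:
        if qid not in best or bp > best[qid][1]:
            best[qid] = (sid, bp)
    mapping = pd.DataFrame(
        [(q, s) for q, (s, _) in sorted(best.items())], columns=["merged_id", "peak_id"]
    )
    n_multi = mapping["peak_id"].duplicated().sum()
    mapping = mapping.drop_duplicates("peak_id")
    mapping.to_csv(outdir / "peak_mapping.tsv", sep="\t", index=False)
    iv_by_id = {cp.interval.id: cp.interval for cp in test_set}
    mapped_intervals = {
        row.peak_id: GenomicInterval(
            iv_by_id[row.merged_id].chrom, iv_by_id[row.merged_id].start,
            iv_by_id[row.merged_id].end, row.peak_id,
        )
        for row in mapping.itertuples()
    }
    return {
        "per_day_consensus": per_day_counts,
        "n_test_peaks": len(test_set),
        "n_mapped": len(mapping),
        "n_unmapped": len(test_set) - len(best),
        "n_multimapped_dropped": int(n_multi),
        "mapped_intervals": mapped_intervals,
    }


def _three_comparisons(counts, sample_day, offsets, cfg):
    results = {}
    for test, ref in COMPARISONS:
        label = f"{test}_vs_{ref}"
        res = diff.nb_wald_test(counts, sample_day, (test, ref), offsets, label=label)
        results[label] = diff.call_differential(res, cfg.lfc_thresh, cfg.fdr)
    return results


def stage_differential_atac(study: StudyData, mapped, cfg: PipelineConfig, outdir: Path) -> dict:
    counts = study.atac_counts.loc[sorted(mapped)]
    sample_day = dict(zip(study.atac_samples["sample"], study.atac_samples["day"]))
    sf = diff.size_factors(counts)
    gcf = diff.gc_quantile_offsets(counts, study.gc)
    offsets = gcf.mul(sf, axis=1)
    results = _three_comparisons(counts, sample_day, offsets, cfg)
    classes = diff.classify_context(results)
    background = diff.select_background(results)
    for label, res in results.items():
        res.rename_axis("peak_id").to_csv(outdir / f"atac_diff_{label}.tsv", sep="\t")
    classes.rename_axis("peak_id").to_csv(outdir / "context_classes.tsv", sep="\t")
    pd.Series(sorted(background), name="peak_id").to_csv(
        outdir / "background_peaks.tsv", sep="\t", index=False
    )
    tally = classes.value_counts().to_dict()
    return {
        "results": results,
        "classes": classes,
        "n_context_dependent": int((classes != "non_differential").sum()),
        "class_counts": {k: int(tally.get(k, 0)) for k in diff.CONTEXT_CLASSES},
        "n_background": int(len(background)),
    }


def stage_differential_rna(study: StudyData, cfg: PipelineConfig, outdir: Path) -> dict:
    counts = study.rna_counts
    sf = diff.size_factors(counts)
    expressed = diff.expressed_features(counts, sf)
    counts = counts.loc[expressed]
    sample_day = dict(zip(study.rna_samples["sample"], study.rna_samples["day"]))
    results = _three_comparisons(counts, sample_day, None, cfg)
    for label, res in results.items():
        res.rename_axis("gene").to_csv(outdir / f"rna_diff_{label}.tsv", sep="\t")
    de_genes = set()
    for res in results.values():
        de_genes |= set(res.index[res["significant"]])
    pd.Series(sorted(de_genes), name="gene").to_csv(
        outdir / "de_genes.tsv", sep="\t", index=False
    )
    return {
        "results": results,
        "de_genes": de_genes,
        "n_expressed": int(len(expressed)),
        "n_de_genes": len(de_genes),
    }


def stage_link(study: StudyData, context_peaks: dict, de_genes: set, outdir: Path) -> dict:
    peaks = list(context_peaks.values())
    typed = link_mod.classify_hic_pairs(study.hic_pairs, study.bait_fragments)
    hic_links = link_mod.link_by_hic(peaks, typed)
    eqtl_links = link_mod.link_by_eqtl(peaks, study.eqtl_signals)
    annotated = link_mod.annotate_de_support(hic_links + eqtl_links, de_genes)
    summary = link_mod.integrate_links(annotated)
    distances = link_mod.peak_tss_distance(summary["pairs"], context_peaks, study.tss)
    rows = [
        {
            "peak": l.peak,
            "gene": l.gene,
            "methods": ",".join(sorted(l.methods)),
            "n_methods": l.n_methods,
            "best_proxy": l.best_proxy[0] if l.best_proxy else "",
            "best_proxy_r2": l.best_proxy[1] if l.best_proxy else "",
            "tss_distance": distances.get((l.peak, l.gene)),
        }
        for l in summary["pairs"]
    ]
    pd.DataFrame(rows).to_csv(outdir / "links.tsv", sep="\t", index=False)
    return {k: v for k, v in summary.items()} | {"distances": distances}


def stage_gwas(study: StudyData, context_peaks: dict, cfg: PipelineConfig, outdir: Path) -> dict:
    filtered = gwas_mod.filter_catalog(study.gwas_catalog, study.allele_counts_catalog)
    signals = gwas_mod.ld_clump(filtered, study.panel, r2_thresh=cfg.r2_thresh)
    hits = gwas_mod.overlap_signals_with_peaks(
        signals, list(context_peaks.values()), study.panel
    )
    overlapping_leads = {lead for lead, _, _ in hits}
    gwas_peaks = {pk for _, pk, _ in hits}
    efo = gwas_mod.efo_normalized_counts(
        signals, overlapping_leads, study.trait_efo, min_total=cfg.efo_min_total
    )
    pd.DataFrame(
        [(s.lead, s.chrom, s.pos, s.best_p, len(s.members), len(s.proxies)) for s in signals],
        columns=["lead", "chrom", "pos", "best_p", "n_members", "n_proxies"],
    ).to_csv(outdir / "clumped_signals.tsv", sep="\t", index=False)
    pd.DataFrame(hits, columns=["lead", "peak_id", "proxy"]).to_csv(
        outdir / "signal_peak_hits.tsv", sep="\t", index=False
    )
    efo.to_csv(outdir / "efo_counts.tsv", sep="\t", index=False)
    return {
        "signals": signals,
        "gwas_peaks": gwas_peaks,
        "n_catalog_records": int(len(study.gwas_catalog)),
        "n_filtered_records": int(len(filtered)),
        "n_signals": len(signals),
        "n_overlapping_signals": len(overlapping_leads),
        "n_gwas_peaks": len(gwas_peaks),
        "top_efo_terms": efo.loc[efo["top"], "term"].tolist(),
    }


def stage_ai(study: StudyData, context_peaks: dict, linked_ge2: set, gwas_peaks: set,
             cfg: PipelineConfig, outdir: Path) -> dict:
    sig_variants: set[str] = set()
    per_day = {}
    frames = []
    for day, grp in study.allele_counts.groupby("day", sort=True):
        testable = ai_mod.filter_ai_variants(grp)
        if not testable:
            per_day[day] = 0
            continue
        res = ai_mod.ai_test(grp[grp["variant"].isin(testable)], theta=cfg.ai_theta)
        res.insert(0, "day_label", day)
        frames.append(res)
        day_sig = set(res.index[res["significant"]])
        sig_variants |= day_sig
        per_day[day] = len(day_sig)
    if frames:
        pd.concat(frames).rename_axis("variant").to_csv(outdir / "ai_results.tsv", sep="\t")
    summary_input = pd.DataFrame({"significant": True}, index=sorted(sig_variants))
    annot = ai_mod.annotate_ai(
        summary_input, study.ai_variant_positions, context_peaks, linked_ge2, gwas_peaks
    )
    annot_out = {k: v for k, v in annot.items() if k != "variant_peak"}
    annot_out["n_significant_per_day"] = per_day
    with open(outdir / "ai_summary.json", "w") as fh:
        json.dump(annot_out, fh, indent=1, sort_keys=True)
    return annot_out


# ---------------------------------------------------------------------------
# run_all
# ---------------------------------------------------------------------------

def run_all(cfg: PipelineConfig, study: StudyData | None = None) -> dict:
    """Execute every stage; returns (and writes) the JSON-able report."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if study is None:
        study = simulate_study(cfg.sim_config())
        write_study(study, outdir / "inputs")
    report: dict = {"seed": cfg.seed, "thresholds": {
        "lfc": cfg.lfc_thresh, "fdr": cfg.fdr, "r2": cfg.r2_thresh,
        "ai_theta": round(cfg.ai_theta, 6), "consensus_min_frac": cfg.consensus_min_frac,
    }}
    logger.info("thresholds: %s", report["thresholds"])

    report["qc"] = stage_qc(study, outdir)
    cons_out = stage_consensus(study, cfg, outdir)
    mapped = cons_out.pop("mapped_intervals")
    report["consensus"] = cons_out

    atac = stage_differential_atac(study, mapped, cfg, outdir)
    report["differential_atac"] = {
        k: atac[k] for k in ("n_context_dependent", "class_counts", "n_background")
    }
    classes = atac["classes"]
    context_peaks = {
        pid: mapped[pid] for pid in classes.index[classes != "non_differential"]
        if pid in mapped
    }

    rna = stage_differential_rna(study, cfg, outdir)
    report["differential_rna"] = {k: rna[k] for k in ("n_expressed", "n_de_genes")}

    links = stage_link(study, context_peaks, rna["de_genes"], outdir)
    report["linking"] = {
        k: links[k]
        for k in ("n_pairs", "n_pairs_ge2", "n_pairs_eq3", "n_peaks", "n_genes",
                  "n_peaks_ge2", "n_genes_ge2", "n_peaks_eq3", "n_genes_eq3")
    }

    if study.gwas_catalog is None or study.panel is None:
        logger.warning("GWAS inputs missing; skipping gwas and overlay stages")
        report["gwas"] = None
        report["gwas_overlay"] = None
        gwas_peaks: set[str] = set()
    else:
        gw = stage_gwas(study, context_peaks, cfg, outdir)
        report["gwas"] = {
            k: gw[k]
            for k in ("n_catalog_records", "n_filtered_records", "n_signals",
                      "n_overlapping_signals", "n_gwas_peaks", "top_efo_terms")
        }
        gwas_peaks = gw["gwas_peaks"]
        overlay = link_mod.gwas_overlay(links["pairs"], gwas_peaks, classes.to_dict())
        report["gwas_overlay"] = {
            k: overlay[k]
            for k in ("n_pairs", "n_pairs_ge2", "n_peaks_ge2", "n_genes_ge2",
                      "peaks_ge2_by_class")
        }

    linked_ge2 = {l.peak for l in links["pairs"] if l.n_methods >= 2}
    report["allelic_imbalance"] = stage_ai(
        study, context_peaks, linked_ge2, gwas_peaks, cfg, outdir
    )

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    return report


# ---------------------------------------------------------------------------
# reading a study back from an inputs directory (stage-wise CLI runs)
# ---------------------------------------------------------------------------

def read_study(indir) -> StudyData:
    """Reconstruct a StudyData from files written by :func:`write_study`.

    GWAS inputs are optional: if the catalog or panel files are absent the
    corresponding fields are None and run_all skips those stages.
    """
    ind = Path(indir)
    with open(ind / "config.json") as fh:
        cfg = SimulationConfig(**json.load(fh))
    replicate_peaks = {
        f.stem: read_narrowpeak(f, source=f.stem)
        for f in sorted((ind / "peaks").glob("*.narrowPeak"))
    }
    atac_counts = pd.read_csv(ind / "atac_counts.tsv", sep="\t", index_col=0)
    atac_samples = pd.read_csv(ind / "atac_samples.tsv", sep="\t")
    gc = pd.read_csv(ind / "peak_gc.tsv", sep="\t", index_col=0)["gc"]
    rna_counts = pd.read_csv(ind / "rna_counts.tsv", sep="\t", index_col=0)
    rna_samples = pd.read_csv(ind / "rna_samples.tsv", sep="\t")
    tss_df = pd.read_csv(ind / "tss.tsv", sep="\t")
    tss = {r.gene: (r.chrom, int(r.pos)) for r in tss_df.itertuples()}
    truth_peaks = pd.read_csv(ind / "truth" / "peaks.tsv", sep="\t")
    peaks = [
        GenomicInterval(r.chrom, int(r.start), int(r.end), r.peak_id)
        for r in truth_peaks.itertuples()
    ]
    baits_df = pd.read_csv(ind / "bait_fragments.tsv", sep="\t")
    bait_fragments = [
        GenomicInterval(r.chrom, int(r.start), int(r.end), r.fragment)
        for r in baits_df.itertuples()
    ]
    hic_df = pd.read_csv(ind / "hic_pairs.tsv", sep="\t", keep_default_na=False)
    hic_pairs = [
        HiCPair(
            GenomicInterval(r.bait_chrom, int(r.bait_start), int(r.bait_end)),
            GenomicInterval(r.oe_chrom, int(r.oe_start), int(r.oe_end)),
            tuple(str(r.bait_genes).split(",")),
            None,
            tuple(g for g in str(r.oe_genes).split(",") if g),
        )
        for r in hic_df.itertuples()
    ]
    eqtl_df = pd.read_csv(ind / "eqtl.tsv", sep="\t")
    eqtl_signals = []
    for (gene, lead, rank), grp in eqtl_df.groupby(["gene", "lead", "rank"], sort=True):
        proxies = tuple(
            (r.proxy, r.chrom, int(r.pos) - 1, float(r.r2)) for r in grp.itertuples()
        )
        eqtl_signals.append(EQTLSignal(gene, lead, rank, proxies))
    panel = gwas_catalog = None
    allele_counts_catalog = {}
    trait_efo = {}
    if (ind / "haplotype_panel.tsv").exists():
        hap_df = pd.read_csv(ind / "haplotype_panel.tsv", sep="\t", index_col=0)
        positions = {
            v: (hap_df.loc[v, "chrom"], int(hap_df.loc[v, "pos"]) - 1) for v in hap_df.index
        }
        panel = HaplotypePanel(hap_df.drop(columns=["chrom", "pos"]), positions)
    if (ind / "gwas_catalog.tsv").exists():
        gwas_catalog = pd.read_csv(ind / "gwas_catalog.tsv", sep="\t")
        at = pd.read_csv(ind / "allele_table.tsv", sep="\t")
        allele_counts_catalog = dict(zip(at["rsid"], at["n_alleles"]))
        efo = pd.read_csv(ind / "efo_map.tsv", sep="\t")
        trait_efo = {r.trait: str(r.efo_terms).split(",") for r in efo.itertuples()}
    allele_counts = pd.read_csv(ind / "allele_counts.tsv", sep="\t")
    ai_pos = pd.read_csv(ind / "ai_variant_positions.tsv", sep="\t")
    ai_positions = {r.variant: (r.chrom, int(r.pos) - 1) for r in ai_pos.itertuples()}
    qc_reads = {
        f.stem: read_bed(f) for f in sorted((ind / "qc_reads").glob("*.bed"))
    }
    from .simulate import GroundTruth

    truth = GroundTruth(
        peaks=truth_peaks,
        de_genes=set(pd.read_csv(ind / "truth" / "de_genes.tsv", sep="\t")["gene"]),
        links=pd.read_csv(ind / "truth" / "links.tsv", sep="\t"),
        gwas_leads=list(pd.read_csv(ind / "truth" / "gwas_leads.tsv", sep="\t")["lead"]),
        gwas_peak_ids=set(pd.read_csv(ind / "truth" / "gwas_peaks.tsv", sep="\t")["peak_id"]),
        ai=pd.read_csv(ind / "truth" / "ai.tsv", sep="\t"),
    )
    return StudyData(
        config=cfg, chrom_names=sorted({p.chrom for p in peaks}), peaks=peaks, gc=gc,
        replicate_peaks=replicate_peaks, atac_counts=atac_counts, atac_samples=atac_samples,
        rna_counts=rna_counts, rna_samples=rna_samples, tss=tss,
        bait_fragments=bait_fragments, hic_pairs=hic_pairs, eqtl_signals=eqtl_signals,
        panel=panel, gwas_catalog=gwas_catalog, allele_counts_catalog=allele_counts_catalog,
        trait_efo=trait_efo, allele_counts=allele_counts, ai_variant_positions=ai_positions,
        qc_reads=qc_reads, truth=truth,
    )
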