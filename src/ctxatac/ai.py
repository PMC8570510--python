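"""Allelic imbalance in ATAC-seq reads at heterozygous variants.

Per differentiation day, variants are testable when strictly more than half
of that day's replicates carry at least 20 reads across both alleles and at
least 3 reads on each allele.  Each testable variant is fit with a
negative-binomial GLM on its 2 x R count table (one fixed effect per
replicate plus one allele effect, shared dispersion across alleles), and the
allele effect beta (log2 alt/ref) is tested against a threshold null: the
null hypothesis is |beta| <= log2(55/45), i.e. only imbalance beyond a 55:45
allelic ratio counts, which guards against calling the pervasive small
imbalances expected from noise.  Wald statistic W = (|beta| - theta)/se when
|beta| > theta, else 0; p = 2*Phi(-W) capped at 1; BH within day.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from . import nbglm
from .differential import bh_fdr
from .intervals import GenomicInterval, _ChromIndex

__all__ = ["AI_THETA", "filter_ai_variants", "ai_test", "annotate_ai"]

AI_THETA = float(np.log2(55 / 45))
LN2 = np.log(2.0)


def filter_ai_variants(
    table: pd.DataFrame,
    min_total: int = 20,
    min_each: int = 3,
    min_frac: float = 0.5,
    mode: str = "per_replicate",
) -> list[str]:
    """Variant ids testable for AI within one day's replicate set.

    ``table`` has columns variant, replicate, ref_count, alt_count (one day).
    Default reading (``per_replicate``): a replicate qualifies when
    ref+alt >= min_total AND ref >= min_each AND alt >= min_each, and the
    variant is testable when the qualifying fraction is strictly >
    ``min_frac``.  Alternative reading (``summed``): the >= min_total rule is
    applied to counts summed over replicates, the per-allele rule stays
    per-replicate.
    """
    out = []
    for variant, grp in table.groupby("variant", sort=False):
        ref = grp["ref_count"].to_numpy()
        alt = grp["alt_count"].to_numpy()
        each_ok = (ref >= min_each) & (alt >= min_each)
        if mode == "per_replicate":
            qual = each_ok & (ref + alt >= min_total)
            ok = qual.mean() > min_frac
        elif mode == "summed":
            ok = (ref.sum() + alt.sum() >= min_total) and (each_ok.mean() > min_frac)
        else:
            raise ValueError(f"unknown filter mode {mode!r}")
        if ok:
            out.append(variant)
    return out


def _fit_allele_effect(ref: np.ndarray, alt: np.ndarray, alpha: np.ndarray, n_iter: int = 40):
    """Alternating Newton fit of mu_ref = e^s_r, mu_alt = e^{s_r + c}.

    ``ref``/``alt`` are (V, R); returns (c, s) with c the natural-log allele
    effect per variant and s the per-replicate fixed effects.
    """
    a = alpha[:, None]
    tot = ref + alt
    s = np.log(np.maximum(tot, 0.5) / 2.0)
    c = np.log((alt.sum(axis=1) + 0.5) / (ref.sum(axis=1) + 0.5))
    clip = nbglm._BETA_CLIP
    for _ in range(n_iter):
        lam = np.exp(np.clip(c, -clip, clip))[:, None]
        # replicate effects: one Newton step each, all replicates at once
        mu_r = np.exp(s)
        mu_a = lam * mu_r
        f = (ref - mu_r) / (1 + a * mu_r) + (alt - mu_a) / (1 + a * mu_a)
        fp = -(mu_r * (1 + a * ref) / (1 + a * mu_r) ** 2
               + mu_a * (1 + a * alt) / (1 + a * mu_a) ** 2)
        s = np.clip(s - np.clip(f / fp, -2.0, 2.0), -clip, clip)
        # allele effect: one Newton step per variant
        mu_a = np.exp(np.clip(c, -clip, clip))[:, None] * np.exp(s)
        f_c = ((alt - mu_a) / (1 + a * mu_a)).sum(axis=1)
        fp_c = -(mu_a * (1 + a * alt) / (1 + a * mu_a) ** 2).sum(axis=1)
        c = np.clip(c - np.clip(f_c / fp_c, -2.0, 2.0), -clip, clip)
    return c, s


def _allele_se(ref, alt, s, c, alpha):
    """SE of the allele effect via the Schur complement of the Fisher info."""
    a = alpha[:, None]
    mu_r = np.exp(s)
    mu_a = np.exp(np.clip(c, -nbglm._BETA_CLIP, nbglm._BETA_CLIP))[:, None] * mu_r
    w_r = mu_r / (1 + a * mu_r)
    w_a = mu_a / (1 + a * mu_a)
    info = w_a.sum(axis=1) - (w_a**2 / (w_r + w_a)).sum(axis=1)
    return 1.0 / np.sqrt(np.maximum(info, 1e-300))


def ai_test(
    table: pd.DataFrame,
    theta: float = AI_THETA,
    alternative: str = "greater_abs",
) -> pd.DataFrame:
    """Threshold Wald test of allelic imbalance for one day's variants.

    ``table`` holds the (already filtered) variants with columns variant,
    replicate, ref_count, alt_count and optionally day.  ``alternative``:
    ``greater_abs`` (default, DESeq2 lfcThreshold/greaterAbs-style two-sided
    band test on |beta|) or ``greater`` (strictly one-sided above +theta).
    Returns one row per variant: beta (log2 alt/ref), se, p, q, significant.
    """
    if alternative not in ("greater_abs", "greater"):
        raise ValueError(f"unknown alternative {alternative!r}")
    wide_ref = table.pivot_table(index="variant", columns="replicate", values="ref_count", sort=False)
    wide_alt = table.pivot_table(index="variant", columns="replicate", values="alt_count", sort=False)
    wide_alt = wide_alt.reindex(index=wide_ref.index, columns=wide_ref.columns)
    if wide_ref.isna().any().any() or wide_alt.isna().any().any():
        raise ValueError("unbalanced replicate table: every variant needs all replicates")
    if wide_ref.shape[1] < 2:
        raise ValueError("AI testing requires >= 2 replicates")
    ref = wide_ref.to_numpy(dtype=float)
    alt = wide_alt.to_numpy(dtype=float)
    y = np.concatenate([ref, alt], axis=1)

    def mu_of(alpha_vec):
        c, s = _fit_allele_effect(ref, alt, alpha_vec)
        lam = np.exp(np.clip(c, -nbglm._BETA_CLIP, nbglm._BETA_CLIP))[:, None]
        return np.concatenate([np.exp(s), lam * np.exp(s)], axis=1)

    def cr_penalty(mu, alpha_vec):
        n_rep = ref.shape[1]
        a = alpha_vec[:, None]
        w = mu / (1 + a * mu)
        w_r, w_a = w[:, :n_rep], w[:, n_rep:]
        log_det = np.log(np.maximum(w_r + w_a, 1e-300)).sum(axis=1)
        schur = w_a.sum(axis=1) - (w_a**2 / np.maximum(w_r + w_a, 1e-300)).sum(axis=1)
        return 0.5 * (log_det + np.log(np.maximum(schur, 1e-300)))

    alpha = nbglm.alpha_mle(y, mu_of, cr_penalty=cr_penalty)
    c, s = _fit_allele_effect(ref, alt, alpha)
    beta = c / LN2  # log2(alt/ref)
    se = _allele_se(ref, alt, s, c, alpha) / LN2
    if alternative == "greater_abs":
        w = np.where(np.abs(beta) > theta, (np.abs(beta) - theta) / se, 0.0)
        p = np.minimum(2.0 * stats.norm.sf(w), 1.0)
    else:
        w = np.where(beta > theta, (beta - theta) / se, 0.0)
        p = np.where(w > 0, stats.norm.sf(w), 1.0)
    out = pd.DataFrame(
        {"beta": beta, "se": se, "p": p}, index=wide_ref.index
    )
    out["q"] = bh_fdr(out["p"])
    out["significant"] = out["q"] < 0.05
    if "day" in table.columns:
        day = table.groupby("variant", sort=False)["day"].first()
        out.insert(0, "day", day.reindex(out.index))
    return out


def annotate_ai(
    results: pd.DataFrame,
    variant_positions: dict[str, tuple[str, int]],
    context_peaks: dict[str, GenomicInterval],
    linked_ge2_peaks: set[str],
    gwas_peaks: set[str],
) -> dict:
    """Cross-tabulate significant AI variants with peaks, links, and GWAS.

    Returns per-variant containing-peak assignments plus the headline
    tallies: AI variants in context-dependent peaks, peaks with > 1 AI
    variant, AI peaks with a >= 2-method gene link, AI peaks containing GWAS
    proxies, and the triple intersection.
    """
    sig = results[results["significant"]]
    index = _ChromIndex(list(context_peaks.values())) if context_peaks else None
    variant_peak: dict[str, str] = {}
    for variant in sig.index:
        loc = variant_positions.get(variant)
        if loc is None or index is None:
            continue
        probe = GenomicInterval(loc[0], loc[1], loc[1] + 1)
        hits = index.overlapping(probe)
        if hits:
            variant_peak[variant] = hits[0].id
    peaks_with_ai: dict[str, int] = {}
    for pk in variant_peak.values():
        peaks_with_ai[pk] = peaks_with_ai.get(pk, 0) + 1
    ai_peaks = set(peaks_with_ai)
    linked = ai_peaks & linked_ge2_peaks
    gwas = ai_peaks & gwas_peaks
    return {
        "variant_peak": variant_peak,
        "n_ai_variants": int(len(sig)),
        "n_ai_variants_in_context_peaks": len(variant_peak),
        "n_context_peaks_with_ai": len(ai_peaks),
        "n_peaks_multi_ai": sum(1 for v in peaks_with_ai.values() if v > 1),
        "n_ai_peaks_linked_ge2": len(linked),
        "n_ai_peaks_with_gwas": len(gwas),
        "n_ai_peaks_linked_and_gwas": len(linked & gwas),
    }
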