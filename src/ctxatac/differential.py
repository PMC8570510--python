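"""Differential accessibility / expression testing.

Normalisation follows the depth + GC two-layer scheme: median-of-ratios size
factors handle sequencing depth, and within-sample full-quantile
normalisation across GC-content bins yields per-feature-per-sample factors
that absorb sample-specific GC amplification bias.  Each feature is then fit
with a negative-binomial GLM, log mu_ij = log(offset_ij) + beta0 + beta1 *
group_j, with per-feature ML dispersion (Cox-Reid adjusted), and the group
effect is tested with a two-sided Wald test on the log2 scale.  Multiple
testing uses Benjamini-Hochberg; the headline call is q < 0.05 and |LFC| > 1.

Timepoint comparisons are labelled "<later>_vs_<earlier>" so a positive LFC
always means more accessible/expressed at the later timepoint.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import nbglm

__all__ = [
    "size_factors",
    "gc_quantile_offsets",
    "nb_wald_test",
    "bh_fdr",
    "call_differential",
    "classify_context",
    "select_background",
    "expressed_features",
    "CONTEXT_CLASSES",
]

LN2 = np.log(2.0)
CONTEXT_CLASSES = (
    "preadipocyte_dependent",
    "adipocyte_dependent",
    "mature_adipocyte_specific",
    "other_context_dependent",
    "non_differential",
)
_COMPARISONS = ("D4_vs_D0", "D14_vs_D0", "D14_vs_D4")


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    factor_j = median over features (positive in every sample) of
    count_ij / geometric-mean_i.  Raises if no feature is positive in all
    samples (a pseudo-reference fallback would be needed for such data).
    """
    y = counts.to_numpy(dtype=float)
    if y.shape[1] == 1:
        return pd.Series([1.0], index=counts.columns, name="size_factor")
    all_pos = (y > 0).all(axis=1)
    if not all_pos.any():
        raise ValueError(
            "no feature has positive counts in every sample; "
            "median-of-ratios undefined (consider a pseudo-reference fallback)"
        )
    logs = np.log(y[all_pos])
    log_geo = logs.mean(axis=1, keepdims=True)
    log_sf = np.median(logs - log_geo, axis=0)
    log_sf = log_sf - log_sf.mean()  # geometric mean 1
    return pd.Series(np.exp(log_sf), index=counts.columns, name="size_factor")


def gc_quantile_offsets(
    counts: pd.DataFrame, gc: pd.Series, n_bins: int = 10, rescale: bool = True
) -> pd.DataFrame:
    """Within-sample full-quantile normalisation factors across GC bins.

    Features are split into ``n_bins`` equal-count bins by GC fraction.  Per
    sample, each bin's count distribution is quantile-mapped onto the mean of
    the bin-wise distributions; the returned factor is raw/normalised (1 for
    zero-count features), with each feature's row rescaled to geometric mean
    1 across samples (``rescale=False`` returns the raw quantile-map
    factors).  Multiplying size factors by these gives the GLM offset.
    """
    import warnings

    gc = gc.reindex(counts.index)
    if gc.isna().any():
        missing = gc.index[gc.isna()][:3].tolist()
        raise ValueError(f"GC fraction missing for features, e.g. {missing}")
    n_feat = counts.shape[0]
    if n_feat < n_bins:
        warnings.warn(f"only {n_feat} features; reducing GC bins to {n_feat}")
        n_bins = max(1, n_feat)
    # equal-count bins on the GC rank (ties broken by input order)
    order = np.argsort(gc.to_numpy(), kind="stable")
    bin_of = np.empty(n_feat, dtype=int)
    bin_of[order] = np.minimum((np.arange(n_feat) * n_bins) // n_feat, n_bins - 1)

    y = counts.to_numpy(dtype=float)
    factors = np.ones_like(y)
    for j in range(y.shape[1]):
        col = y[:, j]
        bin_vals = [col[bin_of == b] for b in range(n_bins)]
        for b in range(n_bins):
            vals = bin_vals[b]
            nb_ = vals.size
            if nb_ == 0:
                continue
            # within-bin quantile of each feature (average rank for ties)
            ranks = stats.rankdata(vals, method="average") - 1.0
            q = ranks / max(nb_ - 1, 1)
            # target quantile function = mean of the bin-wise quantile
            # functions, evaluated at each feature's exact quantile
            normalized = np.mean(
                [np.quantile(other, q) for other in bin_vals], axis=0
            )
            f = np.ones(nb_)
            ok = (vals > 0) & (normalized > 0)
            f[ok] = vals[ok] / normalized[ok]
            factors[bin_of == b, j] = f
    if rescale:
        # per-feature geometric mean 1 so offsets do not shift the intercept
        log_f = np.log(factors)
        factors = np.exp(log_f - log_f.mean(axis=1, keepdims=True))
    return pd.DataFrame(factors, index=counts.index, columns=counts.columns)


def nb_wald_test(
    counts: pd.DataFrame,
    groups: Mapping[str, str] | pd.Series,
    comparison: tuple[str, str],
    offsets: pd.DataFrame | None = None,
    label: str | None = None,
) -> pd.DataFrame:
    """Per-feature NB GLM Wald test of ``comparison = (test, reference)``.

    ``offsets`` is a features x samples matrix of normalisation factors
    (size factors times GC factors); defaults to all ones.  LFC is reported
    on the log2 scale as test over reference.  All-zero features get NA
    p-values and are excluded from the BH denominator.  Requires >= 2
    samples per group.
    """
    groups = pd.Series(groups)
    test_g, ref_g = comparison
    samples = [s for s in counts.columns if groups.get(s) in (test_g, ref_g)]
    y = counts[samples].to_numpy(dtype=float)
    is_test = np.array([groups[s] == test_g for s in samples])
    if is_test.sum() < 2 or (~is_test).sum() < 2:
        raise ValueError(f"comparison {comparison}: need >= 2 samples per group")
    if offsets is None:
        s = np.ones_like(y)
    else:
        s = offsets.reindex(index=counts.index, columns=samples).to_numpy(dtype=float)

    nonzero = y.sum(axis=1) > 0
    yz, sz = y[nonzero], s[nonzero]
    def fit_means(alpha_vec):
        b_ref = nbglm.newton_log_mean(yz[:, ~is_test], sz[:, ~is_test], alpha_vec)
        b_test = nbglm.newton_log_mean(yz[:, is_test], sz[:, is_test], alpha_vec)
        return b_ref, b_test

    def mu_of(alpha_vec):
        b_ref, b_test = fit_means(alpha_vec)
        mu = np.empty_like(yz)
        mu[:, ~is_test] = sz[:, ~is_test] * np.exp(b_ref)[:, None]
        mu[:, is_test] = sz[:, is_test] * np.exp(b_test)[:, None]
        return mu

    def cr_penalty(mu, alpha_vec):
        i_ref = nbglm.fisher_info_mean(mu[:, ~is_test], alpha_vec)
        i_test = nbglm.fisher_info_mean(mu[:, is_test], alpha_vec)
        return 0.5 * (np.log(np.maximum(i_ref, 1e-300)) + np.log(np.maximum(i_test, 1e-300)))

    alpha = nbglm.alpha_mle(yz, mu_of, cr_penalty=cr_penalty)
    b_ref, b_test = fit_means(alpha)
    mu_ref = sz[:, ~is_test] * np.exp(b_ref)[:, None]
    mu_test = sz[:, is_test] * np.exp(b_test)[:, None]
    i_ref = nbglm.fisher_info_mean(mu_ref, alpha)
    i_test = nbglm.fisher_info_mean(mu_test, alpha)
    se_ln = np.sqrt(1.0 / np.maximum(i_ref, 1e-300) + 1.0 / np.maximum(i_test, 1e-300))
    lfc = (b_test - b_ref) / LN2
    se = se_ln / LN2
    wald = lfc / se
    # Student-t reference with df = samples - 2: plug-in ML dispersion makes
    # the normal-reference Wald anticonservative at replicate-level n
    p = 2.0 * stats.t.sf(np.abs(wald), df=len(samples) - 2)

    n = counts.shape[0]
    out = pd.DataFrame(
        {
            "comparison": label or f"{test_g}_vs_{ref_g}",
            "base_mean": np.full(n, np.nan),
            "lfc": np.full(n, np.nan),
            "se": np.full(n, np.nan),
            "p": np.full(n, np.nan),
            "alpha": np.full(n, np.nan),
        },
        index=counts.index,
    )
    out.loc[nonzero, "base_mean"] = (yz / sz).mean(axis=1)
    out.loc[nonzero, "lfc"] = lfc
    out.loc[nonzero, "se"] = se
    out.loc[nonzero, "p"] = p
    out.loc[nonzero, "alpha"] = alpha
    out["q"] = bh_fdr(out["p"])
    return out


def bh_fdr(pvalues) -> pd.Series | np.ndarray:
    """Benjamini-Hochberg step-up q-values; NA inputs yield NA outputs."""
    p = np.asarray(pvalues, dtype=float)
    q = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    if isinstance(pvalues, pd.Series):
        return pd.Series(q, index=pvalues.index, name="q")
    return q


def call_differential(
    results: pd.DataFrame, lfc_thresh: float = 1.0, fdr: float = 0.05
) -> pd.DataFrame:
    """Flag features with q < fdr AND |lfc| > lfc_thresh (both strict)."""
    out = results.copy()
    sig = (out["q"] < fdr) & (out["lfc"].abs() > lfc_thresh)
    out["significant"] = sig.fillna(False)
    out["direction"] = np.sign(out["lfc"]).where(out["significant"], 0).astype(int)
    return out


def _sig_dir(results: Mapping[str, pd.DataFrame], key: str):
    df = results[key]
    up = df["significant"] & (df["lfc"] > 0)
    down = df["significant"] & (df["lfc"] < 0)
    return up, down


def classify_context(results: Mapping[str, pd.DataFrame]) -> pd.Series:
    """Assign each feature to one context class from the three comparisons.

    ``results`` must contain called results (see :func:`call_differential`)
    for D4_vs_D0, D14_vs_D0 and D14_vs_D4.  Precedence: preadipocyte
    (D0>D4 and D0>D14), adipocyte (D4>D0 and D14>D0), mature-adipocyte
    specific (D14>D0 and D14>D4), other (significant anywhere), else
    non-differential.
    """
    missing = [c for c in _COMPARISONS if c not in results]
    if missing:
        raise ValueError(f"missing comparisons: {missing}")
    idx = results[_COMPARISONS[0]].index
    up40, down40 = _sig_dir(results, "D4_vs_D0")
    up140, down140 = _sig_dir(results, "D14_vs_D0")
    up144, down144 = _sig_dir(results, "D14_vs_D4")
    any_sig = (
        results["D4_vs_D0"]["significant"]
        | results["D14_vs_D0"]["significant"]
        | results["D14_vs_D4"]["significant"]
    )
    cls = pd.Series("non_differential", index=idx, name="context_class")
    cls[any_sig] = "other_context_dependent"
    cls[up140 & up144] = "mature_adipocyte_specific"
    cls[up40 & up140] = "adipocyte_dependent"
    cls[down40 & down140] = "preadipocyte_dependent"
    return cls


def select_background(results: Mapping[str, pd.DataFrame]) -> pd.Index:
    """Features with q > 0.5 and |lfc| < 1 in EVERY comparison."""
    keep = None
    for df in results.values():
        ok = (df["q"] > 0.5) & (df["lfc"].abs() < 1.0)
        ok = ok.fillna(False)
        keep = ok if keep is None else (keep & ok)
    return keep[keep].index


def expressed_features(
    counts: pd.DataFrame, factors: pd.Series, min_median: float = 1.0
) -> pd.Index:
    """Features whose median depth-normalised count is >= ``min_median``."""
    norm = counts.div(factors, axis=1)
    med = norm.median(axis=1)
    return med[med >= min_median].index
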