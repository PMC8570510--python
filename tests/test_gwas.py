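"""GWAS catalog filtering, haplotype r^2, LD clumping, EFO counting."""

import numpy as np
import pandas as pd
import pytest

from ctxatac.gwas import (
    HaplotypePanel,
    compute_r2,
    efo_normalized_counts,
    expand_proxies,
    filter_catalog,
    ld_clump,
    overlap_signals_with_peaks,
)
from ctxatac.intervals import GenomicInterval


def make_panel(columns, positions=None):
    """Panel from a dict variant -> allele list."""
    df = pd.DataFrame(columns).T
    pos = positions or {v: ("chr1", 1000 + 100 * i) for i, v in enumerate(df.index)}
    return HaplotypePanel(df, pos)


def clump_oracle(records, panel, r2_thresh=0.8, window=1_000_000):
    """Pairwise removal rule, brute force over all ordered pairs."""
    per_variant = (
        records.sort_values(["p", "chrom", "pos"], kind="stable")
        .groupby("rsid", sort=False).first().reset_index()
    )
    rows = list(per_variant.itertuples())

    def key(r):
        return (r.p, r.chrom, r.pos)

    def r2(a, b):
        if a not in panel or b not in panel:
            return 0.0
        try:
            return compute_r2(panel, a, b)
        except ValueError:
            return 0.0

    survivors = []
    for r in rows:
        # r2 evaluated as (removee, remover), matching compute_r2's argument
        # orientation so exact-boundary thresholds compare identical floats
        removed = any(
            key(o) < key(r)
            and o.chrom == r.chrom
            and abs(o.pos - r.pos) <= window
            and r2(r.rsid, o.rsid) > r2_thresh
            for o in rows
        )
        if not removed:
            survivors.append(r.rsid)
    return set(survivors)


class TestFilterCatalog:
    def _records(self, rows):
        return pd.DataFrame(rows, columns=["rsid", "chrom", "pos", "trait", "p", "ref", "alt"])

    def test_p_threshold_strict(self):
        recs = self._records([
            ("rs1", "chr1", 100, "t", 5e-8, "A", "G"),
            ("rs2", "chr1", 200, "t", 4.9e-8, "A", "G"),
        ])
        out = filter_catalog(recs)
        assert list(out["rsid"]) == ["rs2"]

    def test_multiallelic_and_non_snv_dropped(self):
        recs = self._records([
            ("rs1", "chr1", 100, "t", 1e-10, "A", "G"),
            ("rs2", "chr1", 200, "t", 1e-10, "AT", "G"),   # indel
            ("rs3", "chr1", 300, "t", 1e-10, "A", "G"),    # multiallelic below
            ("rs4 x rs5", "chr1", 400, "t", 1e-10, "A", "G"),  # interaction
        ])
        out = filter_catalog(recs, {"rs1": 2, "rs2": 2, "rs3": 3})
        assert list(out["rsid"]) == ["rs1"]

    def test_unparseable_positions_dropped(self):
        recs = self._records([
            ("rs1", "chr1", "oops", "t", 1e-10, "A", "G"),
            ("rs2", "chr1", 100, "t", 1e-10, "A", "G"),
        ])
        assert list(filter_catalog(recs)["rsid"]) == ["rs2"]

    def test_random_fixture_vs_brute_force(self, rng):
        rows = []
        for i in range(100):
            p = 10.0 ** -rng.uniform(4, 12)
            ref = "A" if rng.random() < 0.8 else "AT"
            rows.append((f"rs{i}", "chr1", int(rng.integers(1, 10**6)), "t", p, ref, "G"))
        recs = self._records(rows)
        out = filter_catalog(recs)
        expect = sum(1 for r in rows if r[4] < 5e-8 and r[5] == "A")
        assert len(out) == expect


class TestComputeR2:
    def test_identical_columns(self):
        panel = make_panel({"a": [1, 1, 0, 0, 1, 0], "b": [1, 1, 0, 0, 1, 0]})
        assert compute_r2(panel, "a", "b") == pytest.approx(1.0)

    def test_independent_pair_is_zero(self):
        panel = make_panel({"a": [1, 1, 0, 0], "b": [1, 0, 1, 0]})
        assert compute_r2(panel, "a", "b") == pytest.approx(0.0)

    def test_six_haplotype_toy_vs_hand_formula(self):
        a = [1, 1, 1, 0, 0, 0]
        b = [1, 1, 0, 1, 0, 0]
        panel = make_panel({"a": a, "b": b})
        p1, q1 = np.mean(a), np.mean(b)
        p11 = np.mean(np.array(a) * np.array(b))
        expect = (p11 - p1 * q1) ** 2 / (p1 * (1 - p1) * q1 * (1 - q1))
        assert compute_r2(panel, "a", "b") == pytest.approx(expect)

    def test_symmetry(self, rng):
        cols = {f"v{i}": rng.integers(0, 2, 30).tolist() for i in range(5)}
        panel = make_panel(cols)
        for i in range(4):
            try:
                assert compute_r2(panel, f"v{i}", f"v{i+1}") == pytest.approx(
                    compute_r2(panel, f"v{i+1}", f"v{i}")
                )
            except ValueError:
                pass

    def test_monomorphic_errors(self):
        panel = make_panel({"a": [1, 1, 1, 1], "b": [1, 0, 1, 0]})
        with pytest.raises(ValueError, match="monomorphic"):
            compute_r2(panel, "a", "b")


class TestLDClump:
    def _records(self, rows):
        return pd.DataFrame(rows, columns=["rsid", "chrom", "pos", "trait", "p"])

    def _ld_pair(self, r2_high=True):
        # two variants in (nearly) perfect or in weak LD
        if r2_high:
            cols = {"rsA": [1, 1, 1, 0, 0, 0, 1, 0], "rsB": [1, 1, 1, 0, 0, 0, 1, 0]}
        else:
            cols = {"rsA": [1, 1, 1, 0, 0, 0, 1, 0], "rsB": [1, 0, 1, 0, 1, 0, 0, 1]}
        return cols

    def test_linked_pair_single_signal(self):
        panel = make_panel(self._ld_pair(), {"rsA": ("chr1", 100_000), "rsB": ("chr1", 600_000)})
        recs = self._records([
            ("rsA", "chr1", 100_000, "t1", 1e-10),
            ("rsB", "chr1", 600_000, "t2", 1e-9),
        ])
        signals = ld_clump(recs, panel)
        assert [s.lead for s in signals] == ["rsA"]
        assert signals[0].traits == {"t1", "t2"}

    def test_weak_ld_two_signals(self):
        panel = make_panel(self._ld_pair(r2_high=False),
                           {"rsA": ("chr1", 100_000), "rsB": ("chr1", 600_000)})
        recs = self._records([
            ("rsA", "chr1", 100_000, "t1", 1e-10),
            ("rsB", "chr1", 600_000, "t2", 1e-9),
        ])
        assert len(ld_clump(recs, panel)) == 2

    def test_window_rule_two_signals(self):
        panel = make_panel(self._ld_pair(), {"rsA": ("chr1", 100_000), "rsB": ("chr1", 2_100_000)})
        recs = self._records([
            ("rsA", "chr1", 100_000, "t1", 1e-10),
            ("rsB", "chr1", 2_100_000, "t2", 1e-9),
        ])
        assert len(ld_clump(recs, panel)) == 2

    def test_survivor_invariant(self, small_study):
        panel = small_study.panel
        from ctxatac.gwas import filter_catalog, _r2_safe

        recs = filter_catalog(small_study.gwas_catalog, small_study.allele_counts_catalog)
        signals = ld_clump(recs, panel)
        for i, a in enumerate(signals):
            for b in signals[i + 1 :]:
                if a.chrom == b.chrom and abs(a.pos - b.pos) <= 1_000_000:
                    assert not _r2_safe(panel, a.lead, b.lead) > 0.8

    def test_best_p_bounds_members(self, small_study):
        from ctxatac.gwas import filter_catalog

        recs = filter_catalog(small_study.gwas_catalog, small_study.allele_counts_catalog)
        for sig in ld_clump(recs, small_study.panel):
            assert all(p >= sig.best_p for _, _, p in sig.members)


class TestExpandProxies:
    def test_lead_alone(self):
        panel = make_panel({"a": [1, 0, 1, 0, 1, 0], "b": [1, 1, 0, 0, 1, 0]})
        # a-b r2 well below 0.8
        proxies = expand_proxies("a", panel)
        assert proxies == [("a", 1.0)]

    def test_perfect_block(self):
        cols = {f"v{i}": [1, 1, 1, 0, 0, 0] for i in range(5)}
        panel = make_panel(cols)
        got = {v for v, _ in expand_proxies("v0", panel)}
        assert got == {f"v{i}" for i in range(5)}

    def test_monomorphic_lead_errors(self):
        panel = make_panel({"a": [0, 0, 0, 0], "b": [1, 0, 1, 0]})
        with pytest.raises(ValueError):
            expand_proxies("a", panel)

    def test_blocks_vs_all_pairs_oracle(self, small_study):
        panel = small_study.panel
        lead = small_study.truth.gwas_leads[0]
        got = dict(expand_proxies(lead, panel))
        for v in panel.haplotypes.index:
            if v == lead:
                continue
            try:
                r2 = compute_r2(panel, lead, v)
            except ValueError:
                continue
            assert (v in got) == (r2 > 0.8)


class TestSignalPeakOverlap:
    def test_hits(self):
        cols = {"rsA": [1, 1, 0, 0, 1, 0]}
        panel = make_panel(cols, {"rsA": ("chr1", 150)})
        from ctxatac.gwas import ClumpedSignal

        sig = ClumpedSignal("rsA", "chr1", 150, 1e-10, proxies=[("rsA", 1.0)])
        peaks = [GenomicInterval("chr1", 100, 200, "pk")]
        assert overlap_signals_with_peaks([sig], peaks, panel) == [("rsA", "pk", "rsA")]
        sig_out = ClumpedSignal("rsA", "chr1", 150, 1e-10, proxies=[("rsA", 1.0)])
        panel_out = make_panel(cols, {"rsA": ("chr1", 5000)})
        assert overlap_signals_with_peaks([sig_out], peaks, panel_out) == []


class TestEFOCounts:
    def _signals(self, n, traits_per_signal):
        from ctxatac.gwas import ClumpedSignal

        out = []
        for i in range(n):
            s = ClumpedSignal(f"lead{i}", "chr1", 1000 * i, 1e-10)
            s.members = [(f"lead{i}", t, 1e-10) for t in traits_per_signal[i]]
            out.append(s)
        return out

    def test_normalised_percentage(self):
        signals = self._signals(200, [["tA"]] * 200)
        overlapping = {f"lead{i}" for i in range(30)}
        df = efo_normalized_counts(signals, overlapping, {"tA": ["term1"]}, min_total=100)
        row = df[df["term"] == "term1"].iloc[0]
        assert row["total"] == 200 and row["overlap"] == 30
        assert row["normalized"] == pytest.approx(15.0)
        assert bool(row["rank_eligible"]) and bool(row["top"])

    def test_total_99_excluded_from_ranking(self):
        signals = self._signals(99, [["tA"]] * 99)
        df = efo_normalized_counts(signals, set(), {"tA": ["term1"]}, min_total=100)
        assert not df["rank_eligible"].iloc[0] and not df["top"].iloc[0]

    def test_term_counted_once_per_signal(self):
        # one signal with two traits sharing a term
        signals = self._signals(1, [["tA", "tB"]])
        df = efo_normalized_counts(
            signals, set(), {"tA": ["shared"], "tB": ["shared"]}, min_total=1
        )
        assert df[df["term"] == "shared"]["total"].iloc[0] == 1

    def test_traits_with_5_or_more_terms_removed(self):
        signals = self._signals(10, [["big"]] * 10)
        df = efo_normalized_counts(
            signals, set(), {"big": [f"t{i}" for i in range(5)]}, min_total=1
        )
        assert df.empty

    def test_overlap_never_exceeds_total(self, rng):
        traits = [[f"t{rng.integers(3)}"] for _ in range(50)]
        signals = self._signals(50, traits)
        overlapping = {f"lead{i}" for i in range(50) if rng.random() < 0.4}
        tmap = {f"t{i}": [f"term{i}", "common"] for i in range(3)}
        df = efo_normalized_counts(signals, overlapping, tmap, min_total=1)
        assert (df["overlap"] <= df["total"]).all()
        assert df["normalized"].between(0, 100).all()
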