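"""Panel-of-normals filters, Fisher test, and the PoN-size sweep."""

import math
from fractions import Fraction
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from chpipe.pon import (
    PoNConfig,
    PoNSiteCounts,
    bonferroni_threshold,
    build_pon_index,
    fisher_exact,
    fisher_greater_pvalues,
    pon_fisher_filter,
    pon_hard_filter,
    pon_size_sweep,
)
from chpipe.variants import CallerCall, MergedVariant, VariantKey

KEY = VariantKey("chr1", 100, "A", "C")


def hypergeom_tail_oracle(a, b, c, d):
    """Exact one-sided p by summing hypergeometric probabilities.

    Enumerates every 2x2 table with the observed margins and alt count
    >= a, with exact rational arithmetic.
    """
    m, n, k = a + b, c + d, a + c
    denom = math.comb(m + n, k)
    if denom == 0:
        return 1.0
    total = Fraction(0)
    for x in range(a, min(m, k) + 1):
        if k - x > n:
            continue
        total += Fraction(math.comb(m, x) * math.comb(n, k - x), denom)
    return float(total)


def _merged(alt, depth, key=KEY):
    call = CallerCall("vardict", True, depth, alt, alt / depth)
    return MergedVariant(key, "S1", {"vardict": call}, 1, alt / depth, alt, depth, "vardict")


def _counts(per_sample, key=KEY):
    return PoNSiteCounts(key=key, per_sample=tuple(per_sample))


class TestBonferroni:
    def test_panel_value(self):
        assert bonferroni_threshold(0.05, 23650) == pytest.approx(2.1e-6, rel=0.01)

    @pytest.mark.parametrize("alpha,bp,expected", [(0.05, 1, 0.05), (0.01, 100, 1e-4)])
    def test_exact_division(self, alpha, bp, expected):
        assert bonferroni_threshold(alpha, bp) == pytest.approx(expected)

    def test_monotone(self):
        assert bonferroni_threshold(0.05, 100) < bonferroni_threshold(0.05, 10)
        assert bonferroni_threshold(0.01, 100) < bonferroni_threshold(0.05, 100)

    def test_invalid(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0)
        with pytest.raises(ValueError):
            bonferroni_threshold(1.5, 100)


class TestHardFilter:
    def test_two_samples_above_fails(self):
        counts = _counts([("P1", 25, 1000), ("P2", 25, 1000), ("P3", 0, 1000)])
        assert not pon_hard_filter(KEY, counts).passed

    def test_one_sample_above_passes(self):
        counts = _counts([("P1", 50, 1000), ("P2", 0, 1000)])
        assert pon_hard_filter(KEY, counts).passed

    def test_all_zero_passes(self):
        counts = _counts([("P1", 0, 1000), ("P2", 0, 1000)])
        assert pon_hard_filter(KEY, counts).passed

    def test_zero_depth_contributes_vaf_zero(self):
        counts = _counts([("P1", 0, 0), ("P2", 30, 1000)])
        assert pon_hard_filter(KEY, counts).passed

    def test_missing_site_passes_with_reason(self):
        verdict = pon_hard_filter(KEY, None)
        assert verdict.passed and "no PoN coverage" in verdict.reason


class TestFisherExact:
    def test_no_alt_anywhere(self):
        assert fisher_exact(0, 100, 0, 1000) == 1.0

    def test_all_zero_convention(self):
        assert fisher_exact(0, 0, 0, 0) == 1.0

    def test_against_enumeration(self):
        assert fisher_exact(10, 90, 0, 1000) == pytest.approx(
            hypergeom_tail_oracle(10, 90, 0, 1000), abs=1e-12
        )

    def test_equal_proportions_one_sided(self):
        p = fisher_exact(5, 95, 50, 950)
        assert p > 0.5
        assert p == pytest.approx(hypergeom_tail_oracle(5, 95, 50, 950), abs=1e-9)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact(-1, 10, 0, 10)

    @given(
        st.integers(0, 12), st.integers(0, 12), st.integers(0, 12), st.integers(0, 12)
    )
    def test_matches_oracle_small_tables(self, a, b, c, d):
        assert fisher_exact(a, b, c, d) == pytest.approx(
            hypergeom_tail_oracle(a, b, c, d), abs=1e-9
        )

    @given(st.integers(0, 20), st.integers(0, 200), st.integers(0, 40), st.integers(100, 400))
    def test_monotone_in_pon_alt(self, a, b, pon_alt, pon_depth):
        """More PoN background (at fixed depth) weakens the evidence."""
        if pon_alt + 1 > pon_depth:
            return
        p1 = fisher_exact(a, b, pon_alt, pon_depth - pon_alt)
        p2 = fisher_exact(a, b, pon_alt + 1, pon_depth - pon_alt - 1)
        assert p2 >= p1 - 1e-12

    @pytest.mark.parametrize("scale", [2, 5])
    def test_scaling_sample_counts_sharpens(self, scale):
        base = fisher_exact(10, 990, 10, 9990)
        scaled = fisher_exact(10 * scale, 990 * scale, 10, 9990)
        assert scaled <= base


class TestFisherFilter:
    CFG = PoNConfig()

    def test_clear_variant_passes(self):
        counts = _counts([("P1", 3, 500_000)])
        verdict = pon_fisher_filter(_merged(200, 20_000), counts, self.CFG)
        assert verdict.passed

    def test_background_proportion_fails(self):
        counts = _counts([("P1", 100, 10_000)])
        verdict = pon_fisher_filter(_merged(100, 10_000), counts, self.CFG)
        assert not verdict.passed

    def test_missing_site_default_open_configurable_closed(self):
        assert pon_fisher_filter(_merged(100, 10_000), None, self.CFG).passed
        closed = PoNConfig(missing_site_action="fail")
        assert not pon_fisher_filter(_merged(100, 10_000), None, closed).passed

    def test_verdict_records_counts(self):
        counts = _counts([("P1", 3, 500_000)])
        verdict = pon_fisher_filter(_merged(200, 20_000), counts, self.CFG)
        values = dict(verdict.values_used)
        assert values["sample_alt"] == 200
        assert values["pon_alt"] == 3
        assert values["threshold"] == pytest.approx(0.05 / 23650)


def _sweep_inputs(seed=0, n_pon=6, n_sites=12):
    rng = np.random.default_rng(seed)
    rows = []
    keys = []
    for j in range(n_sites):
        key = VariantKey("chr1", 1000 + j, "A", "G")
        keys.append(key)
        rate = 10 ** rng.uniform(-5, -3.3)
        for i in range(n_pon):
            depth = int(rng.poisson(20_000))
            rows.append({
                "chrom": key.chrom, "pos": key.pos, "ref": key.ref, "alt": key.alt,
                "pon_sample_id": f"P{i}", "alt_count": int(rng.binomial(depth, rate)),
                "depth": depth,
            })
    truth = [
        (key, int(rng.binomial(20_000, vaf)), 20_000)
        for key, vaf in zip(keys, rng.choice([5e-4, 2e-3, 1e-2], size=n_sites))
    ]
    return pd.DataFrame(rows), truth


class TestPonSizeSweep:
    def test_full_size_equals_single_full_pon(self):
        pon_df, truth = _sweep_inputs()
        out = pon_size_sweep(pon_df, truth, [6], seed=1)
        assert out.n_subsets.iloc[0] == 1 and out.exhaustive.iloc[0]
        # direct full-PoN computation
        idx = build_pon_index(pon_df)
        removed = 0
        threshold = PoNConfig().threshold
        for key, alt, depth in truth:
            c = idx[key]
            p = fisher_exact(alt, depth - alt, c.pooled_alt, c.pooled_depth - c.pooled_alt)
            removed += p >= threshold
        assert out.proportion_removed.iloc[0] == pytest.approx(removed / len(truth))

    def test_matches_exhaustive_enumeration(self):
        """Subset averaging agrees with direct enumeration for small panels."""
        pon_df, truth = _sweep_inputs(seed=3, n_pon=5, n_sites=8)
        out = pon_size_sweep(pon_df, truth, [2], seed=0)
        threshold = PoNConfig().threshold
        samples = sorted(pon_df.pon_sample_id.unique())
        per_site = {
            k: g.set_index("pon_sample_id")
            for k, g in pon_df.groupby(["chrom", "pos", "ref", "alt"])
        }
        props = []
        for subset in combinations(samples, 2):
            removed = 0
            for key, alt, depth in truth:
                g = per_site[(key.chrom, key.pos, key.ref, key.alt)].loc[list(subset)]
                p = fisher_exact(
                    alt, depth - alt,
                    int(g.alt_count.sum()), int(g.depth.sum() - g.alt_count.sum()),
                )
                removed += p >= threshold
            props.append(removed / len(truth))
        assert out.proportion_removed.iloc[0] == pytest.approx(np.mean(props), abs=1e-12)

    def test_zero_alt_pon_removes_nothing_clear(self):
        rows = [
            {"chrom": "chr1", "pos": 1000, "ref": "A", "alt": "G",
             "pon_sample_id": f"P{i}", "alt_count": 0, "depth": 20_000}
            for i in range(4)
        ]
        truth = [(VariantKey("chr1", 1000, "A", "G"), 400, 20_000)]
        out = pon_size_sweep(pd.DataFrame(rows), truth, [1, 4], seed=0)
        assert (out.proportion_removed == 0).all()

    def test_empty_truth_rejected(self):
        pon_df, _ = _sweep_inputs()
        with pytest.raises(ValueError):
            pon_size_sweep(pon_df, [], [1], seed=0)
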