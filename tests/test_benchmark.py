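"""Benchmarking: bins, exact binomial intervals, confusion, replicates."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from chpipe.benchmark import (
    DEFAULT_BIN_EDGES,
    TruthEntry,
    TruthSet,
    clopper_pearson,
    confusion_by_bin,
    define_bona_fide_orthogonal,
    replicate_concordance,
    vaf_bins,
    vaf_correlation_split,
)
from chpipe.variants import VariantKey


def _key(pos, alt="C"):
    return VariantKey("chr1", pos, "A", alt)


class TestVafBins:
    def test_default_boundaries_lower_inclusive(self):
        labels, assign = vaf_bins()
        assert assign(0.004) == labels[2]     # lower edge of the 0.4-1% bin
        assert assign(0.05) == labels[4]      # lower edge of the top bin
        assert assign(0.0005) == labels[0]
        assert assign(0.001) == labels[1]
        assert assign(1.0) == labels[4]
        assert assign(0.0) == labels[0]

    def test_bad_edges_rejected(self):
        with pytest.raises(ValueError):
            vaf_bins((0.0, 0.5, 0.5, 1.0))


def cp_inversion_oracle(x, n, confidence=0.95, grid=200_001):
    """Brute-force tail-probability inversion of the exact binomial interval."""
    alpha = 1.0 - confidence
    p = np.linspace(0.0, 1.0, grid)
    upper_tail = stats.binom.sf(x - 1, n, p)   # P(X >= x | p)
    lower_tail = stats.binom.cdf(x, n, p)      # P(X <= x | p)
    lo = 0.0 if x == 0 else p[upper_tail > alpha / 2].min()
    hi = 1.0 if x == n else p[lower_tail > alpha / 2].max()
    return lo, hi


class TestClopperPearson:
    def test_boundary_endpoints(self):
        assert clopper_pearson(0, 10)[0] == 0.0
        assert clopper_pearson(10, 10)[1] == 1.0

    def test_n_zero_absent(self):
        assert clopper_pearson(0, 0) is None

    @pytest.mark.parametrize("x,n", [(5, 10), (1, 20), (19, 20), (0, 7), (30, 100)])
    def test_matches_inversion_oracle(self, x, n):
        lo, hi = clopper_pearson(x, n)
        olo, ohi = cp_inversion_oracle(x, n)
        assert lo == pytest.approx(olo, abs=2e-5)
        assert hi == pytest.approx(ohi, abs=2e-5)

    @pytest.mark.parametrize("x,n", [(3, 9), (50, 1000), (0, 5), (5, 5)])
    def test_contains_point_estimate(self, x, n):
        lo, hi = clopper_pearson(x, n)
        assert lo <= x / n <= hi

    def test_width_shrinks_with_n(self):
        w10 = np.diff(clopper_pearson(3, 10))[0]
        w100 = np.diff(clopper_pearson(30, 100))[0]
        w1000 = np.diff(clopper_pearson(300, 1000))[0]
        assert w1000 < w100 < w10


class TestConfusionByBin:
    def _truth(self):
        return TruthSet(
            [
                TruthEntry("S1", _key(1), 0.002),
                TruthEntry("S1", _key(2), 0.02),
                TruthEntry("S2", _key(3), 0.2),
            ]
        )

    def test_perfect_recovery(self):
        truth = self._truth()
        passed = {(e.sample_id, e.key): e.expected_vaf for e in truth}
        out = confusion_by_bin(passed, truth)
        nonempty = out[(out.tp + out.fn) > 0]
        assert (nonempty.sensitivity == 1.0).all()
        assert (nonempty.ppv == 1.0).all()

    def test_nothing_passed(self):
        truth = self._truth()
        out = confusion_by_bin({}, truth)
        nonempty = out[(out.tp + out.fn) > 0]
        assert (nonempty.sensitivity == 0.0).all()
        assert nonempty.ppv.isna().all()

    def test_ppv_arithmetic(self):
        truth = TruthSet([TruthEntry("S1", _key(i), 0.02) for i in range(1, 10)])
        passed = {(e.sample_id, e.key): 0.02 for e in truth}
        passed[("S1", _key(99))] = 0.02  # one false positive in the same bin
        out = confusion_by_bin(passed, truth)
        row = out[out.tp > 0].iloc[0]
        assert row.ppv == pytest.approx(0.9)

    def test_count_conservation(self, tiny_cohort):
        from chpipe.evaluate import run_cohort, _passed_maps

        results = run_cohort(tiny_cohort)
        _, post = _passed_maps(results)
        out = confusion_by_bin(post, tiny_cohort.truth)
        assert (out.tp + out.fn).sum() == len(tiny_cohort.truth)
        assert (out.tp + out.fp).sum() == len(post)

    def test_fp_binned_by_observed_vaf(self):
        truth = TruthSet([TruthEntry("S1", _key(1), 0.2)])
        passed = {("S1", _key(1)): 0.19, ("S1", _key(5)): 0.0005}
        out = confusion_by_bin(passed, truth)
        assert out[out.bin.str.startswith("<")].fp.iloc[0] == 1


class TestBonaFideOrthogonal:
    def _results(self, **overrides):
        row = {
            "sample_id": "S1", "chrom": "chr1", "pos": 1, "ref": "A", "alt": "C",
            "rep_vaf": 0.01, "rep_alt_depth": 100, "rep_total_depth": 10_000,
            "n_callers_passed": 2, "pass_varscan_fp": True, "pass_pon_fisher": True,
        }
        row.update(overrides)
        return pd.DataFrame([row])

    def test_admitted_with_orthogonal_support(self):
        truth, _ = define_bona_fide_orthogonal(
            self._results(), {("S1", _key(1)): 6}
        )
        assert len(truth) == 1

    def test_orthogonal_boundary_strict(self):
        truth, _ = define_bona_fide_orthogonal(self._results(), {("S1", _key(1)): 5})
        assert len(truth) == 0

    def test_pon_fisher_required(self):
        truth, _ = define_bona_fide_orthogonal(
            self._results(pass_pon_fisher=False), {("S1", _key(1)): 100}
        )
        assert len(truth) == 0

    def test_uncovered_counted_separately(self):
        truth, n_uncovered = define_bona_fide_orthogonal(self._results(), {})
        assert len(truth) == 0 and n_uncovered == 1

    @pytest.mark.parametrize(
        "field,value", [("rep_vaf", 0.001), ("rep_alt_depth", 5), ("n_callers_passed", 0)]
    )
    def test_primary_criteria_strict(self, field, value):
        truth, _ = define_bona_fide_orthogonal(
            self._results(**{field: value}), {("S1", _key(1)): 100}
        )
        assert len(truth) == 0


class TestReplicateConcordance:
    def _verdicts(self, **filters):
        base = {"min_vaf": True, "pon_fisher": True, "pon_hard_vaf": True,
                "min_alt_depth": True}
        base.update(filters)
        return base

    def test_replicated(self):
        k = _key(1)
        out = replicate_concordance(
            {k: self._verdicts()}, {k}, {k: self._verdicts()}, {k}
        )
        assert out.status.tolist() == ["replicated"]

    def test_min_vaf_reason(self):
        k = _key(1)
        out = replicate_concordance(
            {k: self._verdicts()}, {k},
            {k: self._verdicts(min_vaf=False)}, set(),
        )
        assert out.status.tolist() == ["min_vaf"]

    def test_pon_reason(self):
        k = _key(1)
        out = replicate_concordance(
            {k: self._verdicts()}, {k},
            {k: self._verdicts(pon_fisher=False)}, set(),
        )
        assert out.status.tolist() == ["pon_filter"]

    def test_min_vaf_precedes_pon(self):
        k = _key(1)
        out = replicate_concordance(
            {k: self._verdicts()}, {k},
            {k: self._verdicts(min_vaf=False, pon_fisher=False)}, set(),
        )
        assert out.status.tolist() == ["min_vaf"]

    def test_other_allele_at_site(self):
        k = _key(1, "C")
        other = _key(1, "G")
        out = replicate_concordance(
            {k: self._verdicts()}, {k},
            {other: self._verdicts()}, {other},
        )
        by_key = dict(zip(out.alt, out.status))
        assert by_key["C"] == "other_allele_at_site"
        assert by_key["G"] == "other_allele_at_site"

    def test_not_called_is_other(self):
        k = _key(1)
        out = replicate_concordance({k: self._verdicts()}, {k}, {}, set())
        assert out.status.tolist() == ["other"]

    def test_exhaustive_over_union(self):
        a_only, b_only, both = _key(1), _key(2), _key(3)
        out = replicate_concordance(
            {k: self._verdicts() for k in (a_only, both)}, {a_only, both},
            {k: self._verdicts() for k in (b_only, both)}, {b_only, both},
        )
        assert len(out) == 3
        assert (out.status == "replicated").sum() == 1


class TestVafCorrelation:
    def test_identical_pairs(self):
        a = [0.0005, 0.001, 0.0015, 0.01, 0.05, 0.2]
        below, above = vaf_correlation_split(a, a)
        assert below == pytest.approx(1.0)
        assert above == pytest.approx(1.0)

    def test_anticorrelated(self):
        a = [0.01, 0.05, 0.09]
        b = [0.09, 0.05, 0.01]
        _, above = vaf_correlation_split(a, b)
        assert above == pytest.approx(-1.0)

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(4)
        a = rng.uniform(0.005, 0.2, 30)
        b = a + rng.normal(0, 0.01, 30)
        _, above = vaf_correlation_split(a, b)
        direct = float(
            np.cov(a, b)[0, 1] / np.sqrt(np.var(a, ddof=1) * np.var(b, ddof=1))
        )
        assert above == pytest.approx(direct, abs=1e-12)

    def test_small_stratum_absent(self):
        below, above = vaf_correlation_split([0.01, 0.02], [0.01, 0.02])
        assert below is None and above is not None

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            vaf_correlation_split([0.1], [0.1, 0.2])


class TestTruthSet:
    def test_duplicate_rejected(self):
        e = TruthEntry("S1", _key(1), 0.1)
        with pytest.raises(ValueError):
            TruthSet([e, e])

    def test_frame_round_trip(self):
        truth = TruthSet(
            [TruthEntry("S1", _key(1), 0.1, "dilution"),
             TruthEntry("S2", _key(2), 0.01, "orthogonal")]
        )
        back = TruthSet.from_frame(truth.to_frame())
        assert {(e.sample_id, e.key) for e in back} == {(e.sample_id, e.key) for e in truth}

    def test_invalid_vaf(self):
        with pytest.raises(ValueError):
            TruthEntry("S1", _key(1), 0.0)
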