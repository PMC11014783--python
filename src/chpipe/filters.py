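"""Post-calling false-positive filters for deep targeted CH sequencing.

Each filter is a pure, order-free predicate over a merged variant and its
auxiliary evidence, returning a :class:`FilterVerdict` that records the
decision, a human-readable reason, and the values it used.  The overall
outcome of :func:`apply_all_filters` is the conjunction of every
configured filter; no filter short-circuits another, so the full verdict
list is always available for reporting and for replicate-discordance
classification.

Filters implemented here:

* minimum alternate allele depth (default: fewer than 5 alt reads fails)
* minimum VAF (default: a variant must exceed 0.1% VAF)
* single-strand evidence (alt reads on only one strand)
* long indels (>20 bp) lacking multi-caller support
* a VarScan-style false-positive sub-filter bundle (read position,
  alt strand balance, mismatch quality sum difference, incomplete-read
  fraction), applied to externally computed read metrics
* a low-VAF/low-quality filter for variants called only by VarDictJava
* cohort-wide recurrence (>6% of samples, or >3% if never previously
  reported in large CH sequencing studies)

The two panel-of-normals filters live in :mod:`chpipe.pon` and plug into
the same verdict machinery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from .variants import CallerCall, MergedVariant, ReadMetrics, VariantKey


@dataclass(frozen=True)
class FilterVerdict:
    """Outcome of one filter for one variant."""

    filter_id: str
    passed: bool
    reason: str = ""
    values_used: tuple[tuple[str, object], ...] = ()

    def __post_init__(self) -> None:
        if not self.passed and not self.reason:
            raise ValueError(f"failing verdict for {self.filter_id} must carry a reason")


def _pass(filter_id: str, reason: str = "", **values) -> FilterVerdict:
    return FilterVerdict(filter_id, True, reason, tuple(values.items()))


def _fail(filter_id: str, reason: str, **values) -> FilterVerdict:
    return FilterVerdict(filter_id, False, reason, tuple(values.items()))


@dataclass(frozen=True)
class FilterThresholds:
    """Tunable thresholds for the artifact-filter suite.

    Defaults encode the stated inequalities exactly: alt depth below 5
    fails, VAF must strictly exceed 0.001, indels longer than 20 bp need
    at least two supporting callers, recurrence above 6% (or above 3%
    without prior CH literature support) fails.
    """

    min_alt_depth: int = 5
    min_vaf: float = 0.001
    max_singlecaller_indel_bp: int = 20
    recurrence_known: float = 0.06
    recurrence_novel: float = 0.03
    # VarScan-style fpfilter sub-thresholds
    min_readpos_fraction: float = 0.10
    strand_fraction_low: float = 0.10
    strand_fraction_high: float = 0.90
    max_mmqs_diff: float = 50.0
    max_incomplete_read_fraction: float = 0.90
    # VarDict singleton low-VAF/low-quality expression constants
    vardict_min_af_dp: float = 6.0
    vardict_mq1: float = 55.0
    vardict_nm1: float = 1.0
    vardict_mq2: float = 60.0
    vardict_nm2: float = 2.0
    vardict_min_dp: int = 10
    vardict_min_qual: float = 45.0


@dataclass(frozen=True)
class CohortContext:
    """Cohort-wide state needed by the recurrence and review heuristics.

    ``occurrence`` maps each variant key to the number of distinct cohort
    samples carrying it, computed on merged (pre-filter) calls so that
    artifact recurrence is visible even when individual copies fail other
    filters.
    """

    n_samples: int
    occurrence: Mapping[VariantKey, int] = field(default_factory=dict)
    prior_reported: frozenset[VariantKey] = frozenset()

    def occurrence_fraction(self, key: VariantKey) -> float:
        if self.n_samples <= 0:
            return 0.0
        return self.occurrence.get(key, 0) / self.n_samples


def min_alt_depth_filter(alt_depth: int, min_alt_depth: int = 5) -> FilterVerdict:
    """Fail variants supported by fewer than ``min_alt_depth`` alt reads."""
    if alt_depth < min_alt_depth:
        return _fail(
            "min_alt_depth", f"alt depth {alt_depth} < {min_alt_depth}",
            alt_depth=alt_depth, min_alt_depth=min_alt_depth,
        )
    return _pass("min_alt_depth", alt_depth=alt_depth, min_alt_depth=min_alt_depth)


def min_vaf_filter(vaf: float, min_vaf: float = 0.001) -> FilterVerdict:
    """Fail variants at or below the VAF floor (strictly greater passes)."""
    if vaf <= min_vaf:
        return _fail("min_vaf", f"vaf {vaf:.6g} <= {min_vaf:g}", vaf=vaf, min_vaf=min_vaf)
    return _pass("min_vaf", vaf=vaf, min_vaf=min_vaf)


def strand_support_filter(fwd_alt: int | None, rev_alt: int | None) -> FilterVerdict:
    """Fail variants whose alt evidence sits on a single strand.

    Zero reads on both strands also fails (no strand evidence at all);
    absent counts leave the filter not evaluable, which passes.
    """
    if fwd_alt is None or rev_alt is None:
        return _pass("strand_support", "not evaluable: strand counts absent")
    if fwd_alt > 0 and rev_alt > 0:
        return _pass("strand_support", fwd_alt=fwd_alt, rev_alt=rev_alt)
    side = "forward" if fwd_alt > 0 else "reverse" if rev_alt > 0 else "neither"
    return _fail(
        "strand_support", f"alt evidence on {side} strand only",
        fwd_alt=fwd_alt, rev_alt=rev_alt,
    )


def long_indel_filter(
    key: VariantKey, n_callers_passed: int, max_singlecaller_indel_bp: int = 20
) -> FilterVerdict:
    """Fail indels longer than the threshold unless multiple callers agree.

    Long single-caller indels are typically misaligned reads; SNVs and
    short indels always pass this filter.
    """
    length = key.indel_length
    if length > max_singlecaller_indel_bp and n_callers_passed < 2:
        return _fail(
            "long_indel",
            f"{length} bp indel supported by {n_callers_passed} caller(s)",
            indel_bp=length, n_callers_passed=n_callers_passed,
        )
    return _pass("long_indel", indel_bp=length, n_callers_passed=n_callers_passed)


def varscan_fp_filter(
    metrics: ReadMetrics | None, thresholds: FilterThresholds = FilterThresholds()
) -> FilterVerdict:
    """VarScan-style false-positive sub-filter bundle over read metrics.

    Any evaluable sub-criterion failing fails the variant; sub-criteria
    whose inputs are absent are skipped and recorded.  The sub-criteria:
    median variant position within reads at least ``min_readpos_fraction``
    from the read end; alt strand fraction inside
    [``strand_fraction_low``, ``strand_fraction_high``]; mismatch quality
    sum difference at most ``max_mmqs_diff``; incomplete-read fraction
    (alt reads not fully spanning the variant) at most
    ``max_incomplete_read_fraction``.
    """
    if metrics is None:
        return _pass("varscan_fp", "not evaluable: no read metrics")
    failures: list[str] = []
    skipped: list[str] = []
    values: dict[str, object] = {}

    if metrics.median_readpos_fraction is None:
        skipped.append("readpos")
    else:
        values["median_readpos_fraction"] = metrics.median_readpos_fraction
        if metrics.median_readpos_fraction < thresholds.min_readpos_fraction:
            failures.append(
                f"read position {metrics.median_readpos_fraction:.3g}"
                f" < {thresholds.min_readpos_fraction:g}"
            )
    if metrics.fwd_alt is None or metrics.rev_alt is None or (metrics.fwd_alt + metrics.rev_alt) == 0:
        skipped.append("strand_fraction")
    else:
        frac = metrics.fwd_alt / (metrics.fwd_alt + metrics.rev_alt)
        values["alt_strand_fraction"] = frac
        if not thresholds.strand_fraction_low <= frac <= thresholds.strand_fraction_high:
            failures.append(f"alt strand fraction {frac:.3g} outside "
                            f"[{thresholds.strand_fraction_low:g}, {thresholds.strand_fraction_high:g}]")
    if metrics.mmqs_diff is None:
        skipped.append("mmqs")
    else:
        values["mmqs_diff"] = metrics.mmqs_diff
        if metrics.mmqs_diff > thresholds.max_mmqs_diff:
            failures.append(f"mismatch quality sum diff {metrics.mmqs_diff:.3g}"
                            f" > {thresholds.max_mmqs_diff:g}")
    if metrics.incomplete_read_fraction is None:
        skipped.append("incomplete_reads")
    else:
        values["incomplete_read_fraction"] = metrics.incomplete_read_fraction
        if metrics.incomplete_read_fraction > thresholds.max_incomplete_read_fraction:
            failures.append(
                f"incomplete read fraction {metrics.incomplete_read_fraction:.3g}"
                f" > {thresholds.max_incomplete_read_fraction:g}"
            )

    if skipped:
        values["skipped"] = ",".join(skipped)
    if failures:
        return _fail("varscan_fp", "; ".join(failures), **values)
    return _pass("varscan_fp", "skipped: " + ",".join(skipped) if skipped else "", **values)


def vardict_singleton_filter(
    call: CallerCall | None,
    callers_passed: frozenset[str] | set[str],
    thresholds: FilterThresholds = FilterThresholds(),
) -> FilterVerdict:
    """Low-VAF/low-quality filter for variants passed only by VarDictJava.

    Applies only when VarDict is the sole passing caller.  Fails when the
    effective alt read mass (VAF x depth) is below ``vardict_min_af_dp``
    AND any quality clause holds: low mapping quality with elevated
    mismatches (two tiers), low total depth, or low call quality.
    Missing quality fields neutralize the corresponding clause.
    """
    if set(callers_passed) != {"vardict"} or call is None:
        return _pass("vardict_singleton", "not applicable: not a VarDict-only call")
    af_dp = call.vaf * call.total_depth
    values: dict[str, object] = {"af_dp": af_dp, "dp": call.total_depth}
    if af_dp >= thresholds.vardict_min_af_dp:
        return _pass("vardict_singleton", **values)
    mq, nm, qual = call.mapping_quality, call.mean_mismatches, call.qual
    clauses: list[tuple[str, bool]] = [
        ("mq<{:g} & nm>{:g}".format(thresholds.vardict_mq1, thresholds.vardict_nm1),
         mq is not None and nm is not None and mq < thresholds.vardict_mq1 and nm > thresholds.vardict_nm1),
        ("mq<{:g} & nm>{:g}".format(thresholds.vardict_mq2, thresholds.vardict_nm2),
         mq is not None and nm is not None and mq < thresholds.vardict_mq2 and nm > thresholds.vardict_nm2),
        (f"dp<{thresholds.vardict_min_dp}", call.total_depth < thresholds.vardict_min_dp),
        (f"qual<{thresholds.vardict_min_qual:g}", qual is not None and qual < thresholds.vardict_min_qual),
    ]
    if mq is not None:
        values["mq"] = mq
    if nm is not None:
        values["nm"] = nm
    if qual is not None:
        values["qual"] = qual
    hits = [name for name, hit in clauses if hit]
    if hits:
        return _fail(
            "vardict_singleton",
            f"af*dp {af_dp:.3g} < {thresholds.vardict_min_af_dp:g} and " + "; ".join(hits),
            **values,
        )
    return _pass("vardict_singleton", **values)


def recurrence_filter(
    occurrence_fraction: float,
    previously_reported: bool,
    thresholds: FilterThresholds = FilterThresholds(),
    n_samples: int = 2,
) -> FilterVerdict:
    """Fail cohort-recurrent variants that look like systematic artifacts.

    A variant present in more than ``recurrence_known`` (6%) of samples
    fails outright; one present in more than ``recurrence_novel`` (3%)
    fails unless it was previously identified in large-scale CH
    sequencing studies.  Cohorts of fewer than two samples cannot express
    recurrence, so the filter is not evaluable there.
    """
    if n_samples < 2:
        return _pass("recurrence", "not evaluable: cohort size < 2")
    values = {"occurrence_fraction": occurrence_fraction,
              "previously_reported": previously_reported}
    if occurrence_fraction > thresholds.recurrence_known:
        return _fail(
            "recurrence",
            f"present in {occurrence_fraction:.1%} of samples"
            f" (> {thresholds.recurrence_known:.0%})",
            **values,
        )
    if occurrence_fraction > thresholds.recurrence_novel and not previously_reported:
        return _fail(
            "recurrence",
            f"present in {occurrence_fraction:.1%} of samples"
            f" (> {thresholds.recurrence_novel:.0%}) and not previously reported",
            **values,
        )
    return _pass("recurrence", **values)


def apply_all_filters(
    merged: MergedVariant,
    *,
    metrics: ReadMetrics | None = None,
    pon_index=None,
    pon_config=None,
    cohort: CohortContext | None = None,
    thresholds: FilterThresholds = FilterThresholds(),
) -> tuple[list[FilterVerdict], bool]:
    """Evaluate every configured filter for one merged variant.

    Returns the complete verdict list (sorted by filter id, one verdict
    per filter including not-applicable/not-evaluable ones) and the
    overall conjunction.  PoN filters are included when a PoN index and
    config are supplied; recurrence requires cohort context.
    """
    from . import pon as _pon  # local import: pon depends on FilterVerdict

    verdicts = [
        min_alt_depth_filter(merged.rep_alt_depth, thresholds.min_alt_depth),
        min_vaf_filter(merged.rep_vaf, thresholds.min_vaf),
        strand_support_filter(
            merged.fwd_alt if merged.fwd_alt is not None else (metrics.fwd_alt if metrics else None),
            merged.rev_alt if merged.rev_alt is not None else (metrics.rev_alt if metrics else None),
        ),
        long_indel_filter(merged.key, merged.n_callers_passed, thresholds.max_singlecaller_indel_bp),
        varscan_fp_filter(metrics, thresholds),
        vardict_singleton_filter(
            merged.calls.get("vardict"), merged.callers_passed, thresholds
        ),
    ]
    if cohort is not None:
        verdicts.append(
            recurrence_filter(
                cohort.occurrence_fraction(merged.key),
                merged.key in cohort.prior_reported,
                thresholds,
                n_samples=cohort.n_samples,
            )
        )
    else:
        verdicts.append(_pass("recurrence", "not evaluable: no cohort context"))
    if pon_index is not None and pon_config is not None:
        counts = pon_index.get(merged.key)
        verdicts.append(
            _pon.pon_hard_filter(
                merged.key, counts,
                vaf_threshold=pon_config.hard_vaf_threshold,
                min_samples=pon_config.hard_min_samples,
            )
        )
        verdicts.append(_pon.pon_fisher_filter(merged, counts, pon_config))
    else:
        verdicts.append(_pass("pon_hard_vaf", "not evaluable: no PoN"))
        verdicts.append(_pass("pon_fisher", "not evaluable: no PoN"))
    verdicts.sort(key=lambda v: v.filter_id)
    overall = all(v.passed for v in verdicts)
    return verdicts, overall
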