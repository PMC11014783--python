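"""End-to-end orchestration: merge -> filter -> annotate -> triage.

The in-memory entry point is :func:`process_cohort`, which takes merged
per-sample variants plus the auxiliary evidence and returns one
:class:`SampleResult` per (sample, variant) with the full filter verdict
list, triage bucket and driver call.  :func:`run_pipeline` is the
file-based wrapper used by the command-line interface: it reads the
per-caller VCFs and tables, runs the cohort, and writes the three-way
pass/review/fail outputs, the per-filter report, driver calls and a
machine-readable run manifest.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import __version__ as _version
from . import io as chio
from .drivers import (
    AnnotationEvidence,
    DriverCall,
    KnowledgeBase,
    classify_driver,
    load_knowledge_base,
    read_annotation_tsv,
)
from .filters import CohortContext, FilterThresholds, FilterVerdict, apply_all_filters
from .pon import PoNConfig, build_pon_index
from .triage import TriageOutcome, germline_flag, review_flags, triage_variant
from .variants import MergedVariant, VariantKey, merge_calls

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SampleResult:
    merged: MergedVariant
    verdicts: tuple[FilterVerdict, ...]
    overall_pass: bool
    outcome: TriageOutcome
    driver: DriverCall | None

    @property
    def verdict_map(self) -> dict[str, bool]:
        return {v.filter_id: v.passed for v in self.verdicts}


def build_cohort_context(
    samples_merged: Mapping[str, Sequence[MergedVariant]],
    kb: KnowledgeBase = KnowledgeBase(),
) -> CohortContext:
    """Cohort occurrence counts over pre-filter consensus calls.

    A sample counts once per variant key when at least one caller passed
    it; recurrence is computed before filtering so that systematic
    artifacts remain visible even where individual copies fail other
    filters.
    """
    occurrence: dict[VariantKey, int] = {}
    for merged_list in samples_merged.values():
        seen = {m.key for m in merged_list if m.n_callers_passed >= 1}
        for key in seen:
            occurrence[key] = occurrence.get(key, 0) + 1
    return CohortContext(
        n_samples=len(samples_merged),
        occurrence=occurrence,
        prior_reported=frozenset(kb.prior_ch_variants),
    )


def process_cohort(
    samples_merged: Mapping[str, Sequence[MergedVariant]],
    *,
    metrics: Mapping[tuple[str, VariantKey], object] | None = None,
    pon_index=None,
    pon_config: PoNConfig | None = None,
    thresholds: FilterThresholds = FilterThresholds(),
    annotations: Mapping[VariantKey, AnnotationEvidence] | None = None,
    kb: KnowledgeBase = KnowledgeBase(),
    germline_af_threshold: float = 0.005,
) -> list[SampleResult]:
    """Run filters, driver rules and triage over every sample's variants."""
    cohort = build_cohort_context(samples_merged, kb)
    results: list[SampleResult] = []
    for sample_id in sorted(samples_merged):
        for merged in samples_merged[sample_id]:
            m = metrics.get((sample_id, merged.key)) if metrics else None
            verdicts, overall = apply_all_filters(
                merged,
                metrics=m,
                pon_index=pon_index,
                pon_config=pon_config,
                cohort=cohort,
                thresholds=thresholds,
            )
            ev = annotations.get(merged.key) if annotations else None
            germline = germline_flag(ev, germline_af_threshold)
            flags = review_flags(merged, cohort, kb) if overall and not germline else []
            outcome = triage_variant(merged, verdicts, germline, flags)
            driver = classify_driver(ev, kb) if ev is not None else None
            results.append(
                SampleResult(
                    merged=merged,
                    verdicts=tuple(verdicts),
                    overall_pass=overall,
                    outcome=outcome,
                    driver=driver,
                )
            )
    return results


def results_frame(results: Sequence[SampleResult]) -> pd.DataFrame:
    """Flatten results into one row per (sample, variant).

    Includes ``pass_<filter_id>`` booleans for every evaluated filter,
    the triage bucket with reasons, and the driver call.
    """
    rows = []
    for r in results:
        m = r.merged
        row = {
            "sample_id": m.sample_id,
            "chrom": m.key.chrom, "pos": m.key.pos, "ref": m.key.ref, "alt": m.key.alt,
            "n_callers_passed": m.n_callers_passed,
            "rep_caller": m.rep_caller,
            "rep_vaf": m.rep_vaf,
            "rep_alt_depth": m.rep_alt_depth,
            "rep_total_depth": m.rep_total_depth,
            "bucket": r.outcome.bucket,
            "reasons": ";".join(r.outcome.reasons),
            "failing_filters": ";".join(r.outcome.failing_filters),
            "is_putative_driver": r.driver.is_putative_driver if r.driver else False,
            "matched_rules": ";".join(r.driver.matched_rules) if r.driver else "",
        }
        for v in r.verdicts:
            row[f"pass_{v.filter_id}"] = v.passed
        rows.append(row)
    return pd.DataFrame(rows)


def filter_report_frame(results: Sequence[SampleResult]) -> pd.DataFrame:
    """Long-form per-(variant, filter) report with reasons and values used."""
    rows = []
    for r in results:
        m = r.merged
        for v in r.verdicts:
            rows.append({
                "sample_id": m.sample_id,
                "chrom": m.key.chrom, "pos": m.key.pos, "ref": m.key.ref, "alt": m.key.alt,
                "filter_id": v.filter_id,
                "passed": v.passed,
                "reason": v.reason,
                "values_used": ";".join(f"{k}={val}" for k, val in v.values_used),
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# file-based run

@dataclass
class RunConfig:
    """Fully serializable description of one pipeline run."""

    #: sample_id -> {caller_id -> VCF path}
    vcfs: Mapping[str, Mapping[str, str]]
    annotations_path: str | None = None
    pon_path: str | None = None
    metrics_path: str | None = None
    panel_bed: str | None = None
    panel_bp: int | None = None
    hotspots_path: str | None = None
    prior_ch_path: str | None = None
    no_pon: bool = False
    alpha: float = 0.05
    pon_sidedness: str = "greater"
    germline_af_threshold: float = 0.005
    thresholds: FilterThresholds = field(default_factory=FilterThresholds)
    out_dir: str = "."
    prefix: str = "chpipe"

    def to_jsonable(self) -> dict:
        d = dataclasses.asdict(self)
        d["vcfs"] = {s: dict(c) for s, c in self.vcfs.items()}
        return d


def run_pipeline(config: RunConfig) -> dict:
    """Execute a full file-based run and write the output bundle.

    Outputs under ``out_dir``: ``<prefix>.pass.tsv``,
    ``<prefix>.review.tsv``, ``<prefix>.fail.tsv``, the per-filter report
    ``<prefix>.filter_report.tsv``, driver calls in the main tables, and
    ``<prefix>.manifest.json`` recording the effective config, package
    version and input digests.  Returns the manifest dict.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    if config.pon_path is None and not config.no_pon:
        raise ValueError("no PoN table given; pass no_pon=True to run without one")

    samples_merged: dict[str, list[MergedVariant]] = {}
    for sample_id, caller_paths in config.vcfs.items():
        calls = {
            caller: chio.read_caller_vcf(path, caller)
            for caller, path in caller_paths.items()
        }
        samples_merged[sample_id] = merge_calls(calls, sample_id)

    pon_index = None
    pon_config = None
    if config.pon_path is not None:
        panel_bp = config.panel_bp
        if panel_bp is None and config.panel_bed is not None:
            panel_bp = chio.panel_bp_from_bed(config.panel_bed)
        if panel_bp is None:
            raise ValueError("PoN filtering needs panel_bed or panel_bp")
        pon_index = build_pon_index(chio.read_pon_tsv(config.pon_path))
        pon_config = PoNConfig(
            alpha=config.alpha, panel_bp=panel_bp, sidedness=config.pon_sidedness
        )

    metrics = chio.read_metrics_tsv(config.metrics_path) if config.metrics_path else None
    annotations = (
        read_annotation_tsv(config.annotations_path) if config.annotations_path else None
    )
    kb = load_knowledge_base(
        hotspots_path=config.hotspots_path, prior_ch_path=config.prior_ch_path
    )

    results = process_cohort(
        samples_merged,
        metrics=metrics,
        pon_index=pon_index,
        pon_config=pon_config,
        thresholds=config.thresholds,
        annotations=annotations,
        kb=kb,
        germline_af_threshold=config.germline_af_threshold,
    )

    frame = results_frame(results)
    paths = {}
    for bucket in ("PASS", "REVIEW", "FAIL"):
        sub = frame[frame.bucket == bucket] if len(frame) else frame
        p = out_dir / f"{config.prefix}.{bucket.lower()}.tsv"
        sub.to_csv(p, sep="\t", index=False, float_format="%.6g")
        paths[bucket.lower()] = str(p)
    report = filter_report_frame(results)
    report_path = out_dir / f"{config.prefix}.filter_report.tsv"
    report.to_csv(report_path, sep="\t", index=False)
    paths["filter_report"] = str(report_path)

    counts = frame.bucket.value_counts().to_dict() if len(frame) else {}
    for stage, n in sorted(counts.items()):
        log.info("triage %s: %d variants", stage, n)

    input_paths = [
        p for caller_paths in config.vcfs.values() for p in caller_paths.values()
    ]
    for p in (config.pon_path, config.metrics_path, config.annotations_path,
              config.panel_bed, config.hotspots_path, config.prior_ch_path):
        if p:
            input_paths.append(p)
    manifest = {
        "version": _version,
        "config": config.to_jsonable(),
        "input_digests": {str(p): chio.file_digest(p) for p in input_paths},
        "n_variants": int(len(frame)),
        "bucket_counts": {k: int(v) for k, v in counts.items()},
        "outputs": paths,
    }
    manifest_path = out_dir / f"{config.prefix}.manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
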