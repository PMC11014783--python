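"""Canned evaluation experiments on simulated cohorts.

These functions wire the simulator to the pipeline and the benchmark
module to measure, from scratch, the pipeline's operating
characteristics under the default study conditions: VAF-binned
sensitivity and PPV before and after filtering, the PoN-size sweep, and
technical-replicate concordance.  They are the substance behind the
package's reproducibility script and the end-to-end tests.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .benchmark import (
    confusion_by_bin,
    replicate_concordance,
    vaf_correlation_split,
)
from .drivers import annotation_from_row
from .pipeline import SampleResult, process_cohort, results_frame
from .pon import PoNConfig, build_pon_index, pon_size_sweep
from .simulate import (
    ErrorMixture,
    SimCohortConfig,
    SimulatedCohort,
    simulate_cohort,
    simulate_pon,
    simulate_sample,
    simulate_site_error_model,
)
from .variants import VariantKey, merge_calls


def run_cohort(cohort: SimulatedCohort) -> list[SampleResult]:
    """Run the full pipeline in memory on a simulated cohort."""
    annotations = {}
    for row in cohort.annotations.itertuples(index=False):
        ev = annotation_from_row(row)
        annotations[ev.key] = ev
    pon_index = build_pon_index(cohort.pon)
    pon_config = PoNConfig(panel_bp=cohort.panel.total_bp)
    samples_merged = {
        s.sample_id: merge_calls(dict(s.calls), s.sample_id) for s in cohort.samples
    }
    metrics = {
        (s.sample_id, k): m for s in cohort.samples for k, m in s.metrics.items()
    }
    return process_cohort(
        samples_merged,
        metrics=metrics,
        pon_index=pon_index,
        pon_config=pon_config,
        annotations=annotations,
    )


def _passed_maps(results: Sequence[SampleResult]) -> tuple[dict, dict]:
    """(pre-filter, post-filter) maps of (sample, key) -> observed VAF.

    Pre-filter = consensus calls passed by at least one caller;
    post-filter = the PASS triage bucket.
    """
    pre: dict[tuple[str, VariantKey], float] = {}
    post: dict[tuple[str, VariantKey], float] = {}
    for r in results:
        pair = (r.merged.sample_id, r.merged.key)
        if r.merged.n_callers_passed >= 1:
            pre[pair] = r.merged.rep_vaf
        if r.outcome.bucket == "PASS":
            post[pair] = r.merged.rep_vaf
    return pre, post


def evaluate_default_cohort(
    seed: int = 0, config: SimCohortConfig | None = None
) -> dict:
    """Simulate the default cohort, run the pipeline, and score it.

    Returns the truth set, the pre- and post-filter per-bin confusion
    tables, overall sensitivity for truth VAF >= 1%, and the results
    frame.
    """
    if config is None:
        config = SimCohortConfig(seed=seed)
    cohort = simulate_cohort(config)
    results = run_cohort(cohort)
    pre, post = _passed_maps(results)
    truth = cohort.truth
    confusion_pre = confusion_by_bin(pre, truth)
    confusion_post = confusion_by_bin(post, truth)

    high = [e for e in truth if e.expected_vaf >= 0.01]
    detected = sum(1 for e in high if (e.sample_id, e.key) in post)
    sensitivity_high = detected / len(high) if high else float("nan")
    return {
        "cohort": cohort,
        "results": results,
        "frame": results_frame(results),
        "truth": truth,
        "pre": pre,
        "post": post,
        "confusion_pre": confusion_pre,
        "confusion_post": confusion_post,
        "sensitivity_vaf_ge_1pct": sensitivity_high,
        "n_truth_vaf_ge_1pct": len(high),
    }


def ppv_improved_bins(
    confusion_pre: pd.DataFrame,
    confusion_post: pd.DataFrame,
    min_positives: int = 10,
) -> pd.DataFrame:
    """Per-bin comparison of PPV before vs after filtering.

    Bins are compared when the pre-filter set reports at least
    ``min_positives`` calls there.  A bin whose pre-filter PPV is
    already 1.0 cannot strictly improve (``improvable`` is False there);
    for such bins the relevant check is that filtering does not degrade
    it.  When filtering empties a bin, the bin counts as improved iff it
    contained no truth entries (every call there was false and every one
    was removed); losing true calls does not.
    """
    rows = []
    for pre_row, post_row in zip(
        confusion_pre.itertuples(index=False), confusion_post.itertuples(index=False)
    ):
        assert pre_row.bin == post_row.bin
        positives_pre = pre_row.tp + pre_row.fp
        if positives_pre < min_positives:
            continue
        positives_post = post_row.tp + post_row.fp
        if positives_post == 0:
            improved = (pre_row.tp + pre_row.fn) == 0
            degraded = not improved
        else:
            improved = post_row.ppv > pre_row.ppv
            degraded = post_row.ppv < pre_row.ppv
        rows.append({
            "bin": pre_row.bin,
            "ppv_pre": pre_row.ppv,
            "ppv_post": post_row.ppv,
            "positives_pre": positives_pre,
            "positives_post": positives_post,
            "improvable": pre_row.ppv < 1.0,
            "improved": bool(improved),
            "degraded": bool(degraded),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# PoN-size sweep experiment

def pon_sweep_experiment(
    seed: int = 0,
    sizes: Sequence[int] = (1, 2, 4, 8, 12, 16, 20, 27),
    n_pon: int = 27,
    depth: int = 20_000,
    n_tumors: int = 6,
    n_variants_per_tumor: int = 6,
    dilution_ratios: Sequence[float] = (10.0, 100.0, 1000.0, 5000.0),
    max_combinations: int = 300,
) -> pd.DataFrame:
    """PoN-size sweep over a simulated dilution-series truth set.

    Emulates the design of the real optimization: known tumor variants
    (source VAF 0.2-0.5) serially diluted 1:10 to 1:5000 land on panel
    sites whose background error follows the background mixture; for
    each PoN size the expected fraction of these true variants removed
    by the Fisher filter (p >= alpha/panel_bp) is averaged over PoN
    subsets.
    """
    rng = np.random.default_rng(seed)
    n_truth = n_tumors * n_variants_per_tumor * len(dilution_ratios)
    n_sites = n_tumors * n_variants_per_tumor
    model = simulate_site_error_model(
        n_sites, ErrorMixture(artifact_fraction=0.0), seed=rng
    )
    pon = simulate_pon(model, n_pon, depth, seed=rng)

    source_vafs = rng.uniform(0.2, 0.5, size=n_sites)
    truth: list[tuple[VariantKey, int, int]] = []
    for i, key in enumerate(model.keys):
        for ratio in dilution_ratios:
            vaf = source_vafs[i] / (1.0 + ratio)
            d = int(rng.poisson(depth))
            a = int(rng.binomial(d, vaf))
            truth.append((key, a, d))
    assert len(truth) == n_truth
    return pon_size_sweep(
        pon, truth, sizes, PoNConfig(), max_combinations=max_combinations,
        seed=int(rng.integers(2**31)),
    )


# ---------------------------------------------------------------------------
# replicate concordance experiment

def replicate_experiment(
    seed: int = 0,
    depth: int = 20_000,
    n_low: int = 20,
    n_high: int = 20,
    n_error_sites: int = 400,
) -> dict:
    """Technical-replicate reproducibility on one simulated sample pair.

    True variants cluster either near the detection floor (VAF around
    0.1%, where small alt-count changes dominate) or across 0.2%-20%.
    Both replicates share the truth and the site error model but draw
    reads independently; each replicate is filtered alone (single-sample
    run: recurrence not evaluable) and discordant pass calls are
    classified by the counterpart's failure reason.  Also returns the
    replicate VAF correlation below/above 0.2% for variants passing in
    both.
    """
    rng = np.random.default_rng(seed)
    model = simulate_site_error_model(n_error_sites, seed=rng)
    used = {(k.chrom, k.pos) for k in model.keys}
    from .simulate import Panel, TRUTH_SITE_FLOOR_RATE, _BASES

    panel = Panel()
    positions = [p for p in panel.positions() if (p[1], p[2]) not in used]
    chosen = rng.choice(len(positions), size=n_low + n_high, replace=False)
    low_vafs = np.exp(rng.uniform(np.log(8e-4), np.log(1.5e-3), size=n_low))
    high_vafs = np.exp(rng.uniform(np.log(2e-3), np.log(0.2), size=n_high))
    vafs = np.concatenate([low_vafs, high_vafs])
    truths: list[tuple[VariantKey, float]] = []
    for i, idx in enumerate(chosen):
        _, chrom, pos, _ = positions[idx]
        ref = str(_BASES[rng.integers(0, 4)])
        alt = str(_BASES[(list(_BASES).index(ref) + int(rng.integers(1, 4))) % 4])
        truths.append((VariantKey(chrom, pos, ref, alt), float(vafs[i])))

    from .simulate import SiteErrorModel

    full_model = SiteErrorModel(
        sites=tuple(sorted(
            list(model.sites) + [(k, TRUTH_SITE_FLOOR_RATE) for k, _ in truths],
            key=lambda s: s[0],
        ))
    )
    pon = simulate_pon(full_model, 27, depth, seed=rng)
    pon_index = build_pon_index(pon)
    pon_config = PoNConfig(panel_bp=panel.total_bp)

    rep_results = {}
    for rep in ("A", "B"):
        sample = simulate_sample(
            full_model, truths, depth, seed=rng, sample_id=f"rep{rep}"
        )
        merged = merge_calls(dict(sample.calls), sample.sample_id)
        metrics = {(sample.sample_id, k): m for k, m in sample.metrics.items()}
        results = process_cohort(
            {sample.sample_id: merged},
            metrics=metrics, pon_index=pon_index, pon_config=pon_config,
        )
        rep_results[rep] = {
            "verdicts": {r.merged.key: r.verdict_map for r in results},
            "passed": {r.merged.key for r in results if r.outcome.bucket == "PASS"},
            "vaf": {r.merged.key: r.merged.rep_vaf for r in results},
        }

    concordance = replicate_concordance(
        rep_results["A"]["verdicts"], rep_results["A"]["passed"],
        rep_results["B"]["verdicts"], rep_results["B"]["passed"],
    )
    both = sorted(rep_results["A"]["passed"] & rep_results["B"]["passed"])
    vaf_a = [rep_results["A"]["vaf"][k] for k in both]
    vaf_b = [rep_results["B"]["vaf"][k] for k in both]
    corr_below, corr_above = vaf_correlation_split(vaf_a, vaf_b, split=0.002)
    status_counts = (
        concordance.status.value_counts().to_dict() if len(concordance) else {}
    )
    return {
        "concordance": concordance,
        "status_counts": status_counts,
        "n_pass_union": int(len(rep_results["A"]["passed"] | rep_results["B"]["passed"])),
        "corr_below": corr_below,
        "corr_above": corr_above,
        "n_pairs": len(both),
    }
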