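"""Three-way triage: partition variants into PASS, REVIEW, and FAIL.

FAIL collects variants rejected by any artifact filter or flagged as
possible germline; REVIEW collects variants that pass every filter but
exhibit characteristics that historically needed a human look (complex
indels supported by a single caller, variants recurring across samples
without any prior literature support); everything else is PASS.  FAIL
dominates REVIEW dominates PASS, and every variant lands in exactly one
bucket.  Driver annotation is reported for all three buckets — review
never blocks it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .drivers import AnnotationEvidence, KnowledgeBase
from .filters import CohortContext, FilterVerdict
from .variants import MergedVariant, VariantKey

BUCKETS = ("PASS", "REVIEW", "FAIL")


@dataclass(frozen=True)
class TriageOutcome:
    key: VariantKey
    sample_id: str
    bucket: str
    reasons: tuple[str, ...] = ()
    failing_filters: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.bucket not in BUCKETS:
            raise ValueError(f"bucket must be one of {BUCKETS}, got {self.bucket!r}")
        if self.bucket == "FAIL" and not (self.failing_filters or self.reasons):
            raise ValueError("FAIL outcome must carry failing filters or a germline reason")


def germline_flag(
    ev: AnnotationEvidence | None, threshold: float = 0.005
) -> bool:
    """Possible-germline heuristic: population allele frequency above threshold.

    gnomAD AF > 0.005 marks a variant as likely inherited rather than
    clonal.  Deliberately no VAF-based (~50%/100%) inference: large CH
    clones legitimately reach high VAFs.  Absent annotation or AF means
    not flagged.
    """
    if ev is None or ev.gnomad_af is None:
        return False
    return ev.gnomad_af > threshold


def review_flags(
    merged: MergedVariant,
    cohort: CohortContext | None,
    kb: KnowledgeBase,
) -> list[str]:
    """Manual-review heuristics for variants that pass every filter.

    ``complex_indel_single_caller``: a length-changing event whose ref
    and alt both span multiple bases, supported by exactly one caller —
    the classic misalignment signature.  ``recurrent_not_reported``: seen
    in two or more cohort samples yet absent from the prior-CH knowledge
    lists.
    """
    flags: list[str] = []
    if merged.key.is_complex_indel and merged.n_callers_passed == 1:
        flags.append("complex_indel_single_caller")
    if cohort is not None:
        n_occ = cohort.occurrence.get(merged.key, 0)
        known = (
            merged.key in kb.prior_ch_variants
            or merged.key in cohort.prior_reported
        )
        if n_occ >= 2 and not known:
            flags.append("recurrent_not_reported")
    return flags


def triage_variant(
    merged: MergedVariant,
    verdicts: Sequence[FilterVerdict],
    germline: bool,
    review_reasons: Sequence[str],
) -> TriageOutcome:
    """Combine filter verdicts and heuristics into one bucket.

    Precedence: any failing filter or germline flag -> FAIL; otherwise
    any review reason -> REVIEW; otherwise PASS.
    """
    failing = tuple(v.filter_id for v in verdicts if not v.passed)
    reasons: list[str] = [f"filter:{v.filter_id}:{v.reason}" for v in verdicts if not v.passed]
    if germline:
        reasons.append("possible_germline")
    if failing or germline:
        bucket = "FAIL"
    elif review_reasons:
        bucket = "REVIEW"
        reasons = list(review_reasons)
    else:
        bucket = "PASS"
    return TriageOutcome(
        key=merged.key,
        sample_id=merged.sample_id,
        bucket=bucket,
        reasons=tuple(reasons),
        failing_filters=failing,
    )
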