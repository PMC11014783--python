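"""Variant data model, allele normalization, and multi-caller consensus merging.

Somatic calls for one sample arrive as per-caller VCFs (Mutect2-,
VarDictJava-, LoFreq2- and optionally Pindel-style).  Every record is
reduced to a :class:`VariantKey` — a parsimony-trimmed (chrom, pos, ref,
alt) tuple that serves as the join key across callers, the panel of
normals, annotation tables and truth sets — and the per-caller evidence
is merged into one :class:`MergedVariant` per distinct key, carrying the
consensus support count (how many callers emitted a passing call) and a
representative depth/VAF chosen by a configurable caller priority.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

log = logging.getLogger(__name__)

#: Callers understood by the pipeline, in default representative-metric
#: priority order.  Mutect2 ranks first because its reported depths come
#: from assembly realignment; the order is configurable everywhere it is
#: used.
KNOWN_CALLERS = ("mutect2", "lofreq2", "vardict", "pindel")

#: Callers whose passing calls count toward consensus support by default.
#: Pindel is excluded from the consensus count (it remains in the
#: evidence) because of its discordant singleton behaviour on short
#: indels; pass ``counted_callers`` explicitly to include it.
DEFAULT_COUNTED_CALLERS = ("mutect2", "lofreq2", "vardict")

_VALID_BASES = frozenset("ACGTN")


class NonVariantError(ValueError):
    """Raised when ref and alt describe the same sequence."""


@dataclass(frozen=True, order=True)
class VariantKey:
    """A normalized genomic change.

    Coordinates are 1-based and fully closed, matching VCF.  Alleles are
    uppercase and parsimony-trimmed: no common suffix remains, and no
    common prefix remains unless removing it would empty an allele.
    """

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise ValueError("ref and alt must be non-empty")
        if self.ref == self.alt:
            raise NonVariantError(f"ref == alt ({self.ref!r}) is not a variant")
        for allele in (self.ref, self.alt):
            if not set(allele) <= _VALID_BASES:
                raise ValueError(f"allele {allele!r} contains non-ACGTN characters")

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def indel_length(self) -> int:
        """Absolute length change (0 for SNVs and balanced substitutions)."""
        return abs(len(self.ref) - len(self.alt))

    @property
    def is_complex_indel(self) -> bool:
        """Length-changing event where both alleles span multiple bases."""
        return self.indel_length > 0 and len(self.ref) > 1 and len(self.alt) > 1

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"


def trim_alleles(chrom: str, pos: int, ref: str, alt: str) -> VariantKey:
    """Parsimony-trim an allele pair into a normalized :class:`VariantKey`.

    Shared trailing bases are removed first; shared leading bases are then
    removed while both alleles retain more than one base, advancing ``pos``
    by one per removed leading base.  This reproduces allele-trimming
    normalization (left-alignment against the reference genome is out of
    scope; inputs are expected pre-normalized or trim-only).

    Raises
    ------
    NonVariantError
        If ref equals alt (before or after trimming there is no change).
    ValueError
        If either allele is empty.
    """
    ref = ref.upper()
    alt = alt.upper()
    if not ref or not alt:
        raise ValueError("ref and alt must be non-empty")
    if ref == alt:
        raise NonVariantError(f"{chrom}:{pos} {ref}>{alt} is not a variant")
    # shared suffix
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    # shared prefix
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return VariantKey(chrom=chrom, pos=int(pos), ref=ref, alt=alt)


@dataclass(frozen=True)
class CallerCall:
    """One caller's evidence for one variant in one sample."""

    caller_id: str
    passed: bool
    total_depth: int
    alt_depth: int
    vaf: float
    fwd_alt: int | None = None
    rev_alt: int | None = None
    qual: float | None = None
    mapping_quality: float | None = None
    mean_mismatches: float | None = None

    def __post_init__(self) -> None:
        if self.caller_id not in KNOWN_CALLERS:
            raise ValueError(f"unknown caller {self.caller_id!r}")
        if not 0 <= self.alt_depth <= self.total_depth:
            raise ValueError(
                f"alt_depth {self.alt_depth} outside [0, total_depth={self.total_depth}]"
            )
        if not 0.0 <= self.vaf <= 1.0:
            raise ValueError(f"vaf {self.vaf} outside [0, 1]")
        if self.fwd_alt is not None and self.rev_alt is not None:
            if self.fwd_alt + self.rev_alt != self.alt_depth:
                raise ValueError(
                    f"strand counts {self.fwd_alt}+{self.rev_alt} != alt_depth {self.alt_depth}"
                )


@dataclass(frozen=True)
class ReadMetrics:
    """Read-level support metrics consumed from an upstream pileup table.

    All fields are optional; an absent metric renders the corresponding
    artifact sub-filter "not evaluable" rather than failing the variant.
    """

    key: VariantKey
    median_readpos_fraction: float | None = None
    fwd_alt: int | None = None
    rev_alt: int | None = None
    mean_alt_baseq: float | None = None
    mmqs_diff: float | None = None
    incomplete_read_fraction: float | None = None

    def __post_init__(self) -> None:
        for name in ("median_readpos_fraction", "incomplete_read_fraction"):
            value = getattr(self, name)
            if value is not None and not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} {value} outside [0, 1]")


@dataclass(frozen=True)
class MergedVariant:
    """One variant in one sample, with evidence from every caller that saw it."""

    key: VariantKey
    sample_id: str
    calls: Mapping[str, CallerCall]
    n_callers_passed: int
    rep_vaf: float
    rep_alt_depth: int
    rep_total_depth: int
    rep_caller: str

    @property
    def callers_passed(self) -> frozenset[str]:
        return frozenset(c for c, call in self.calls.items() if call.passed)

    @property
    def fwd_alt(self) -> int | None:
        return self.calls[self.rep_caller].fwd_alt

    @property
    def rev_alt(self) -> int | None:
        return self.calls[self.rep_caller].rev_alt


def merge_calls(
    calls_by_caller: Mapping[str, Iterable[tuple[VariantKey, CallerCall]]],
    sample_id: str,
    *,
    priority: Sequence[str] = KNOWN_CALLERS,
    counted_callers: Sequence[str] | None = None,
) -> list[MergedVariant]:
    """Merge per-caller call lists for one sample into consensus records.

    Every distinct normalized key in the union of inputs yields exactly one
    :class:`MergedVariant`.  ``n_callers_passed`` counts passing calls from
    ``counted_callers`` (all non-Pindel callers by default); calls that a
    caller emitted but filtered remain in the evidence without contributing
    to the count.  Representative VAF/depths are taken from the
    highest-priority caller with a passing call, falling back to the
    highest-priority call of any status when nothing passed.

    Duplicate records from a single caller for the same key keep the one
    with the higher alt depth (a warning is logged); this tolerates caller
    quirks rather than aborting a run.
    """
    if counted_callers is None:
        counted_callers = DEFAULT_COUNTED_CALLERS
    counted = frozenset(counted_callers)
    by_key: dict[VariantKey, dict[str, CallerCall]] = {}
    for caller_id, calls in calls_by_caller.items():
        for key, call in calls:
            if call.caller_id != caller_id:
                call = replace(call, caller_id=caller_id)
            slot = by_key.setdefault(key, {})
            if caller_id in slot:
                kept = max(slot[caller_id], call, key=lambda c: c.alt_depth)
                log.warning(
                    "duplicate %s record for %s in %s; keeping alt_depth=%d",
                    caller_id, key, sample_id, kept.alt_depth,
                )
                slot[caller_id] = kept
            else:
                slot[caller_id] = call

    rank = {caller: i for i, caller in enumerate(priority)}
    merged: list[MergedVariant] = []
    for key in sorted(by_key):
        calls = by_key[key]
        n_passed = sum(1 for c, call in calls.items() if call.passed and c in counted)
        passing = [c for c in calls.values() if c.passed]
        pool = passing if passing else list(calls.values())
        rep = min(pool, key=lambda c: rank.get(c.caller_id, len(rank)))
        merged.append(
            MergedVariant(
                key=key,
                sample_id=sample_id,
                calls=dict(sorted(calls.items())),
                n_callers_passed=n_passed,
                rep_vaf=rep.vaf,
                rep_alt_depth=rep.alt_depth,
                rep_total_depth=rep.total_depth,
                rep_caller=rep.caller_id,
            )
        )
    return merged
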