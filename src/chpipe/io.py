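"""Readers and writers for the pipeline's file formats.

VCF access goes through :mod:`pysam`; tabular interchange formats (merged
variants, PoN counts, read metrics, annotations, truth sets) are
tab-separated files read and written with :mod:`pandas`.  All coordinates
in tables are 1-based VCF-style; BED input is converted from 0-based
half-open on load.
"""

from __future__ import annotations

import hashlib
import logging
import math
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
import pysam

from .variants import (
    CallerCall,
    MergedVariant,
    NonVariantError,
    ReadMetrics,
    VariantKey,
    trim_alleles,
)

log = logging.getLogger(__name__)

MERGED_COLUMNS = [
    "sample_id", "chrom", "pos", "ref", "alt", "n_callers_passed",
    "rep_caller", "rep_vaf", "rep_alt_depth", "rep_total_depth",
    "fwd_alt", "rev_alt",
]


def _is_symbolic(alt: str) -> bool:
    return alt.startswith("<") or "[" in alt or "]" in alt or alt in (".", "*")


def split_multiallelic(
    record: pysam.VariantRecord, sample: str | None = None
) -> list[tuple[VariantKey, dict]]:
    """Decompose a VCF record into one (key, evidence) pair per alt allele.

    Each alt allele is trimmed independently against the shared ref.
    Per-allele alt depths are apportioned from the AD field when present;
    the total depth is repeated for every allele.  Symbolic alleles
    (``<DEL>``, breakends, spanning deletions) are skipped with a warning.
    """
    out: list[tuple[VariantKey, dict]] = []
    if not record.alts:
        return out
    samp = record.samples[sample] if sample else record.samples[0] if record.samples else None
    formats = record.header.formats
    ad = samp.get("AD") if samp is not None and "AD" in formats else None
    dp = samp.get("DP") if samp is not None and "DP" in formats else None
    if dp is None and "DP" in record.header.info:
        dp = record.info.get("DP")
    for i, alt in enumerate(record.alts):
        if _is_symbolic(alt):
            log.warning("skipping symbolic allele %s at %s:%d", alt, record.chrom, record.pos)
            continue
        try:
            key = trim_alleles(record.chrom, record.pos, record.ref, alt)
        except NonVariantError:
            log.warning("skipping non-variant allele at %s:%d", record.chrom, record.pos)
            continue
        alt_depth = None
        if ad is not None and len(ad) > i + 1 and ad[i + 1] is not None:
            alt_depth = int(ad[i + 1])
        out.append((key, {"alt_index": i, "alt_depth": alt_depth, "total_depth": dp}))
    return out


def read_caller_vcf(
    path: str | Path, caller_id: str, sample: str | None = None
) -> list[tuple[VariantKey, CallerCall]]:
    """Read one caller's VCF into normalized (key, call) pairs.

    The FILTER column defines the caller-native pass status: PASS or
    missing ('.') means passed, anything else means present-but-filtered.
    Depth and allelic depth come from FORMAT DP/AD; strand-split alt
    counts from FORMAT SB (ref-fwd, ref-rev, alt-fwd, alt-rev) or INFO
    DP4.  Optional quality fields (MQ, NM) populate the VarDict singleton
    filter when present.
    """
    calls: list[tuple[VariantKey, CallerCall]] = []
    with pysam.VariantFile(str(path)) as vcf:
        has_mq = "MQ" in vcf.header.info
        has_nm = "NM" in vcf.header.info
        has_dp4 = "DP4" in vcf.header.info
        for record in vcf:
            passed = (not record.filter.keys()) or ("PASS" in record.filter.keys())
            samp = record.samples[sample] if sample else (
                record.samples[0] if len(record.samples) else None
            )
            fwd = rev = None
            sb = samp.get("SB") if samp is not None and "SB" in vcf.header.formats else None
            if sb is not None and len(sb) == 4:
                fwd, rev = int(sb[2]), int(sb[3])
            elif has_dp4 and "DP4" in record.info:
                dp4 = record.info["DP4"]
                fwd, rev = int(dp4[2]), int(dp4[3])
            mq = record.info.get("MQ") if has_mq else None
            if isinstance(mq, tuple):
                mq = mq[0]
            nm = record.info.get("NM") if has_nm else None
            if isinstance(nm, tuple):
                nm = nm[0]
            for key, ev in split_multiallelic(record, sample=sample):
                total = int(ev["total_depth"] or 0)
                alt_depth = ev["alt_depth"]
                if alt_depth is None:
                    alt_depth = 0
                alt_depth = min(int(alt_depth), total)
                vaf = alt_depth / total if total else 0.0
                strand_ok = fwd is not None and rev is not None and fwd + rev == alt_depth
                calls.append(
                    (
                        key,
                        CallerCall(
                            caller_id=caller_id,
                            passed=passed,
                            total_depth=total,
                            alt_depth=alt_depth,
                            vaf=vaf,
                            fwd_alt=fwd if strand_ok else None,
                            rev_alt=rev if strand_ok else None,
                            qual=float(record.qual) if record.qual is not None else None,
                            mapping_quality=float(mq) if mq is not None else None,
                            mean_mismatches=float(nm) if nm is not None else None,
                        ),
                    )
                )
    return calls


# ---------------------------------------------------------------------------
# merged-variant table

_CALL_FIELDS = (
    "passed", "total_depth", "alt_depth", "vaf", "fwd_alt", "rev_alt",
    "qual", "mapping_quality", "mean_mismatches",
)


def merged_to_frame(variants: Iterable[MergedVariant]) -> pd.DataFrame:
    rows = []
    for v in variants:
        row = {
            "sample_id": v.sample_id,
            "chrom": v.key.chrom,
            "pos": v.key.pos,
            "ref": v.key.ref,
            "alt": v.key.alt,
            "n_callers_passed": v.n_callers_passed,
            "rep_caller": v.rep_caller,
            "rep_vaf": v.rep_vaf,
            "rep_alt_depth": v.rep_alt_depth,
            "rep_total_depth": v.rep_total_depth,
            "fwd_alt": v.fwd_alt,
            "rev_alt": v.rev_alt,
        }
        for caller, call in v.calls.items():
            for f in _CALL_FIELDS:
                row[f"{caller}_{f}"] = getattr(call, f)
        rows.append(row)
    return pd.DataFrame(rows)


def merged_from_frame(df: pd.DataFrame) -> dict[str, list[MergedVariant]]:
    """Rebuild merged-variant records (grouped by sample) from the table."""
    from .variants import KNOWN_CALLERS

    def _opt(value, cast):
        if value is None or (isinstance(value, float) and math.isnan(value)):
            return None
        return cast(value)

    out: dict[str, list[MergedVariant]] = {}
    for row in df.itertuples(index=False):
        key = VariantKey(str(row.chrom), int(row.pos), row.ref, row.alt)
        calls: dict[str, CallerCall] = {}
        for caller in KNOWN_CALLERS:
            passed = getattr(row, f"{caller}_passed", None)
            if passed is None or (isinstance(passed, float) and math.isnan(passed)):
                continue
            calls[caller] = CallerCall(
                caller_id=caller,
                passed=bool(passed),
                total_depth=int(getattr(row, f"{caller}_total_depth")),
                alt_depth=int(getattr(row, f"{caller}_alt_depth")),
                vaf=float(getattr(row, f"{caller}_vaf")),
                fwd_alt=_opt(getattr(row, f"{caller}_fwd_alt", None), int),
                rev_alt=_opt(getattr(row, f"{caller}_rev_alt", None), int),
                qual=_opt(getattr(row, f"{caller}_qual", None), float),
                mapping_quality=_opt(getattr(row, f"{caller}_mapping_quality", None), float),
                mean_mismatches=_opt(getattr(row, f"{caller}_mean_mismatches", None), float),
            )
        out.setdefault(str(row.sample_id), []).append(
            MergedVariant(
                key=key,
                sample_id=str(row.sample_id),
                calls=calls,
                n_callers_passed=int(row.n_callers_passed),
                rep_vaf=float(row.rep_vaf),
                rep_alt_depth=int(row.rep_alt_depth),
                rep_total_depth=int(row.rep_total_depth),
                rep_caller=str(row.rep_caller),
            )
        )
    return out


def write_merged_tsv(variants: Iterable[MergedVariant], path: str | Path) -> None:
    # %.17g keeps doubles exact across the write/read round trip
    merged_to_frame(variants).to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_merged_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", dtype={"chrom": str, "sample_id": str},
        float_precision="round_trip",
    )
    missing = [c for c in MERGED_COLUMNS[:10] if c not in df.columns]
    if missing:
        raise ValueError(f"merged table {path} lacks columns {missing}")
    return df


# ---------------------------------------------------------------------------
# PoN counts

def read_pon_tsv(path: str | Path) -> pd.DataFrame:
    """Load per-PoN-sample allele counts.

    Required columns: chrom, pos, ref, alt, pon_sample_id, alt_count,
    depth.  Pooled totals are always derived downstream, never read.
    """
    df = pd.read_csv(
        path, sep="\t",
        dtype={"chrom": str, "pon_sample_id": str, "pos": int, "alt_count": int, "depth": int},
    )
    required = ["chrom", "pos", "ref", "alt", "pon_sample_id", "alt_count", "depth"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"PoN table {path} lacks columns {missing}")
    bad = df[(df.alt_count < 0) | (df.alt_count > df.depth)]
    if len(bad):
        first = bad.iloc[0]
        raise ValueError(
            f"PoN table {path}: alt_count > depth at "
            f"{first.chrom}:{first.pos} sample {first.pon_sample_id}"
        )
    return df


def write_pon_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# read metrics

def read_metrics_tsv(path: str | Path) -> dict[tuple[str, VariantKey], ReadMetrics]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "sample_id": str})
    out: dict[tuple[str, VariantKey], ReadMetrics] = {}
    optional = [
        "median_readpos_fraction", "fwd_alt", "rev_alt",
        "mean_alt_baseq", "mmqs_diff", "incomplete_read_fraction",
    ]
    for row in df.itertuples(index=False):
        key = VariantKey(row.chrom, int(row.pos), row.ref, row.alt)
        kwargs = {}
        for name in optional:
            value = getattr(row, name, None)
            if value is not None and not (isinstance(value, float) and math.isnan(value)):
                kwargs[name] = int(value) if name in ("fwd_alt", "rev_alt") else float(value)
        out[(str(row.sample_id), key)] = ReadMetrics(key=key, **kwargs)
    return out


# ---------------------------------------------------------------------------
# panel BED

def panel_bp_from_bed(path: str | Path) -> int:
    """Total merged length of a panel BED (0-based half-open) in bp."""
    df = pd.read_csv(
        path, sep="\t", header=None, usecols=[0, 1, 2],
        names=["chrom", "start", "end"], comment="#",
        dtype={"chrom": str, "start": int, "end": int},
    )
    if ((df.end <= df.start) | (df.start < 0)).any():
        raise ValueError(f"BED {path} contains empty or negative intervals")
    total = 0
    for _, group in df.groupby("chrom", sort=False):
        cur_start = cur_end = None
        for start, end in sorted(zip(group.start, group.end)):
            if cur_end is None or start > cur_end:
                if cur_end is not None:
                    total += cur_end - cur_start
                cur_start, cur_end = start, end
            else:
                cur_end = max(cur_end, end)
        if cur_end is not None:
            total += cur_end - cur_start
    return int(total)


# ---------------------------------------------------------------------------
# misc

def file_digest(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def iter_frame_keys(df: pd.DataFrame) -> Iterator[VariantKey]:
    for row in df.itertuples(index=False):
        yield VariantKey(str(row.chrom), int(row.pos), row.ref, row.alt)
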