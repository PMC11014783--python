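"""Benchmarking: truth sets, VAF-binned sensitivity/PPV, replicate concordance.

Sensitivity here is the fraction of known ("bona fide") variants the
pipeline reports within a VAF stratum; PPV is the fraction of reported
variants that are bona fide.  PPV is used instead of specificity because
the space of true negatives at every panel position is uncountable.
Confidence intervals are exact binomial (Clopper-Pearson).  Truth sets
come from three procedures: dilution-series provenance (expected VAF =
source VAF scaled by the dilution), orthogonal-platform support, and
technical-replicate support.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .variants import VariantKey

TRUTH_SOURCES = ("dilution", "orthogonal", "replicate", "simulated")

#: Default VAF strata: <0.1%, 0.1-0.4%, 0.4-1%, 1-5%, >5%.
#: Lower-inclusive / upper-exclusive; the top bin includes 1.0.
DEFAULT_BIN_EDGES = (0.0, 0.001, 0.004, 0.01, 0.05, 1.0)


@dataclass(frozen=True)
class TruthEntry:
    sample_id: str
    key: VariantKey
    expected_vaf: float
    source: str = "simulated"

    def __post_init__(self) -> None:
        if not 0.0 < self.expected_vaf <= 1.0:
            raise ValueError(f"expected_vaf {self.expected_vaf} outside (0, 1]")
        if self.source not in TRUTH_SOURCES:
            raise ValueError(f"unknown truth source {self.source!r}")


class TruthSet:
    """A set of bona fide (sample, variant) pairs with expected VAFs."""

    def __init__(self, entries: Iterable[TruthEntry] = ()):
        self._entries: dict[tuple[str, VariantKey], TruthEntry] = {}
        for e in entries:
            k = (e.sample_id, e.key)
            if k in self._entries:
                raise ValueError(f"duplicate truth entry for {k}")
            self._entries[k] = e

    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, pair: tuple[str, VariantKey]) -> bool:
        return pair in self._entries

    def __iter__(self):
        return iter(self._entries.values())

    def expected_vaf(self, sample_id: str, key: VariantKey) -> float:
        return self._entries[(sample_id, key)].expected_vaf

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "sample_id": e.sample_id, "chrom": e.key.chrom, "pos": e.key.pos,
                    "ref": e.key.ref, "alt": e.key.alt,
                    "expected_vaf": e.expected_vaf, "source": e.source,
                }
                for e in self
            ]
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TruthSet":
        return cls(
            TruthEntry(
                sample_id=str(r.sample_id),
                key=VariantKey(str(r.chrom), int(r.pos), r.ref, r.alt),
                expected_vaf=float(r.expected_vaf),
                source=str(getattr(r, "source", "simulated")),
            )
            for r in df.itertuples(index=False)
        )


# ---------------------------------------------------------------------------
# binning

def vaf_bins(edges: Sequence[float] = DEFAULT_BIN_EDGES):
    """Return (labels, assign) for a VAF binning scheme.

    Bins are lower-inclusive/upper-exclusive except the last, which
    includes its upper edge, so e.g. VAF exactly 0.05 falls in the top
    (">5%") bin under the default edges.
    """
    edges = tuple(float(e) for e in edges)
    if any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValueError("bin edges must be strictly increasing")
    labels = []
    for i, (lo, hi) in enumerate(zip(edges, edges[1:])):
        if i == 0 and lo == 0.0:
            labels.append(f"<{hi:.4g}")
        elif i == len(edges) - 2 and hi >= 1.0:
            labels.append(f">={lo:.4g}")
        else:
            labels.append(f"[{lo:.4g},{hi:.4g})")

    def assign(vaf: float) -> str:
        if not 0.0 <= vaf <= edges[-1]:
            raise ValueError(f"vaf {vaf} outside [0, {edges[-1]}]")
        idx = int(np.searchsorted(edges, vaf, side="right")) - 1
        idx = min(max(idx, 0), len(labels) - 1)
        return labels[idx]

    return labels, assign


def clopper_pearson(x: int, n: int, confidence: float = 0.95) -> tuple[float, float] | None:
    """Exact (Clopper-Pearson) binomial confidence interval for x/n.

    Returns None for n = 0 (no information).  Endpoints are exact at the
    boundaries: lower = 0 when x = 0, upper = 1 when x = n.
    """
    if n == 0:
        return None
    if not 0 <= x <= n:
        raise ValueError(f"x {x} outside [0, n={n}]")
    lo, hi = proportion_confint(x, n, alpha=1.0 - confidence, method="beta")
    return float(lo), float(hi)


def confusion_by_bin(
    passed: Mapping[tuple[str, VariantKey], float],
    truth: TruthSet,
    edges: Sequence[float] = DEFAULT_BIN_EDGES,
    confidence: float = 0.95,
) -> pd.DataFrame:
    """Per-VAF-bin confusion counts with sensitivity, PPV and exact CIs.

    ``passed`` maps reported (sample, key) pairs to their observed
    representative VAF.  True/false negatives and positives bin by the
    truth's expected VAF; false positives — which have no truth VAF by
    definition — bin by observed VAF.  Undefined ratios (0/0) are
    reported as NaN, never coerced to 0.
    """
    labels, assign = vaf_bins(edges)
    tp = {lab: 0 for lab in labels}
    fp = {lab: 0 for lab in labels}
    fn = {lab: 0 for lab in labels}
    for entry in truth:
        lab = assign(entry.expected_vaf)
        if (entry.sample_id, entry.key) in passed:
            tp[lab] += 1
        else:
            fn[lab] += 1
    for pair, vaf in passed.items():
        if pair not in truth:
            fp[assign(min(max(vaf, 0.0), 1.0))] += 1

    rows = []
    for lab, lo, hi in zip(labels, edges, edges[1:]):
        t, f, miss = tp[lab], fp[lab], fn[lab]
        sens = t / (t + miss) if (t + miss) else math.nan
        ppv = t / (t + f) if (t + f) else math.nan
        sens_ci = clopper_pearson(t, t + miss, confidence) if (t + miss) else None
        ppv_ci = clopper_pearson(t, t + f, confidence) if (t + f) else None
        rows.append({
            "bin": lab, "vaf_lo": lo, "vaf_hi": hi,
            "tp": t, "fp": f, "fn": miss,
            "sensitivity": sens, "ppv": ppv,
            "sensitivity_lo": sens_ci[0] if sens_ci else math.nan,
            "sensitivity_hi": sens_ci[1] if sens_ci else math.nan,
            "ppv_lo": ppv_ci[0] if ppv_ci else math.nan,
            "ppv_hi": ppv_ci[1] if ppv_ci else math.nan,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# truth-set construction

def define_bona_fide_orthogonal(
    primary_results: pd.DataFrame,
    orthogonal_alt_counts: Mapping[tuple[str, VariantKey], int | None],
    min_alt_orthogonal: int = 5,
    min_vaf: float = 0.001,
    min_alt_depth: int = 5,
    required_filters: Sequence[str] = ("varscan_fp", "pon_fisher"),
    source: str = "orthogonal",
) -> tuple[TruthSet, int]:
    """Admit variants with independent support on an orthogonal platform.

    Primary-platform criteria: VAF strictly above ``min_vaf``, alt depth
    strictly above ``min_alt_depth``, passed by at least one caller, and
    passing a reduced filter set — by default the incomplete-read-count
    (VarScan-style) filter and the PoN Fisher test.  Surviving variants
    are admitted when the orthogonal platform shows strictly more than
    ``min_alt_orthogonal`` alt reads.  Variants whose orthogonal site is
    uncovered are excluded and counted separately (second return value).

    ``primary_results`` needs columns: sample_id, chrom, pos, ref, alt,
    rep_vaf, rep_alt_depth, n_callers_passed, and ``pass_<filter_id>``
    booleans for each required filter.
    """
    entries: list[TruthEntry] = []
    n_uncovered = 0
    for row in primary_results.itertuples(index=False):
        key = VariantKey(str(row.chrom), int(row.pos), row.ref, row.alt)
        if row.rep_vaf <= min_vaf:
            continue
        if row.rep_alt_depth <= min_alt_depth:
            continue
        if row.n_callers_passed < 1:
            continue
        if not all(bool(getattr(row, f"pass_{f}")) for f in required_filters):
            continue
        ortho = orthogonal_alt_counts.get((str(row.sample_id), key))
        if ortho is None:
            n_uncovered += 1
            continue
        if ortho > min_alt_orthogonal:
            entries.append(
                TruthEntry(str(row.sample_id), key, float(row.rep_vaf), source)
            )
    return TruthSet(entries), n_uncovered


# ---------------------------------------------------------------------------
# replicate concordance

#: Reason precedence for variants passing in exactly one replicate,
#: matching the granularity of the observed failure taxonomy.
DISCORDANCE_PRECEDENCE = ("min_vaf", "pon_filter", "other_allele_at_site", "other")

_PON_FILTER_IDS = ("pon_fisher", "pon_hard_vaf")


def replicate_concordance(
    results_a: Mapping[VariantKey, Mapping[str, bool]],
    passed_a: set[VariantKey],
    results_b: Mapping[VariantKey, Mapping[str, bool]],
    passed_b: set[VariantKey],
) -> pd.DataFrame:
    """Classify variants by replication status across technical replicates.

    ``results_x`` maps every called key in replicate x to its per-filter
    pass booleans; ``passed_x`` is the final pass set.  Variants passing
    in both replicates are ``replicated``; a variant passing in exactly
    one is classified by what happened in the counterpart, with
    precedence min_vaf > pon_filter > other_allele_at_site > other.
    Classification is exhaustive over the union of the two pass sets.
    """
    rows = []
    for key in sorted(passed_a | passed_b):
        if key in passed_a and key in passed_b:
            rows.append({"status": "replicated", "detail": "", "key": key})
            continue
        counterpart, counterpart_passed = (
            (results_b, passed_b) if key in passed_a else (results_a, passed_a)
        )
        status, detail = _classify_discordant(key, counterpart, counterpart_passed)
        rows.append({
            "status": status, "detail": detail, "key": key,
        })
    df = pd.DataFrame(rows)
    if len(df):
        df["chrom"] = [k.chrom for k in df.key]
        df["pos"] = [k.pos for k in df.key]
        df["ref"] = [k.ref for k in df.key]
        df["alt"] = [k.alt for k in df.key]
    return df


def _classify_discordant(
    key: VariantKey,
    counterpart: Mapping[VariantKey, Mapping[str, bool]],
    counterpart_passed: set[VariantKey],
) -> tuple[str, str]:
    verdicts = counterpart.get(key)
    if verdicts is not None:
        if not verdicts.get("min_vaf", True):
            return "min_vaf", "below VAF cut-off in counterpart"
        failed_pon = [f for f in _PON_FILTER_IDS if not verdicts.get(f, True)]
        if failed_pon:
            return "pon_filter", ",".join(failed_pon)
    other_allele = [
        k for k in counterpart_passed
        if k.chrom == key.chrom and k.pos == key.pos and k != key
    ]
    if other_allele:
        return "other_allele_at_site", str(other_allele[0])
    if verdicts is not None:
        failed = sorted(f for f, ok in verdicts.items() if not ok)
        if failed:
            return "other", "failed:" + ",".join(failed)
        return "other", "called but not passed"
    return "other", "not called in counterpart"


def vaf_correlation_split(
    vaf_a: Sequence[float],
    vaf_b: Sequence[float],
    split: float = 0.002,
) -> tuple[float | None, float | None]:
    """Pearson VAF correlation between replicates, below and above a split.

    Pairs are stratified by their mean VAF (< split vs >= split); a
    stratum with fewer than two pairs yields None.
    """
    a = np.asarray(vaf_a, dtype=float)
    b = np.asarray(vaf_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("replicate VAF vectors differ in length")
    mean = (a + b) / 2.0
    out = []
    for mask in (mean < split, mean >= split):
        if mask.sum() < 2 or np.std(a[mask]) == 0 or np.std(b[mask]) == 0:
            out.append(1.0 if mask.sum() >= 2 and np.allclose(a[mask], b[mask]) else None)
            continue
        out.append(float(np.corrcoef(a[mask], b[mask])[0, 1]))
    return out[0], out[1]
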