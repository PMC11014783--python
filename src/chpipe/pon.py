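"""Panel-of-normals (PoN) error model and filters.

Deep targeted sequencing carries a position-specific background error
rate; a panel of technical-control samples sequenced on the same assay
provides an empirical estimate of that rate at every panel position.
Two filters are derived from it:

* a hard filter removing variants seen above 2% VAF in two or more PoN
  samples (replicating the caller-internal PoN behaviour), and
* a Fisher exact test comparing the sample's alt/ref allele counts with
  the pooled PoN counts; a variant survives only when its alt fraction is
  significantly above the PoN background at a family-wise threshold of
  alpha divided by the panel size in base pairs (Bonferroni over every
  testable position: 0.05 / 23 650 bp ~= 2.1e-6 for the nine-gene panel
  the defaults are modelled on).

The module also provides the PoN-size sweep: for a range of panel sizes
k, the expected proportion of known true variants that the Fisher filter
would (wrongly) remove, averaged over subsets of the available PoN
samples — full enumeration when feasible, seeded sampling beyond a cap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .filters import FilterVerdict, _fail, _pass
from .variants import MergedVariant, VariantKey


@dataclass(frozen=True)
class PoNSiteCounts:
    """Per-site alt/depth counts across PoN samples, with pooled totals."""

    key: VariantKey
    per_sample: tuple[tuple[str, int, int], ...]  # (pon_sample_id, alt_count, depth)

    def __post_init__(self) -> None:
        for sid, alt, depth in self.per_sample:
            if not 0 <= alt <= depth:
                raise ValueError(f"PoN sample {sid}: alt {alt} outside [0, depth={depth}]")

    @property
    def pooled_alt(self) -> int:
        return sum(alt for _, alt, _ in self.per_sample)

    @property
    def pooled_depth(self) -> int:
        return sum(depth for _, _, depth in self.per_sample)

    def n_samples_above_vaf(self, vaf_threshold: float) -> int:
        return sum(
            1 for _, alt, depth in self.per_sample
            if depth > 0 and alt / depth > vaf_threshold
        )


@dataclass(frozen=True)
class PoNConfig:
    """Configuration of the PoN filters.

    ``alpha`` is the family-wise error rate and ``panel_bp`` the panel
    capture size in base pairs; the per-test significance threshold is
    their ratio.  ``sidedness`` selects the Fisher alternative: the
    default ``greater`` keeps a variant only when its alt fraction
    significantly exceeds the PoN background.  ``missing_site_action``
    governs sites absent from the PoN table (``pass`` with a warning by
    default, since the PoN covers the whole panel and a missing site
    means the variant falls outside it; ``fail`` is the closed option).
    """

    alpha: float = 0.05
    panel_bp: int = 23650
    sidedness: str = "greater"
    hard_vaf_threshold: float = 0.02
    hard_min_samples: int = 2
    missing_site_action: str = "pass"

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha {self.alpha} outside (0, 1)")
        if self.panel_bp < 1:
            raise ValueError(f"panel_bp must be positive, got {self.panel_bp}")
        if self.sidedness not in ("greater", "two_sided"):
            raise ValueError(f"sidedness must be 'greater' or 'two_sided', got {self.sidedness!r}")
        if self.missing_site_action not in ("pass", "fail"):
            raise ValueError("missing_site_action must be 'pass' or 'fail'")

    @property
    def threshold(self) -> float:
        return bonferroni_threshold(self.alpha, self.panel_bp)


def bonferroni_threshold(alpha: float, panel_bp: int) -> float:
    """Per-test significance threshold: alpha divided by the panel size in bp.

    Every base pair in the capture region is a potential test, so the
    family-wise rate alpha is split across ``panel_bp`` hypotheses.
    """
    if panel_bp < 1:
        raise ValueError(f"panel_bp must be >= 1, got {panel_bp}")
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha {alpha} outside (0, 1)")
    return alpha / panel_bp


def fisher_exact(
    sample_alt: int, sample_ref: int, pon_alt: int, pon_ref: int,
    sidedness: str = "greater",
) -> float:
    """Fisher exact test of sample vs pooled-PoN allele proportions.

    ``greater`` tests whether the sample's alt proportion exceeds the
    PoN's (one-sided hypergeometric tail); ``two_sided`` sums all tables
    as or less probable than the observed one.  An all-zero table yields
    p = 1 by convention.
    """
    for name, c in (("sample_alt", sample_alt), ("sample_ref", sample_ref),
                    ("pon_alt", pon_alt), ("pon_ref", pon_ref)):
        if c < 0:
            raise ValueError(f"{name} must be >= 0, got {c}")
    total = sample_alt + sample_ref + pon_alt + pon_ref
    if total == 0:
        return 1.0
    if sidedness == "greater":
        return float(
            fisher_greater_pvalues(
                np.array([sample_alt]), np.array([sample_ref]),
                np.array([pon_alt]), np.array([pon_ref]),
            )[0]
        )
    if sidedness == "two_sided":
        table = [[sample_alt, sample_ref], [pon_alt, pon_ref]]
        return float(stats.fisher_exact(table, alternative="two-sided")[1])
    raise ValueError(f"unknown sidedness {sidedness!r}")


def fisher_greater_pvalues(
    sample_alt: np.ndarray, sample_ref: np.ndarray,
    pon_alt: np.ndarray, pon_ref: np.ndarray,
) -> np.ndarray:
    """Vectorized one-sided ('greater') Fisher exact p-values.

    P(X >= sample_alt) under the hypergeometric null with the observed
    margins; used heavily by the PoN-size sweep where millions of tables
    are evaluated.
    """
    sample_alt = np.asarray(sample_alt, dtype=np.int64)
    sample_ref = np.asarray(sample_ref, dtype=np.int64)
    pon_alt = np.asarray(pon_alt, dtype=np.int64)
    pon_ref = np.asarray(pon_ref, dtype=np.int64)
    total = sample_alt + sample_ref + pon_alt + pon_ref
    k_alt = sample_alt + pon_alt          # total alt successes
    n_sample = sample_alt + sample_ref    # sample margin
    with np.errstate(invalid="ignore"):
        p = stats.hypergeom.sf(sample_alt - 1, total, k_alt, n_sample)
    return np.where(total == 0, 1.0, p)


# ---------------------------------------------------------------------------
# site index

def build_pon_index(pon_df: pd.DataFrame) -> dict[VariantKey, PoNSiteCounts]:
    """Group a per-sample PoN counts table into per-site objects."""
    index: dict[VariantKey, PoNSiteCounts] = {}
    grouped = pon_df.groupby(["chrom", "pos", "ref", "alt"], sort=True)
    for (chrom, pos, ref, alt), group in grouped:
        key = VariantKey(str(chrom), int(pos), ref, alt)
        per_sample = tuple(
            (str(r.pon_sample_id), int(r.alt_count), int(r.depth))
            for r in group.itertuples(index=False)
        )
        index[key] = PoNSiteCounts(key=key, per_sample=per_sample)
    return index


# ---------------------------------------------------------------------------
# filters

def pon_hard_filter(
    key: VariantKey,
    counts: PoNSiteCounts | None,
    vaf_threshold: float = 0.02,
    min_samples: int = 2,
) -> FilterVerdict:
    """Fail variants above ``vaf_threshold`` VAF in >= ``min_samples`` PoN samples.

    A PoN sample with zero depth contributes VAF 0.  A site with no PoN
    coverage passes with a "no PoN coverage" reason.
    """
    if counts is None:
        return _pass("pon_hard_vaf", "no PoN coverage at site")
    n_above = counts.n_samples_above_vaf(vaf_threshold)
    values = {"n_pon_above_vaf": n_above, "vaf_threshold": vaf_threshold}
    if n_above >= min_samples:
        return _fail(
            "pon_hard_vaf",
            f"VAF > {vaf_threshold:.0%} in {n_above} PoN samples (>= {min_samples})",
            **values,
        )
    return _pass("pon_hard_vaf", **values)


def pon_fisher_filter(
    merged: MergedVariant,
    counts: PoNSiteCounts | None,
    config: PoNConfig = PoNConfig(),
) -> FilterVerdict:
    """Keep a variant only when its alt fraction beats the PoN background.

    The sample's representative alt/ref counts are compared with the
    pooled PoN counts by Fisher's exact test; the variant passes iff
    p < alpha / panel_bp.
    """
    if counts is None:
        if config.missing_site_action == "fail":
            return _fail("pon_fisher", "no PoN coverage at site (fail-closed)")
        return _pass("pon_fisher", "no PoN coverage at site")
    sample_alt = merged.rep_alt_depth
    sample_ref = merged.rep_total_depth - merged.rep_alt_depth
    p = fisher_exact(
        sample_alt, sample_ref, counts.pooled_alt,
        counts.pooled_depth - counts.pooled_alt, config.sidedness,
    )
    threshold = config.threshold
    values = {
        "p_value": p, "threshold": threshold,
        "sample_alt": sample_alt, "sample_ref": sample_ref,
        "pon_alt": counts.pooled_alt, "pon_depth": counts.pooled_depth,
    }
    if p < threshold:
        return _pass("pon_fisher", **values)
    return _fail(
        "pon_fisher",
        f"not significantly above PoN background (p={p:.3g} >= {threshold:.3g})",
        **values,
    )


# ---------------------------------------------------------------------------
# PoN size sweep

def pon_size_sweep(
    pon_df: pd.DataFrame,
    truth: Sequence[tuple[VariantKey, int, int]],
    sizes: Iterable[int],
    config: PoNConfig = PoNConfig(),
    max_combinations: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Expected fraction of true variants removed by the Fisher filter vs PoN size.

    ``truth`` lists (key, sample_alt, sample_depth) for known true
    variants.  For each requested size k, subsets of the PoN samples are
    either fully enumerated (when C(n, k) <= ``max_combinations``) or
    sampled uniformly with the given seed; for each subset the pooled
    counts are recomputed and the proportion of truth variants with
    p >= alpha/panel_bp (i.e. removed as background) is averaged.

    Returns a frame with columns (size, proportion_removed, n_subsets,
    exhaustive).
    """
    truth = list(truth)
    if not truth:
        raise ValueError("truth set is empty")
    pon_samples = sorted(pon_df["pon_sample_id"].astype(str).unique())
    n = len(pon_samples)
    sizes = sorted(set(int(s) for s in sizes))
    if any(s < 1 or s > n for s in sizes):
        raise ValueError(f"sizes must lie in [1, {n}]")

    # per-variant x per-PoN-sample count matrices, zero where uncovered;
    # a key may appear in several truth entries (e.g. dilution levels)
    keys = [t[0] for t in truth]
    cols_by_key: dict[VariantKey, list[int]] = {}
    for j, k in enumerate(keys):
        cols_by_key.setdefault(k, []).append(j)
    alt_mat = np.zeros((n, len(keys)), dtype=np.int64)
    dep_mat = np.zeros((n, len(keys)), dtype=np.int64)
    sample_pos = {s: i for i, s in enumerate(pon_samples)}
    for row in pon_df.itertuples(index=False):
        key = VariantKey(str(row.chrom), int(row.pos), row.ref, row.alt)
        cols = cols_by_key.get(key)
        if cols is None:
            continue
        i = sample_pos[str(row.pon_sample_id)]
        for j in cols:
            alt_mat[i, j] = row.alt_count
            dep_mat[i, j] = row.depth

    sample_alt = np.array([t[1] for t in truth], dtype=np.int64)
    sample_ref = np.array([t[2] - t[1] for t in truth], dtype=np.int64)
    threshold = config.threshold
    rng = np.random.default_rng(seed)

    rows = []
    for k in sizes:
        n_comb = math.comb(n, k)
        if n_comb <= max_combinations:
            subsets = np.array(list(combinations(range(n), k)), dtype=np.intp)
            exhaustive = True
        else:
            subsets = np.array(
                [rng.choice(n, size=k, replace=False) for _ in range(max_combinations)],
                dtype=np.intp,
            )
            exhaustive = False
        pooled_alt = alt_mat[subsets].sum(axis=1)   # (n_subsets, n_truth)
        pooled_dep = dep_mat[subsets].sum(axis=1)
        p = fisher_greater_pvalues(
            np.broadcast_to(sample_alt, pooled_alt.shape),
            np.broadcast_to(sample_ref, pooled_alt.shape),
            pooled_alt, pooled_dep - pooled_alt,
        )
        removed = (p >= threshold).mean(axis=1)     # per subset
        rows.append({
            "size": k,
            "proportion_removed": float(removed.mean()),
            "n_subsets": len(subsets),
            "exhaustive": exhaustive,
        })
    return pd.DataFrame(rows)
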