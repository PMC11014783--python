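"""Seeded simulator for deep targeted CH sequencing cohorts.

The simulator produces everything the pipeline consumes — per-caller
VCFs, a panel-of-normals count table, read-metrics and annotation
tables, a panel BED, and a matching truth set — with the statistical
structure the filters assume:

* a nine-gene panel (23 650 bp total) with per-site error rates drawn
  from a two-component mixture: a log-uniform background over
  [1e-5, 2e-4] alt fraction and a small artifact-prone component
  (default 2% of sites) log-uniform over [2e-4, 5e-2], spanning the
  0.02%-5% VAF range over which real panels show intrinsic error;
* binomial read sampling at high depth (default mean 20 000x, Poisson
  per site), with a 50:50 binomial strand split;
* true variants injected at configurable VAFs, with tumor:normal
  dilution arithmetic (expected VAF = source VAF / (1 + ratio)) for
  dilution-series cohorts;
* threshold-based caller emulation: VarDict-like (>= 3 alt reads, no
  VAF floor — hence it dominates low-VAF singletons), LoFreq-like
  (>= 5 reads and VAF >= 5e-4), Mutect-like (>= 8 reads and
  VAF >= 2e-3).  A caller emits a present-but-filtered record when the
  read floor is met but the VAF floor is not.

Error is modelled post-consensus at the site level (UMI consensus
building is upstream of this package), so artifact VAFs realize the
error-rate range directly.  Everything is deterministic under a fixed
seed, including emitted file bytes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from .benchmark import TruthEntry, TruthSet
from .variants import CallerCall, ReadMetrics, VariantKey

log = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"))

#: Synthetic nine-gene panel; (gene, chrom, start, length) with lengths
#: summing to 23 650 bp.  Coordinates are arbitrary but fixed so that
#: fixtures are stable and BED/VCF outputs are internally consistent.
DEFAULT_PANEL_GENES: tuple[tuple[str, str, int, int], ...] = (
    ("DNMT3A", "chr2", 25_234_300, 3500),
    ("SF3B1", "chr2", 197_389_000, 1950),
    ("TET2", "chr4", 105_145_000, 6500),
    ("JAK2", "chr9", 5_021_000, 1500),
    ("TP53", "chr17", 7_668_000, 2500),
    ("PPM1D", "chr17", 60_600_000, 500),
    ("SRSF2", "chr17", 76_734_500, 700),
    ("ASXL1", "chr20", 32_358_000, 4500),
    ("CHEK2", "chr22", 28_687_000, 2000),
)

#: Residual per-site error at panel positions outside the modelled
#: error-prone subset (true-variant sites).  Far below every caller's
#: read floor at 20 000x, matching the observed dominance of a small
#: error-prone site subset in real panels.
TRUTH_SITE_FLOOR_RATE = 1e-6

#: Caller emulation floors: caller -> (min alt reads, min VAF).
DEFAULT_CALLER_THRESHOLDS: Mapping[str, tuple[int, float]] = {
    "vardict": (3, 0.0),
    "lofreq2": (5, 5e-4),
    "mutect2": (8, 2e-3),
}


@dataclass(frozen=True)
class Panel:
    genes: tuple[tuple[str, str, int, int], ...] = DEFAULT_PANEL_GENES

    @property
    def total_bp(self) -> int:
        return sum(length for _, _, _, length in self.genes)

    def gene_at(self, chrom: str, pos: int) -> str | None:
        for gene, g_chrom, start, length in self.genes:
            if g_chrom == chrom and start < pos <= start + length:
                return gene
        return None

    def positions(self) -> list[tuple[str, int, str, int]]:
        """All (gene, chrom, pos, offset) positions, 1-based."""
        out = []
        for gene, chrom, start, length in self.genes:
            for off in range(length):
                out.append((gene, chrom, start + off + 1, off))
        return out

    def write_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for gene, chrom, start, length in sorted(self.genes, key=lambda g: (g[1], g[2])):
                fh.write(f"{chrom}\t{start}\t{start + length}\t{gene}\n")


@dataclass(frozen=True)
class ErrorMixture:
    """Two-component per-site error-rate mixture (alt-read probabilities)."""

    background_lo: float = 1e-5
    background_hi: float = 2e-4
    artifact_fraction: float = 0.02
    artifact_lo: float = 2e-4
    artifact_hi: float = 5e-2

    def __post_init__(self) -> None:
        for rate in (self.background_lo, self.background_hi, self.artifact_lo, self.artifact_hi):
            if not 0.0 < rate < 0.5:
                raise ValueError(f"error rate {rate} outside (0, 0.5)")
        if not 0.0 <= self.artifact_fraction <= 1.0:
            raise ValueError("artifact_fraction outside [0, 1]")


@dataclass(frozen=True)
class SiteErrorModel:
    """Per-site error rates over a set of panel positions."""

    sites: tuple[tuple[VariantKey, float], ...]

    def __post_init__(self) -> None:
        for key, rate in self.sites:
            if not 0.0 < rate < 0.5:
                raise ValueError(f"rate {rate} at {key} outside (0, 0.5)")

    @property
    def keys(self) -> tuple[VariantKey, ...]:
        return tuple(k for k, _ in self.sites)

    @property
    def rates(self) -> np.ndarray:
        return np.array([r for _, r in self.sites])


def _loguniform(rng: np.random.Generator, lo: float, hi: float, size: int) -> np.ndarray:
    return np.exp(rng.uniform(np.log(lo), np.log(hi), size=size))


def simulate_site_error_model(
    n_sites: int,
    mixture: ErrorMixture = ErrorMixture(),
    seed: int | np.random.Generator = 0,
    panel: Panel = Panel(),
) -> SiteErrorModel:
    """Draw per-site error rates at ``n_sites`` distinct panel positions.

    Each site becomes an SNV key (random ref/alt bases) at a position
    sampled without replacement from the panel; a seeded draw assigns it
    to the artifact-prone component with probability
    ``mixture.artifact_fraction`` and a log-uniform rate from the
    matching range.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    positions = panel.positions()
    if n_sites > len(positions):
        raise ValueError(f"n_sites {n_sites} exceeds panel size {len(positions)}")
    chosen = rng.choice(len(positions), size=n_sites, replace=False)
    is_artifact = rng.random(n_sites) < mixture.artifact_fraction
    rates = np.where(
        is_artifact,
        _loguniform(rng, mixture.artifact_lo, mixture.artifact_hi, n_sites),
        _loguniform(rng, mixture.background_lo, mixture.background_hi, n_sites),
    )
    ref_idx = rng.integers(0, 4, size=n_sites)
    alt_shift = rng.integers(1, 4, size=n_sites)
    sites = []
    for i, idx in enumerate(chosen):
        _, chrom, pos, _ = positions[idx]
        ref = _BASES[ref_idx[i]]
        alt = _BASES[(ref_idx[i] + alt_shift[i]) % 4]
        sites.append((VariantKey(chrom, pos, str(ref), str(alt)), float(rates[i])))
    sites.sort(key=lambda s: s[0])
    return SiteErrorModel(sites=tuple(sites))


def simulate_pon(
    model: SiteErrorModel,
    n_pon: int,
    depth: int,
    seed: int | np.random.Generator = 0,
    sample_dispersion: float = 0.0,
) -> pd.DataFrame:
    """Simulate a PoN count table over the model's sites.

    Per PoN sample and site: depth ~ Poisson(depth), alt count ~
    Binomial(depth, rate).  ``sample_dispersion`` > 0 multiplies each PoN
    sample's rates by a lognormal factor (sigma = dispersion, capped at
    0.5 absolute rate), producing heterogeneous per-sample error
    profiles; the default 0 keeps samples exchangeable.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    keys = model.keys
    rates = model.rates
    rows = []
    for i in range(n_pon):
        sid = f"PoN{i + 1:02d}"
        sample_rates = rates
        if sample_dispersion > 0:
            factor = rng.lognormal(mean=0.0, sigma=sample_dispersion, size=len(rates))
            sample_rates = np.minimum(rates * factor, 0.5)
        depths = rng.poisson(depth, size=len(keys))
        alts = rng.binomial(depths, sample_rates)
        for key, d, a in zip(keys, depths, alts):
            rows.append({
                "chrom": key.chrom, "pos": key.pos, "ref": key.ref, "alt": key.alt,
                "pon_sample_id": sid, "alt_count": int(a), "depth": int(d),
            })
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class SimulatedSample:
    """One sample's emulated caller output plus per-site read metrics."""

    sample_id: str
    calls: Mapping[str, tuple[tuple[VariantKey, CallerCall], ...]]
    metrics: Mapping[VariantKey, ReadMetrics]
    truth: tuple[TruthEntry, ...]


def simulate_sample(
    model: SiteErrorModel,
    true_variants: Sequence[tuple[VariantKey, float]],
    depth: int,
    caller_thresholds: Mapping[str, tuple[int, float]] = DEFAULT_CALLER_THRESHOLDS,
    seed: int | np.random.Generator = 0,
    sample_id: str = "S01",
) -> SimulatedSample:
    """Simulate one sample's reads and emulate the caller ensemble.

    Every model site draws depth ~ Poisson(depth) and alt reads ~
    Binomial(depth, rate); sites carrying a true variant use its VAF
    instead of the site error rate (a collision is logged).  Alt reads
    split across strands as Binomial(alt, 0.5).  Each emulated caller
    emits a record when the alt read count reaches its read floor; the
    record passes when the observed VAF also reaches the caller's VAF
    floor.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    true_map = dict(true_variants)
    site_keys = list(model.keys)
    rates = model.rates.copy()
    key_index = {k: i for i, k in enumerate(site_keys)}
    for key, vaf in true_map.items():
        if key in key_index:
            log.info("true variant %s collides with an error-model site; truth wins", key)
            rates[key_index[key]] = vaf
        else:
            site_keys.append(key)
            rates = np.append(rates, vaf)
    order = sorted(range(len(site_keys)), key=lambda i: site_keys[i])
    site_keys = [site_keys[i] for i in order]
    rates = rates[np.array(order)]

    depths = rng.poisson(depth, size=len(site_keys))
    alts = rng.binomial(depths, rates)
    fwd = rng.binomial(alts, 0.5)
    rev = alts - fwd

    calls: dict[str, list[tuple[VariantKey, CallerCall]]] = {c: [] for c in caller_thresholds}
    metrics: dict[VariantKey, ReadMetrics] = {}
    min_floor = min(f for f, _ in caller_thresholds.values())
    for i, key in enumerate(site_keys):
        d, a = int(depths[i]), int(alts[i])
        if d == 0 or a < min_floor:
            continue
        vaf = a / d
        for caller, (read_floor, vaf_floor) in caller_thresholds.items():
            if a < read_floor:
                continue
            calls[caller].append(
                (
                    key,
                    CallerCall(
                        caller_id=caller,
                        passed=vaf >= vaf_floor,
                        total_depth=d,
                        alt_depth=a,
                        vaf=vaf,
                        fwd_alt=int(fwd[i]),
                        rev_alt=int(rev[i]),
                        qual=60.0,
                        mapping_quality=60.0,
                        mean_mismatches=0.5,
                    ),
                )
            )
        metrics[key] = ReadMetrics(
            key=key,
            median_readpos_fraction=0.5,
            fwd_alt=int(fwd[i]),
            rev_alt=int(rev[i]),
            mmqs_diff=0.0,
            incomplete_read_fraction=0.05,
        )
    truth = tuple(
        TruthEntry(sample_id=sample_id, key=key, expected_vaf=vaf, source="simulated")
        for key, vaf in sorted(true_map.items())
    )
    return SimulatedSample(
        sample_id=sample_id,
        calls={c: tuple(v) for c, v in calls.items()},
        metrics=metrics,
        truth=truth,
    )


def simulate_dilution_series(
    tumor_truth: Sequence[tuple[VariantKey, float]],
    ratios: Sequence[float],
    model: SiteErrorModel,
    depth: int,
    caller_thresholds: Mapping[str, tuple[int, float]] = DEFAULT_CALLER_THRESHOLDS,
    seed: int = 0,
) -> list[SimulatedSample]:
    """Simulate a tumor:normal dilution series.

    For a dilution ratio r (1 part tumor to r parts normal), the expected
    VAF of each tumor variant becomes source VAF / (1 + r); r = 0 is the
    undiluted tumor.  One sample is simulated per ratio, with truth
    entries carrying the diluted expected VAFs (source: dilution).
    """
    rng = np.random.default_rng(seed)
    samples = []
    for ratio in ratios:
        if ratio < 0:
            raise ValueError("dilution ratio must be >= 0")
        diluted = [(key, vaf / (1.0 + ratio)) for key, vaf in tumor_truth]
        sid = f"dil_1to{int(ratio) if float(ratio).is_integer() else ratio}"
        sample = simulate_sample(
            model, diluted, depth, caller_thresholds, seed=rng, sample_id=sid
        )
        sample = replace(
            sample,
            truth=tuple(
                TruthEntry(e.sample_id, e.key, e.expected_vaf, "dilution")
                for e in sample.truth
            ),
        )
        samples.append(sample)
    return samples


# ---------------------------------------------------------------------------
# cohort simulation

@dataclass(frozen=True)
class SimCohortConfig:
    """Study conditions for a simulated cohort.

    Defaults mirror the conditions the pipeline was designed around: 40
    study samples against a 27-sample PoN at ~20 000x consensus depth,
    true variants on a VAF grid spanning 0.2%-20%, and 2 000 modelled
    error-prone panel positions.
    """

    n_samples: int = 40
    n_pon: int = 27
    depth: int = 20_000
    n_error_sites: int = 2000
    mixture: ErrorMixture = ErrorMixture()
    truth_vaf_grid: tuple[float, ...] = (0.002, 0.005, 0.01, 0.05, 0.2)
    n_truth_per_sample: int = 5
    dilution_ratios: tuple[float, ...] = (10.0, 100.0, 1000.0, 5000.0)
    caller_thresholds: Mapping[str, tuple[int, float]] = field(
        default_factory=lambda: dict(DEFAULT_CALLER_THRESHOLDS)
    )
    pon_sample_dispersion: float = 0.0
    seed: int = 0


@dataclass(frozen=True)
class SimulatedCohort:
    config: SimCohortConfig
    panel: Panel
    model: SiteErrorModel
    pon: pd.DataFrame
    samples: tuple[SimulatedSample, ...]
    annotations: pd.DataFrame
    truth: TruthSet


def _annotation_for_truth(key: VariantKey, panel: Panel) -> dict:
    """Driver-style annotation for an injected true variant.

    Variants landing in a recurrent-truncation CH gene are annotated as
    frameshift (rule R1 territory); others as missense with COSMIC
    haematopoietic counts above the rule R4 floor and SIFT support.
    """
    gene = panel.gene_at(key.chrom, key.pos) or "UNKNOWN"
    start = next((s for g, c, s, L in panel.genes if g == gene), key.pos)
    offset = key.pos - start
    base = {
        "chrom": key.chrom, "pos": key.pos, "ref": key.ref, "alt": key.alt,
        "gene": gene,
        "protein_pos": offset // 3 + 1,
        "cdna_pos": offset + 1,
        "exon": offset // 500 + 1,
        "gnomad_af": None,
    }
    if gene in ("DNMT3A", "TET2", "TP53", "ASXL1", "CHEK2"):
        base.update(consequence="frameshift", cosmic_total=0, cosmic_haem=0,
                    cosmic_myeloid=0, oncokb="absent", clinvar="absent",
                    sift="absent", polyphen="absent")
    else:
        base.update(consequence="missense", cosmic_total=12, cosmic_haem=8,
                    cosmic_myeloid=4, oncokb="absent", clinvar="absent",
                    sift="deleterious", polyphen="probably_damaging")
    return base


def _annotation_for_artifact(key: VariantKey, panel: Panel, rng: np.random.Generator) -> dict:
    gene = panel.gene_at(key.chrom, key.pos) or "UNKNOWN"
    start = next((s for g, c, s, L in panel.genes if g == gene), key.pos)
    offset = key.pos - start
    return {
        "chrom": key.chrom, "pos": key.pos, "ref": key.ref, "alt": key.alt,
        "gene": gene,
        "consequence": str(rng.choice(["synonymous", "other", "missense"])),
        "protein_pos": offset // 3 + 1,
        "cdna_pos": offset + 1,
        "exon": offset // 500 + 1,
        "cosmic_total": 0, "cosmic_haem": 0, "cosmic_myeloid": 0,
        "oncokb": "absent", "clinvar": "absent",
        "sift": "absent", "polyphen": "absent",
        "gnomad_af": None,
    }


def simulate_cohort(config: SimCohortConfig = SimCohortConfig()) -> SimulatedCohort:
    """Simulate a full study: PoN, per-sample caller output, annotations, truth.

    Truth variants are placed at distinct panel positions per sample
    (never shared between samples, as real CH drivers rarely recur within
    a small cohort), each with a VAF cycling through the configured grid.
    The PoN and every study sample share the same per-site error model,
    which is what makes the PoN Fisher test informative.
    """
    panel = Panel()
    root = np.random.default_rng(config.seed)
    model_rng, pon_rng, truth_rng, ann_rng, *sample_rngs = root.spawn(
        4 + config.n_samples
    )
    model = simulate_site_error_model(
        config.n_error_sites, config.mixture, seed=model_rng, panel=panel
    )

    # truth sites: distinct panel positions not used by the error model
    used = {(k.chrom, k.pos) for k in model.keys}
    positions = [p for p in panel.positions() if (p[1], p[2]) not in used]
    n_truth_total = config.n_samples * config.n_truth_per_sample
    if n_truth_total > len(positions):
        raise ValueError("not enough panel positions for the requested truth variants")
    chosen = truth_rng.choice(len(positions), size=n_truth_total, replace=False)
    ref_idx = truth_rng.integers(0, 4, size=n_truth_total)
    alt_shift = truth_rng.integers(1, 4, size=n_truth_total)
    truth_keys = []
    for i, idx in enumerate(chosen):
        _, chrom, pos, _ = positions[idx]
        ref = str(_BASES[ref_idx[i]])
        alt = str(_BASES[(ref_idx[i] + alt_shift[i]) % 4])
        truth_keys.append(VariantKey(chrom, pos, ref, alt))

    # Truth sites sit at ordinary panel positions outside the error-prone
    # subset; their residual post-consensus error is below every caller's
    # read floor (floor rate 1e-6), so the PoN observes essentially zero
    # alt reads there while still covering the site.
    full_model = SiteErrorModel(
        sites=tuple(sorted(
            list(model.sites)
            + [(k, TRUTH_SITE_FLOOR_RATE) for k in truth_keys],
            key=lambda s: s[0],
        ))
    )

    pon = simulate_pon(
        full_model, config.n_pon, config.depth, seed=pon_rng,
        sample_dispersion=config.pon_sample_dispersion,
    )

    samples = []
    grid = config.truth_vaf_grid
    for s in range(config.n_samples):
        sid = f"S{s + 1:02d}"
        sample_truth = [
            (truth_keys[s * config.n_truth_per_sample + j],
             grid[(s * config.n_truth_per_sample + j) % len(grid)])
            for j in range(config.n_truth_per_sample)
        ]
        samples.append(
            simulate_sample(
                full_model, sample_truth, config.depth,
                config.caller_thresholds, seed=sample_rngs[s], sample_id=sid,
            )
        )

    ann_rows = [
        _annotation_for_artifact(key, panel, ann_rng) for key in full_model.keys
        if key not in set(truth_keys)
    ]
    ann_rows += [_annotation_for_truth(key, panel) for key in truth_keys]
    annotations = pd.DataFrame(ann_rows).sort_values(
        ["chrom", "pos", "ref", "alt"], kind="mergesort"
    ).reset_index(drop=True)

    truth = TruthSet(e for sample in samples for e in sample.truth)
    return SimulatedCohort(
        config=config, panel=panel, model=full_model, pon=pon,
        samples=tuple(samples), annotations=annotations, truth=truth,
    )


def simulate_orthogonal_counts(
    cohort: SimulatedCohort,
    depth: int = 2000,
    error_rate: float = 1e-5,
    seed: int = 0,
) -> dict[tuple[str, VariantKey], int]:
    """Emulate re-sequencing on an orthogonal platform.

    True variants reappear at their expected VAF; everything else sees
    only a flat platform error rate, since artifact profiles do not
    transfer between platforms.  Returns alt read counts per
    (sample, key) over all sites of the cohort's error model.
    """
    rng = np.random.default_rng(seed)
    counts: dict[tuple[str, VariantKey], int] = {}
    truth_vaf = {(e.sample_id, e.key): e.expected_vaf for e in cohort.truth}
    for sample in cohort.samples:
        for key in cohort.model.keys:
            rate = truth_vaf.get((sample.sample_id, key), error_rate)
            d = rng.poisson(depth)
            counts[(sample.sample_id, key)] = int(rng.binomial(d, rate))
    return counts


# ---------------------------------------------------------------------------
# fixture emission

_FILTER_FAIL = "low_vaf"


def _vcf_header(panel: Panel, sample_id: str) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for gene, chrom, start, length in panel.genes:
        if chrom not in header.contigs:
            header.contigs.add(chrom, length=300_000_000)
    header.filters.add(_FILTER_FAIL, None, None, "Below caller VAF floor")
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("DP", 1, "Integer", "Read depth")
    header.formats.add("AD", "R", "Integer", "Allelic depths")
    header.formats.add("SB", 4, "Integer",
                       "Strand bias components: ref-fwd, ref-rev, alt-fwd, alt-rev")
    header.info.add("MQ", 1, "Float", "Mean mapping quality")
    header.info.add("NM", 1, "Float", "Mean mismatches per read")
    header.add_sample(sample_id)
    return header


def write_caller_vcf(
    sample: SimulatedSample, caller: str, path: str | Path, panel: Panel = Panel()
) -> None:
    header = _vcf_header(panel, sample.sample_id)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for key, call in sample.calls.get(caller, ()):
            rec = vcf.new_record(
                contig=key.chrom, start=key.pos - 1,
                alleles=(key.ref, key.alt), qual=call.qual,
            )
            rec.filter.add("PASS" if call.passed else _FILTER_FAIL)
            rec.info["MQ"] = call.mapping_quality
            rec.info["NM"] = call.mean_mismatches
            samp = rec.samples[sample.sample_id]
            samp["GT"] = (0, 1)
            samp["DP"] = call.total_depth
            samp["AD"] = (call.total_depth - call.alt_depth, call.alt_depth)
            ref_total = call.total_depth - call.alt_depth
            samp["SB"] = (ref_total // 2, ref_total - ref_total // 2,
                          call.fwd_alt, call.rev_alt)
            vcf.write(rec)


def metrics_frame(cohort: SimulatedCohort) -> pd.DataFrame:
    rows = []
    for sample in cohort.samples:
        for key, m in sorted(sample.metrics.items()):
            rows.append({
                "chrom": key.chrom, "pos": key.pos, "ref": key.ref, "alt": key.alt,
                "sample_id": sample.sample_id,
                "median_readpos_fraction": m.median_readpos_fraction,
                "fwd_alt": m.fwd_alt, "rev_alt": m.rev_alt,
                "mmqs_diff": m.mmqs_diff,
                "incomplete_read_fraction": m.incomplete_read_fraction,
            })
    return pd.DataFrame(rows)


def emit_fixtures(cohort: SimulatedCohort, out_dir: str | Path) -> dict[str, Path]:
    """Write the complete fixture bundle for a simulated cohort.

    Produces per-caller VCFs (``<sample>.<caller>.vcf``), ``pon.tsv``,
    ``metrics.tsv``, ``annotations.tsv``, ``truth.tsv`` and
    ``panel.bed``.  Output bytes are a pure function of the cohort, hence
    of the seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for sample in cohort.samples:
        for caller in cohort.config.caller_thresholds:
            p = out / f"{sample.sample_id}.{caller}.vcf"
            write_caller_vcf(sample, caller, p, cohort.panel)
            paths[f"{sample.sample_id}.{caller}"] = p
    cohort.pon.to_csv(out / "pon.tsv", sep="\t", index=False)
    metrics_frame(cohort).to_csv(out / "metrics.tsv", sep="\t", index=False)
    cohort.annotations.to_csv(out / "annotations.tsv", sep="\t", index=False)
    cohort.truth.to_frame().to_csv(out / "truth.tsv", sep="\t", index=False)
    cohort.panel.write_bed(out / "panel.bed")
    paths.update({
        "pon": out / "pon.tsv", "metrics": out / "metrics.tsv",
        "annotations": out / "annotations.tsv", "truth": out / "truth.tsv",
        "panel": out / "panel.bed",
    })
    return paths
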