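# Methods

## Problem setting

Deep targeted sequencing of blood (10 000–20 000× UMI-consensus depth over
a small gene panel) detects clonal hematopoiesis mutations down to ~0.1%
VAF, but at that depth many panel positions show a reproducible,
position-specific error rate of the same magnitude as the clones of
interest. `chpipe` models the decision problem downstream of variant
calling: given per-caller call sets, a panel-of-normals (PoN) count table,
read-level metrics and functional annotation, decide for every candidate
variant whether it is a credible somatic call (`PASS`), an artifact or
likely germline variant (`FAIL`), or something a human should inspect
(`REVIEW`), and annotate credible calls as putative CH drivers.

## Variant model

A variant is keyed by (chrom, 1-based pos, ref, alt) after parsimony
trimming: shared trailing bases are removed first, then shared leading
bases while both alleles keep ≥ 1 base, advancing the position
accordingly. SNVs are fixed points; trimming is idempotent. Reference-aware
left-alignment is *not* performed (it needs the genome); inputs are
expected pre-normalized or trim-only. Multi-allelic records are split
per alt allele with per-allele AD apportionment; symbolic alleles are
skipped with a warning.

Merging produces one record per (sample, key) with at most one call per
caller. `n_callers_passed` counts caller-native PASS calls among the
counted callers — Pindel is excluded from the count by default (its
singleton behaviour on short indels is unreliable) but its evidence is
retained. Representative VAF/depths come from the highest-priority
passing caller, default order mutect2 > lofreq2 > vardict > pindel
(Mutect2 depths are assembly-realigned, hence first); both the order and
the counted set are configurable. Duplicate records from one caller keep
the higher alt depth rather than aborting the run.

## PoN error model

The PoN is a set of technical-control samples sequenced on the same
assay; its per-site, per-allele alt/depth counts estimate the
position-specific error rate.

* **Hard filter** — fail when per-sample VAF > 2% in ≥ 2 PoN samples
  (zero-depth PoN samples contribute VAF 0).
* **Fisher filter** — one-sided (`greater`) Fisher exact test of the
  sample's alt/ref counts against the pooled PoN counts; a variant passes
  only when p < α / L with α = 0.05 and L the panel size in bp (merged
  BED length; 23 650 bp for the default nine-gene panel, giving
  2.114e-6). One-sided is the default because the scientific question is
  whether the sample's alt fraction *exceeds* background; two-sided is
  configurable. An all-zero table yields p = 1. Sites missing from the
  PoN pass with a "no PoN coverage" reason by default (the PoN covers
  the whole panel, so a missing site means the variant lies outside it);
  a fail-closed mode exists.

The **PoN-size sweep** measures, for each panel size k, the expected
fraction of known true variants the Fisher filter removes, averaged over
k-subsets of the available normals (exhaustive when C(n,k) is at most
`max_combinations`, default 10 000, otherwise seeded uniform sampling;
the size-n case reduces bit-for-bit to the single full-PoN result). The
one-sided p-values are computed vectorized over all subsets × variants.

## Artifact filters

All filters are pure predicates returning a verdict (pass/fail, reason,
values used); the overall decision is their conjunction and is invariant
to evaluation order. Inequalities are implemented exactly as stated:
alt depth < 5 fails and 5 passes; VAF must strictly exceed 0.001; indels
with |len(ref) − len(alt)| > 20 fail only with single-caller support;
recurrence > 6% fails always, > 3% fails only variants never reported in
prior large-scale CH studies (a user-supplied variant list, not a
hardcoded dataset). Strand evidence on exactly one strand fails; zero
reads on both strands also fails (no evidence), while absent strand
counts make the filter "not evaluable" (a pass, with the reason
recorded). The VarScan-style sub-filters (median read-position fraction
≥ 0.10, alt strand fraction within [0.10, 0.90], mismatch-quality-sum
difference ≤ 50, incomplete-read fraction ≤ 0.90) are reconstructed from
that tool family's documented behaviour and are all config-exposed; the
incomplete-read criterion is a configurable maximum fraction of alt
reads not fully spanning the variant. The VarDict-only filter applies
when VarDict is the sole passing caller and fails calls with
VAF × depth < 6 combined with any low-quality clause (MQ < 55 & NM > 1;
MQ < 60 & NM > 2; DP < 10; QUAL < 45); missing quality fields neutralize
their clause.

Cohort occurrence is computed **before** filtering (a sample counts once
per key when ≥ 1 caller passed it) so systematic artifacts stay visible
even where individual copies fail other filters. Note the thresholds
presume study-scale cohorts: below ~35 samples a singleton variant
already exceeds 3%, and below 17 samples it exceeds 6%, so in small
cohorts the recurrence filter should be reconfigured or disabled.

## Driver rules

Ten rules over annotation evidence and a curated knowledge base, pure
disjunction, all matches recorded with provenance (evaluation order
R1→R10 is fixed only for reproducible reporting). "Truncating" means
{stop_gained, frameshift, splice_acceptor, splice_donor} (start/stop-lost
excluded by default, configurable); "computationally damaging" means
SIFT deleterious or PolyPhen probably/possibly damaging. Hotspot entries
must satisfy the qualification predicate (≥ 5 prior CH reports, or
COSMIC ≥ 25 overall / ≥ 20 haematopoietic-lymphoid / ≥ 10 myeloid, plus
damage evidence) and are validated at load. Proximity matching uses
≤ 3 amino-acid residues or ≤ 9 nucleotides (cDNA coordinates, since
hotspots are transcript-defined); indel distances use the first affected
residue. R7 accepts any prior CH variant at the residue regardless of
its consequence class. The shipped defaults are illustrative; real
COSMIC/OncoKB/ClinVar/prior-CH exports are user-supplied for licensing
reasons.

## Triage

FAIL dominates REVIEW dominates PASS; every variant lands in exactly one
bucket. FAIL requires a failing filter or the germline flag (gnomAD
AF > 0.005 — deliberately no VAF-based ~50%/100% inference, because
large CH clones legitimately reach high VAFs). REVIEW flags: a complex
indel (length-changing, both alleles > 1 base) supported by exactly one
caller, or a variant in ≥ 2 samples absent from the prior-CH lists.
Driver calls are reported for all three buckets; review never blocks
annotation.

## Benchmarking

Sensitivity and PPV are tabulated per VAF bin (default edges 0, 0.001,
0.004, 0.01, 0.05, 1; lower-inclusive, top bin closed) with exact
Clopper–Pearson 95% intervals. True and missed variants bin by the
truth's expected VAF; false positives, which have no truth VAF, bin by
observed VAF. 0/0 ratios are reported as absent, never coerced to 0.
Orthogonal truth sets require, on the primary platform, VAF > 0.001,
alt depth > 5, ≥ 1 passing caller and a reduced filter set (by default
the incomplete-read/VarScan bundle and the PoN Fisher test — the subset
is configurable), then > 5 alt reads on the orthogonal platform;
uncovered sites are excluded and counted separately. Replicate
discordance (passed in exactly one replicate) is classified by the
counterpart's state with precedence min_vaf → pon_filter →
other_allele_at_site → other; classification is exhaustive over the
union of pass sets. Replicate VAF correlation is Pearson, stratified at
0.2% mean VAF.

## Simulator

The simulator generates everything the pipeline reads. A synthetic
nine-gene panel (fixed arbitrary coordinates, 23 650 bp total) hosts:

* `n_error_sites` **error-prone positions** (default 2 000) whose
  per-site error rates follow a two-component mixture: log-uniform
  background over [1e-5, 2e-4] alt fraction, and an artifact-prone
  component (default 2% of sites) log-uniform over [2e-4, 5e-2] — the
  VAF range over which real panels show intrinsic error. The 2 000-site
  default reproduces a realistic call density (several hundred caller
  records per sample on a 23 650 bp panel).
* **True variants** at distinct panel positions outside that subset, one
  set per sample (VAF grid default {0.002, 0.005, 0.01, 0.05, 0.2}).
  Truth sites carry a floor error rate of 1e-6 — far below every caller
  floor — reflecting that the error-prone subset is a minority of the
  panel and that drivers land at ordinary positions. This matters: if
  driver sites shared the mid-range background, background calls at the
  same key across samples would (correctly) trip the cohort-recurrence
  filter, a behaviour real panels do not show.

Reads are site-level binomial draws (depth ~ Poisson(20 000) per site,
alt ~ Binomial(depth, rate or VAF), strand split Binomial(alt, 0.5));
error is modelled post-consensus because UMI consensus building is
upstream of this package. Caller emulation is threshold-based, not a
re-implementation: VarDict-like passes at ≥ 3 alt reads with no VAF
floor (hence it dominates low-VAF singleton calls), LoFreq-like at ≥ 5
reads and VAF ≥ 5e-4, Mutect-like at ≥ 8 reads and VAF ≥ 2e-3; a caller
emits a present-but-filtered record when the read floor is met but the
VAF floor is not. Dilution arithmetic: expected VAF = source VAF /
(1 + ratio) for tumor:normal ratio 1:r, default ratios {10, 100, 1000,
5000}. PoN samples are exchangeable by default; a lognormal per-sample
rate multiplier (`pon_sample_dispersion`) is available for heterogeneous
panels. Everything is deterministic under a fixed seed, including
emitted file bytes (verified by digest).

**What the simulator does not emulate** — and hence what passing tests
do not demonstrate about real data: alignment and mapping artifacts,
error motifs (OxoG-style strand-asymmetric damage, homopolymer indels),
UMI family-size effects, germline variation, read-position pathology
(emitted read metrics are neutral), and inter-site error correlation.
The end-to-end numbers on simulated cohorts are consistency checks of
the filtering logic under its own model, not estimates of real-world
performance.

## Evaluation experiments

`evaluate.py` wires simulator → pipeline → metrics:

* **Default-cohort recovery** (40 samples, 27 PoN, 20 000×): sensitivity
  for truth VAF ≥ 1% and per-bin PPV before (≥ 1 caller) vs after (PASS
  bucket) filtering. A bin whose pre-filter PPV is already 1.0 cannot
  strictly improve (this genuinely occurs in the > 5% VAF stratum, where
  consensus calling alone is already precise); the improvement check
  therefore requires strict gains in every well-populated bin with
  pre-filter PPV < 1 and non-degradation everywhere. A bin emptied by
  filtering counts as improved only if it contained no truth.
* **PoN-size sweep** (sizes 1…27, 300 subsets/size): dilution-series
  truth (6 tumors × 6 variants, source VAF 0.2–0.5, ratios 1:10–1:5000)
  at sites with background-mixture error. Removal is driven by the
  1:1000 stratum (VAF ~2–5e-4, inside the error band); the curve
  plateaus once the pooled PoN depth dwarfs the sample depth, around 8
  samples.
* **Replicate pair**: shared truth (half near the 0.1% floor, half
  0.2–20%) sampled twice independently; discordance classification plus
  the VAF correlation split at 0.2%, where binomial counting noise
  dominates below and clone size dominates above.

Problem sizes (2 000 error sites, 300 subsets per sweep size, single
replicate pair) were chosen as the smallest that leave the measured
proportions stable to a few percent between seeds.

## Numerical notes

Fisher one-sided p-values are hypergeometric survival functions
(vectorized via `scipy.stats.hypergeom`); the test suite checks them
exhaustively against an explicit tail-sum oracle for all 2×2 tables with
N ≤ 60 (|Δ| ≤ 1e-9) and against exact rational arithmetic on small
tables. Clopper–Pearson intervals come from `statsmodels`
(`proportion_confint(method="beta")`) and are checked against brute-force
tail-probability inversion; endpoints are exact at x = 0 and x = n.
Merged-variant TSVs are written with `%.17g` floats and read with
round-trip parsing so records survive a write/read cycle bit-for-bit.
Binning is lower-inclusive with a closed top bin, so VAF exactly 0.05
falls in the > 5% stratum.

## Known limitations

* No reference-aware left-alignment; identical indels represented at
  different positions in different caller VCFs will not merge.
* Recurrence thresholds are miscalibrated for cohorts under ~35 samples
  (see above).
* The VarScan-style sub-filter thresholds follow that tool family's
  common defaults; the exact historical threshold set varies by version,
  so every value is configuration, and runs record the set used.
* The simulator's caller emulation reproduces qualitative caller
  discordance (VarDict-dominated low-VAF singletons, conservative
  Mutect-like behaviour), not any caller's actual decision boundary.
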