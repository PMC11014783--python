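"""Rule-based classification of CH putative-driver variants.

A variant is a putative clonal-hematopoiesis driver when it matches any
of ten curated rules evaluated over its functional annotation (gene,
consequence, protein/cDNA position) and a knowledge base of curated
lists: CH genes with recurrent truncating mutations, hotspot catalogues
distilled from COSMIC and two large prior CH sequencing studies, OncoKB
oncogenicity calls and ClinVar assertions.  The engine is a pure
disjunction — every rule is evaluated, all matches are recorded with the
values that produced them, and removing a rule can only shrink the
driver set.

Rules (identifiers are stable and appear in output provenance):

R1   truncating mutation in a recurrent-truncation CH gene
     (DNMT3A, TET2, TP53, ASXL1, CHEK2 by default)
R2   truncating mutation in exon 6 of PPM1D
R3   in-frame indel in CHEK2
R4   missense seen somatically in COSMIC >= 10 times overall or >= 5
     times in the haematopoietic-and-lymphoid category
R5   variant previously reported as CH in healthy/solid-tumor cohorts
R6   OncoKB oncogenic or likely oncogenic
R7   missense at the same residue as a previously reported CH variant,
     with SIFT/PolyPhen damaging evidence
R8   missense within 3 residues or 9 nucleotides of a CH hotspot
R9   missense in an established hotspot region (SRSF2 residue 95;
     SF3B1 622-626, 662-666, 700-704, 740-742)
R10  ClinVar pathogenic or likely pathogenic
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import pandas as pd

from .variants import VariantKey

CONSEQUENCES = (
    "stop_gained", "frameshift", "splice_acceptor", "splice_donor",
    "missense", "inframe_indel", "synonymous", "other",
)

#: Consequences treated as protein-truncating.  Start-lost/stop-lost are
#: excluded by default (standard CH-annotation practice); override via
#: ``KnowledgeBase.truncating_consequences``.
TRUNCATING_CONSEQUENCES = frozenset(
    {"stop_gained", "frameshift", "splice_acceptor", "splice_donor"}
)


@dataclass(frozen=True)
class AnnotationEvidence:
    """Functional annotation for one variant (canonical transcript)."""

    key: VariantKey
    gene: str
    consequence: str
    protein_pos: int | None = None
    cdna_pos: int | None = None
    exon: int | None = None
    cosmic_total: int = 0
    cosmic_haem: int = 0
    cosmic_myeloid: int = 0
    oncokb: str = "absent"          # oncogenic | likely_oncogenic | other | absent
    clinvar: str = "absent"         # pathogenic | likely_pathogenic | other | absent
    ch_source_counts: tuple[int, int] = (0, 0)
    sift: str = "absent"            # deleterious | tolerated | absent
    polyphen: str = "absent"        # probably_damaging | possibly_damaging | benign | absent
    gnomad_af: float | None = None

    def __post_init__(self) -> None:
        if self.consequence not in CONSEQUENCES:
            raise ValueError(f"unknown consequence {self.consequence!r}")
        for name in ("cosmic_total", "cosmic_haem", "cosmic_myeloid"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.protein_pos is not None and self.protein_pos < 1:
            raise ValueError("protein_pos must be >= 1")

    @property
    def computationally_damaging(self) -> bool:
        """SIFT deleterious, or PolyPhen probably/possibly damaging."""
        return self.sift == "deleterious" or self.polyphen in (
            "probably_damaging", "possibly_damaging"
        )


@dataclass(frozen=True)
class Hotspot:
    """A curated CH hotspot with the counts that qualified it."""

    gene: str
    protein_pos: int | None
    cdna_pos: int | None
    ch_report_count: int = 0
    cosmic_total: int = 0
    cosmic_haem: int = 0
    cosmic_myeloid: int = 0
    damaging: bool = True


def is_hotspot(entry: Hotspot) -> bool:
    """Hotspot qualification predicate.

    Requires computational damage evidence plus any of: reported >= 5
    times in a prior CH study, COSMIC >= 25 overall, >= 20 in the
    haematopoietic-and-lymphoid category, or >= 10 in the myeloid
    category.
    """
    counts_ok = (
        entry.ch_report_count >= 5
        or entry.cosmic_total >= 25
        or entry.cosmic_haem >= 20
        or entry.cosmic_myeloid >= 10
    )
    return counts_ok and entry.damaging


@dataclass(frozen=True)
class KnowledgeBase:
    """Curated lists driving the rule cascade.

    The defaults reflect the nine-gene CH panel the rules were designed
    around; all fields are user-configurable, and the real COSMIC /
    OncoKB / ClinVar / prior-CH exports are user-supplied (licensing).
    Hotspot entries are validated against :func:`is_hotspot` at load.
    """

    truncating_genes: frozenset[str] = frozenset({"DNMT3A", "TET2", "TP53", "ASXL1", "CHEK2"})
    ppm1d_truncating_exon: int = 6
    inframe_genes: frozenset[str] = frozenset({"CHEK2"})
    prior_ch_variants: frozenset[VariantKey] = frozenset()
    prior_ch_residues: frozenset[tuple[str, int]] = frozenset()
    hotspots: tuple[Hotspot, ...] = ()
    region_rules: Mapping[str, tuple[tuple[int, int], ...]] = field(
        default_factory=lambda: {
            "SRSF2": ((95, 95),),
            "SF3B1": ((622, 626), (662, 666), (700, 704), (740, 742)),
        }
    )
    truncating_consequences: frozenset[str] = TRUNCATING_CONSEQUENCES
    hotspot_aa_distance: int = 3
    hotspot_nt_distance: int = 9

    def __post_init__(self) -> None:
        for gene, ranges in self.region_rules.items():
            for lo, hi in ranges:
                if lo > hi:
                    raise ValueError(f"region rule {gene} {lo}-{hi} has lower > upper")
        bad = [h for h in self.hotspots if not is_hotspot(h)]
        if bad:
            raise ValueError(
                f"{len(bad)} hotspot entries fail the hotspot definition, e.g. {bad[0]}"
            )


@dataclass(frozen=True)
class DriverCall:
    key: VariantKey
    is_putative_driver: bool
    matched_rules: tuple[str, ...]
    provenance: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        if self.is_putative_driver != bool(self.matched_rules):
            raise ValueError("is_putative_driver must equal (matched_rules non-empty)")


def is_truncating(consequence: str, kb: KnowledgeBase = KnowledgeBase()) -> bool:
    return consequence in kb.truncating_consequences


def rule_R1_truncating_genes(ev: AnnotationEvidence, kb: KnowledgeBase) -> bool:
    return is_truncating(ev.consequence, kb) and ev.gene in kb.truncating_genes


def rule_R2_ppm1d(ev: AnnotationEvidence, kb: KnowledgeBase) -> bool:
    return (
        is_truncating(ev.consequence, kb)
        and ev.gene == "PPM1D"
        and ev.exon is not None
        and ev.exon == kb.ppm1d_truncating_exon
    )


def rule_R3_chek2_inframe(ev: AnnotationEvidence, kb: KnowledgeBase) -> bool:
    return ev.consequence == "inframe_indel" and ev.gene in kb.inframe_genes


def rule_R4_cosmic_missense(ev: AnnotationEvidence, kb: KnowledgeBase) -> bool:
    return ev.consequence == "missense" and (ev.cosmic_total >= 10 or ev.cosmic_haem >= 5)


def rule_R5_prior_ch(ev: AnnotationEvidence, kb: KnowledgeBase) -> bool:
    return ev.key in kb.prior_ch_variants


def rule_R6_oncokb(ev: AnnotationEvidence, kb: KnowledgeBase) -> bool:
    return ev.oncokb in ("oncogenic", "likely_oncogenic")


def rule_R7_same_residue(ev: AnnotationEvidence, kb: KnowledgeBase) -> bool:
    return (
        ev.consequence == "missense"
        and ev.protein_pos is not None
        and (ev.gene, ev.protein_pos) in kb.prior_ch_residues
        and ev.computationally_damaging
    )


def rule_R8_hotspot_proximity(ev: AnnotationEvidence, kb: KnowledgeBase) -> bool:
    if ev.consequence != "missense":
        return False
    if ev.protein_pos is None and ev.cdna_pos is None:
        return False
    for h in kb.hotspots:
        if h.gene != ev.gene:
            continue
        if (
            ev.protein_pos is not None
            and h.protein_pos is not None
            and abs(ev.protein_pos - h.protein_pos) <= kb.hotspot_aa_distance
        ):
            return True
        if (
            ev.cdna_pos is not None
            and h.cdna_pos is not None
            and abs(ev.cdna_pos - h.cdna_pos) <= kb.hotspot_nt_distance
        ):
            return True
    return False


def rule_R9_regions(ev: AnnotationEvidence, kb: KnowledgeBase) -> bool:
    if ev.consequence != "missense" or ev.protein_pos is None:
        return False
    return any(
        lo <= ev.protein_pos <= hi
        for lo, hi in kb.region_rules.get(ev.gene, ())
    )


def rule_R10_clinvar(ev: AnnotationEvidence, kb: KnowledgeBase) -> bool:
    return ev.clinvar in ("pathogenic", "likely_pathogenic")


#: Fixed R1..R10 evaluation order for reproducible provenance.  The
#: semantics are a pure disjunction, so order never changes the outcome.
RULES: tuple[tuple[str, Callable[[AnnotationEvidence, KnowledgeBase], bool]], ...] = (
    ("R1", rule_R1_truncating_genes),
    ("R2", rule_R2_ppm1d),
    ("R3", rule_R3_chek2_inframe),
    ("R4", rule_R4_cosmic_missense),
    ("R5", rule_R5_prior_ch),
    ("R6", rule_R6_oncokb),
    ("R7", rule_R7_same_residue),
    ("R8", rule_R8_hotspot_proximity),
    ("R9", rule_R9_regions),
    ("R10", rule_R10_clinvar),
)

_RULE_PROVENANCE_FIELDS = {
    "R1": ("gene", "consequence"),
    "R2": ("gene", "consequence", "exon"),
    "R3": ("gene", "consequence"),
    "R4": ("consequence", "cosmic_total", "cosmic_haem"),
    "R5": ("key",),
    "R6": ("oncokb",),
    "R7": ("gene", "protein_pos", "sift", "polyphen"),
    "R8": ("gene", "protein_pos", "cdna_pos"),
    "R9": ("gene", "protein_pos"),
    "R10": ("clinvar",),
}


def classify_driver(ev: AnnotationEvidence, kb: KnowledgeBase = KnowledgeBase()) -> DriverCall:
    """Evaluate every rule and return the full set of matches.

    No short-circuiting: a DNMT3A frameshift that is also in the prior-CH
    list reports both R1 and R5.  Provenance records, per matched rule,
    the evidence fields the predicate read.
    """
    matched: list[str] = []
    provenance: list[tuple[str, str]] = []
    for rule_id, predicate in RULES:
        if predicate(ev, kb):
            matched.append(rule_id)
            used = ";".join(
                f"{f}={getattr(ev, f)}" for f in _RULE_PROVENANCE_FIELDS[rule_id]
            )
            provenance.append((rule_id, used))
    return DriverCall(
        key=ev.key,
        is_putative_driver=bool(matched),
        matched_rules=tuple(matched),
        provenance=tuple(provenance),
    )


# ---------------------------------------------------------------------------
# table I/O

_INT_FIELDS = ("protein_pos", "cdna_pos", "exon",
               "cosmic_total", "cosmic_haem", "cosmic_myeloid")


def annotation_from_row(row) -> AnnotationEvidence:
    """Build evidence from one row of the annotation table.

    Unknown consequence labels are coerced to ``other``; empty cells mean
    absent.
    """
    def _opt_int(value, default=None):
        if value is None or (isinstance(value, float) and pd.isna(value)):
            return default
        return int(value)

    consequence = getattr(row, "consequence", "other")
    if not isinstance(consequence, str) or consequence not in CONSEQUENCES:
        consequence = "other"
    gnomad = getattr(row, "gnomad_af", None)
    if gnomad is not None and pd.isna(gnomad):
        gnomad = None

    def _enum(name: str, allowed: tuple[str, ...]) -> str:
        value = getattr(row, name, "absent")
        return value if isinstance(value, str) and value in allowed else "absent"

    return AnnotationEvidence(
        key=VariantKey(str(row.chrom), int(row.pos), row.ref, row.alt),
        gene=str(row.gene),
        consequence=consequence,
        protein_pos=_opt_int(getattr(row, "protein_pos", None)),
        cdna_pos=_opt_int(getattr(row, "cdna_pos", None)),
        exon=_opt_int(getattr(row, "exon", None)),
        cosmic_total=_opt_int(getattr(row, "cosmic_total", None), 0),
        cosmic_haem=_opt_int(getattr(row, "cosmic_haem", None), 0),
        cosmic_myeloid=_opt_int(getattr(row, "cosmic_myeloid", None), 0),
        oncokb=_enum("oncokb", ("oncogenic", "likely_oncogenic", "other")),
        clinvar=_enum("clinvar", ("pathogenic", "likely_pathogenic", "other")),
        ch_source_counts=(
            _opt_int(getattr(row, "ch_count_healthy", None), 0),
            _opt_int(getattr(row, "ch_count_tumor", None), 0),
        ),
        sift=_enum("sift", ("deleterious", "tolerated")),
        polyphen=_enum("polyphen", ("probably_damaging", "possibly_damaging", "benign")),
        gnomad_af=float(gnomad) if gnomad is not None else None,
    )


def read_annotation_tsv(path) -> dict[VariantKey, AnnotationEvidence]:
    """Load the per-variant annotation table (one row per variant key)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "gene": str})
    out: dict[VariantKey, AnnotationEvidence] = {}
    for row in df.itertuples(index=False):
        ev = annotation_from_row(row)
        out[ev.key] = ev
    return out


def load_knowledge_base(
    hotspots_path=None, prior_ch_path=None, **overrides
) -> KnowledgeBase:
    """Assemble a knowledge base from TSV exports plus keyword overrides.

    The hotspots TSV carries (gene, protein_pos, cdna_pos,
    ch_report_count, cosmic_total, cosmic_haem, cosmic_myeloid,
    damaging); entries failing the hotspot definition are rejected.  The
    prior-CH TSV carries (chrom, pos, ref, alt, gene, protein_pos) and
    feeds both the exact-variant list (R5) and the residue list (R7).
    """
    kwargs: dict = dict(overrides)
    if hotspots_path is not None:
        df = pd.read_csv(hotspots_path, sep="\t", dtype={"gene": str})
        kwargs["hotspots"] = tuple(
            Hotspot(
                gene=str(r.gene),
                protein_pos=int(r.protein_pos) if pd.notna(r.protein_pos) else None,
                cdna_pos=int(r.cdna_pos) if pd.notna(r.cdna_pos) else None,
                ch_report_count=int(getattr(r, "ch_report_count", 0) or 0),
                cosmic_total=int(getattr(r, "cosmic_total", 0) or 0),
                cosmic_haem=int(getattr(r, "cosmic_haem", 0) or 0),
                cosmic_myeloid=int(getattr(r, "cosmic_myeloid", 0) or 0),
                damaging=bool(getattr(r, "damaging", True)),
            )
            for r in df.itertuples(index=False)
        )
    if prior_ch_path is not None:
        df = pd.read_csv(prior_ch_path, sep="\t", dtype={"chrom": str, "gene": str})
        variants = set()
        residues = set()
        for r in df.itertuples(index=False):
            variants.add(VariantKey(str(r.chrom), int(r.pos), r.ref, r.alt))
            ppos = getattr(r, "protein_pos", None)
            if ppos is not None and pd.notna(ppos):
                residues.add((str(r.gene), int(ppos)))
        kwargs["prior_ch_variants"] = frozenset(variants)
        kwargs["prior_ch_residues"] = frozenset(residues)
    return KnowledgeBase(**kwargs)
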