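"""Putative-driver rule cascade over annotation evidence."""

import dataclasses

import pytest

from chpipe.drivers import (
    AnnotationEvidence,
    Hotspot,
    KnowledgeBase,
    classify_driver,
    is_hotspot,
    is_truncating,
    rule_R8_hotspot_proximity,
)
from chpipe.variants import VariantKey

KEY = VariantKey("chr2", 25_234_400, "C", "T")


def ev(**kw):
    base = dict(key=KEY, gene="DNMT3A", consequence="missense")
    base.update(kw)
    return AnnotationEvidence(**base)


class TestTruncating:
    @pytest.mark.parametrize(
        "consequence,expected",
        [
            ("stop_gained", True), ("frameshift", True),
            ("splice_acceptor", True), ("splice_donor", True),
            ("missense", False), ("inframe_indel", False), ("synonymous", False),
        ],
    )
    def test_consequence_set(self, consequence, expected):
        assert is_truncating(consequence) is expected


class TestIndividualRules:
    def test_R1_truncating_ch_gene(self, demo_kb):
        assert "R1" in classify_driver(ev(consequence="frameshift"), demo_kb).matched_rules
        assert "R1" not in classify_driver(ev(consequence="missense"), demo_kb).matched_rules
        jak2 = ev(gene="JAK2", consequence="stop_gained")
        assert "R1" not in classify_driver(jak2, demo_kb).matched_rules

    @pytest.mark.parametrize("exon,match", [(6, True), (5, False), (None, False)])
    def test_R2_ppm1d_exon6(self, demo_kb, exon, match):
        e = ev(gene="PPM1D", consequence="stop_gained", exon=exon)
        assert ("R2" in classify_driver(e, demo_kb).matched_rules) is match

    def test_R2_requires_truncating(self, demo_kb):
        e = ev(gene="PPM1D", consequence="missense", exon=6)
        assert "R2" not in classify_driver(e, demo_kb).matched_rules

    def test_R3_chek2_inframe(self, demo_kb):
        assert "R3" in classify_driver(
            ev(gene="CHEK2", consequence="inframe_indel"), demo_kb).matched_rules
        assert "R3" not in classify_driver(
            ev(gene="TET2", consequence="inframe_indel"), demo_kb).matched_rules
        # a CHEK2 frameshift matches R1, not R3
        call = classify_driver(ev(gene="CHEK2", consequence="frameshift"), demo_kb)
        assert "R3" not in call.matched_rules and "R1" in call.matched_rules

    @pytest.mark.parametrize(
        "total,haem,match",
        [(10, 0, True), (0, 5, True), (9, 4, False), (25, 0, True)],
    )
    def test_R4_cosmic_thresholds(self, demo_kb, total, haem, match):
        e = ev(cosmic_total=total, cosmic_haem=haem)
        assert ("R4" in classify_driver(e, demo_kb).matched_rules) is match

    def test_R4_missense_only(self, demo_kb):
        e = ev(consequence="synonymous", cosmic_total=100)
        assert "R4" not in classify_driver(e, demo_kb).matched_rules

    def test_R5_prior_ch_presence(self, demo_kb):
        prior_key = next(iter(demo_kb.prior_ch_variants))
        e = ev(key=prior_key, consequence="synonymous")
        assert "R5" in classify_driver(e, demo_kb).matched_rules
        assert "R5" not in classify_driver(ev(), demo_kb).matched_rules

    @pytest.mark.parametrize(
        "oncokb,match",
        [("oncogenic", True), ("likely_oncogenic", True), ("other", False), ("absent", False)],
    )
    def test_R6_oncokb(self, demo_kb, oncokb, match):
        assert ("R6" in classify_driver(ev(oncokb=oncokb), demo_kb).matched_rules) is match

    def test_R7_same_residue_needs_damage(self, demo_kb):
        at_residue = dict(gene="JAK2", protein_pos=617)
        damaging = ev(sift="deleterious", **at_residue)
        assert "R7" in classify_driver(damaging, demo_kb).matched_rules
        benign = ev(sift="tolerated", polyphen="benign", **at_residue)
        assert "R7" not in classify_driver(benign, demo_kb).matched_rules
        elsewhere = ev(gene="JAK2", protein_pos=400, sift="deleterious")
        assert "R7" not in classify_driver(elsewhere, demo_kb).matched_rules

    def test_R7_polyphen_possibly_damaging_counts(self, demo_kb):
        e = ev(gene="JAK2", protein_pos=617, polyphen="possibly_damaging")
        assert "R7" in classify_driver(e, demo_kb).matched_rules

    @pytest.mark.parametrize(
        "ppos,cpos,match",
        [
            (885, None, True),    # 3 residues from DNMT3A 882
            (886, None, False),   # 4 residues away
            (None, 2654, True),   # 9 nt from cDNA 2645
            (None, 2655, False),  # 10 nt away
            (None, None, False),  # nothing evaluable
        ],
    )
    def test_R8_proximity_windows(self, demo_kb, ppos, cpos, match):
        e = ev(protein_pos=ppos, cdna_pos=cpos)
        assert rule_R8_hotspot_proximity(e, demo_kb) is match

    def test_R8_gene_scoped(self, demo_kb):
        e = ev(gene="TET2", protein_pos=882)
        assert not rule_R8_hotspot_proximity(e, demo_kb)

    @pytest.mark.parametrize(
        "gene,pos,match",
        [
            ("SRSF2", 95, True), ("SRSF2", 96, False),
            ("SF3B1", 622, True), ("SF3B1", 626, True), ("SF3B1", 627, False),
            ("SF3B1", 700, True), ("SF3B1", 705, False),
            ("SF3B1", 740, True), ("SF3B1", 742, True), ("SF3B1", 743, False),
            ("SF3B1", 662, True), ("SF3B1", 666, True),
        ],
    )
    def test_R9_region_rules(self, demo_kb, gene, pos, match):
        e = ev(gene=gene, protein_pos=pos)
        assert ("R9" in classify_driver(e, demo_kb).matched_rules) is match

    @pytest.mark.parametrize(
        "clinvar,match",
        [("pathogenic", True), ("likely_pathogenic", True), ("other", False), ("absent", False)],
    )
    def test_R10_clinvar(self, demo_kb, clinvar, match):
        assert ("R10" in classify_driver(ev(clinvar=clinvar), demo_kb).matched_rules) is match


class TestHotspotDefinition:
    @pytest.mark.parametrize(
        "kw,expected",
        [
            (dict(ch_report_count=5, damaging=True), True),
            (dict(ch_report_count=4, damaging=True), False),
            (dict(cosmic_total=25, damaging=True), True),
            (dict(cosmic_haem=20, damaging=True), True),
            (dict(cosmic_myeloid=10, damaging=True), True),
            (dict(cosmic_myeloid=9, damaging=True), False),
            (dict(cosmic_total=25, damaging=False), False),
        ],
    )
    def test_qualification(self, kw, expected):
        assert is_hotspot(Hotspot("DNMT3A", 882, 2645, **kw)) is expected

    def test_kb_rejects_invalid_hotspots(self):
        with pytest.raises(ValueError):
            KnowledgeBase(hotspots=(Hotspot("X", 1, 1, ch_report_count=1, damaging=True),))


class TestClassify:
    def test_union_semantics(self, demo_kb):
        prior_key = next(iter(demo_kb.prior_ch_variants))
        e = ev(key=prior_key, consequence="frameshift")
        call = classify_driver(e, demo_kb)
        assert call.matched_rules == ("R1", "R5")
        assert call.is_putative_driver

    def test_no_evidence_not_driver(self, demo_kb):
        call = classify_driver(ev(consequence="synonymous"), demo_kb)
        assert not call.is_putative_driver and call.matched_rules == ()

    def test_srsf2_p95(self, demo_kb):
        e = ev(gene="SRSF2", protein_pos=95)
        call = classify_driver(e, demo_kb)
        assert call.is_putative_driver and "R9" in call.matched_rules

    def test_deterministic(self, demo_kb):
        e = ev(consequence="frameshift", oncokb="oncogenic")
        assert classify_driver(e, demo_kb) == classify_driver(e, demo_kb)

    def test_removing_a_rule_never_adds_a_driver(self, demo_kb):
        """Disjunction semantics: a reduced knowledge base shrinks the set."""
        reduced = dataclasses.replace(demo_kb, truncating_genes=frozenset())
        cases = [
            ev(consequence="frameshift"),
            ev(consequence="frameshift", oncokb="oncogenic"),
            ev(consequence="synonymous"),
        ]
        for e in cases:
            full = classify_driver(e, demo_kb)
            red = classify_driver(e, reduced)
            assert set(red.matched_rules) <= set(full.matched_rules)

    def test_added_evidence_never_removes_match(self, demo_kb):
        weak = ev(cosmic_total=10)
        strong = ev(cosmic_total=50, cosmic_haem=30, oncokb="oncogenic",
                    clinvar="pathogenic", sift="deleterious")
        assert set(classify_driver(weak, demo_kb).matched_rules) <= set(
            classify_driver(strong, demo_kb).matched_rules
        )

    def test_provenance_reproduces_decision(self, demo_kb):
        e = ev(consequence="frameshift")
        call = classify_driver(e, demo_kb)
        prov = dict(call.provenance)
        assert "R1" in prov and "consequence=frameshift" in prov["R1"]
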