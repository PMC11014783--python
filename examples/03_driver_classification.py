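"""Classify variants against the CH putative-driver rule cascade.

Each variant is checked against all ten rules (truncating CH genes,
PPM1D exon 6, CHEK2 in-frame indels, COSMIC counts, prior CH reports,
OncoKB, residue/hotspot proximity, SRSF2/SF3B1 regions, ClinVar); any
match makes it a putative driver, and all matches are reported.
"""

from chpipe.drivers import AnnotationEvidence, Hotspot, KnowledgeBase, classify_driver
from chpipe.variants import VariantKey

kb = KnowledgeBase(
    hotspots=(
        Hotspot("DNMT3A", protein_pos=882, cdna_pos=2645,
                ch_report_count=50, cosmic_haem=90, damaging=True),
    ),
)

variants = [
    AnnotationEvidence(VariantKey("chr2", 25_234_410, "CA", "C"),
                       gene="DNMT3A", consequence="frameshift"),
    AnnotationEvidence(VariantKey("chr2", 25_234_500, "C", "T"),
                       gene="DNMT3A", consequence="missense", protein_pos=884,
                       sift="deleterious"),
    AnnotationEvidence(VariantKey("chr17", 76_735_100, "G", "T"),
                       gene="SRSF2", consequence="missense", protein_pos=95),
    AnnotationEvidence(VariantKey("chr9", 5_021_988, "G", "T"),
                       gene="JAK2", consequence="missense", protein_pos=617,
                       cosmic_haem=4, cosmic_total=9),
]
for ev in variants:
    call = classify_driver(ev, kb)
    rules = ",".join(call.matched_rules) or "-"
    print(f"{ev.gene:7s} {ev.consequence:11s} p.{ev.protein_pos}: "
          f"driver={call.is_putative_driver}  rules=[{rules}]")
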