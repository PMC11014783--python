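"""The panel-of-normals Fisher exact error filter on hand-built counts.

A variant survives only when its alt-read fraction is significantly
above the pooled PoN background at the Bonferroni-corrected threshold
alpha / panel_bp (0.05 / 23 650 ~= 2.1e-6).
"""

from chpipe.pon import PoNConfig, bonferroni_threshold, fisher_exact

threshold = bonferroni_threshold(0.05, 23650)
print(f"panel-wide significance threshold: {threshold:.4g}")

cases = [
    ("true 1% VAF variant, clean site", 200, 19_800, 3, 539_997),
    ("0.05% VAF call at a 0.05% error site", 10, 19_990, 270, 539_730),
    ("0.2% VAF call at a 0.02% error site", 40, 19_960, 108, 539_892),
]
for label, sample_alt, sample_ref, pon_alt, pon_ref in cases:
    p = fisher_exact(sample_alt, sample_ref, pon_alt, pon_ref, "greater")
    verdict = "kept" if p < threshold else "removed (background)"
    print(f"{label}: p = {p:.3g} -> {verdict}")
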