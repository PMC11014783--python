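import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tiny_cohort():
    """A small simulated cohort shared by integration-style tests."""
    from chpipe.simulate import SimCohortConfig, simulate_cohort

    return simulate_cohort(
        SimCohortConfig(n_samples=4, n_pon=6, depth=20_000, n_error_sites=200, seed=7)
    )


@pytest.fixture(scope="session")
def demo_kb():
    """Knowledge base with one entry exercising each curated list."""
    from chpipe.drivers import Hotspot, KnowledgeBase
    from chpipe.variants import VariantKey

    prior = VariantKey("chr2", 25_240_000, "C", "T")
    return KnowledgeBase(
        prior_ch_variants=frozenset({prior}),
        prior_ch_residues=frozenset({("JAK2", 617)}),
        hotspots=(
            Hotspot("DNMT3A", protein_pos=882, cdna_pos=2645, ch_report_count=50,
                    cosmic_total=100, cosmic_haem=90, cosmic_myeloid=80, damaging=True),
            Hotspot("JAK2", protein_pos=617, cdna_pos=1849, ch_report_count=5,
                    damaging=True),
        ),
    )
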