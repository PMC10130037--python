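import numpy as np
import pytest

from starrscreen.intervals import GenomeRegion


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def two_regions():
    return [GenomeRegion("chr1", 0, 10_000), GenomeRegion("chr2", 500, 8_500)]


@pytest.fixture(scope="session")
def tiny_screen():
    """A small planted-enhancer screen shared by the slower end-to-end tests."""
    from starrscreen.simulate import (
        SimConfig, EnhancerSpec, generate_reference, generate_library,
        simulate_screen,
    )

    cfg = SimConfig(
        seed=42, n_regions=3, region_length=20_000, n_fragments=8_000,
        dna_depth=60_000, rna_depth=20_000,
    )
    cfg.enhancers = [
        EnhancerSpec(GenomeRegion("tile01", 5_000, 6_000), effect=8.0),
        EnhancerSpec(GenomeRegion("tile02", 12_000, 13_000), effect=8.0),
        EnhancerSpec(GenomeRegion("tile03", 3_000, 4_000), effect=8.0),
    ]
    _, regions = generate_reference(cfg)
    library = generate_library(cfg, regions)
    return simulate_screen(cfg, library)
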