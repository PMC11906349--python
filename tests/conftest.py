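import numpy as np
import pytest

from cispqtl import simulate


@pytest.fixture(scope="session")
def small_locus() -> simulate.Locus:
    """Reduced locus shared by read-only tests (do not mutate)."""
    cfg = simulate.LocusConfig(
        n_samples=500, window_length=60_000, n_variants=900,
        gene_span=12_000, seed=11,
    )
    return simulate.simulate_locus(cfg)


@pytest.fixture(scope="session")
def medium_locus() -> simulate.Locus:
    cfg = simulate.LocusConfig(
        n_samples=2_000, window_length=80_000, n_variants=1_200,
        gene_span=15_000, seed=23,
    )
    return simulate.simulate_locus(cfg)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
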