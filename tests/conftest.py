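import pytest

from readermap import ReaderSpec, SyntheticConfig, simulate_bundle


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    """Compact two-chromosome genome used by the slower integration tests."""
    return SyntheticConfig(
        seed=7,
        chrom_lengths={"chrI": 400_000, "chrII": 400_000},
        readers=[ReaderSpec("cdp1", "H3K9me2", 0.9, 120),
                 ReaderSpec("cdp2", "H3K4me3", 0.9, 120),
                 ReaderSpec("cdp0", "H3K9me2", 0.0, 120)],
        n_genes=120,
        repeats_per_family=40,
    )


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return simulate_bundle(small_config)
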