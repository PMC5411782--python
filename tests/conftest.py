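import pytest

from polyqc.simulate import GenomeConfig, generate_genome


@pytest.fixture(scope="session")
def small_config() -> GenomeConfig:
    """A desk-scale genome: 30 triads over 21 chromosomes, ~190 kb."""
    return GenomeConfig(n_triads=30, seed=11, spacer_length=200, repeat_fraction=0.10)


@pytest.fixture(scope="session")
def small_genome(small_config):
    """Shared read-only genome; tests that mutate truth must regenerate."""
    return generate_genome(small_config)


def fresh_genome(**overrides):
    cfg = GenomeConfig(
        **{
            "n_triads": 30,
            "seed": 11,
            "spacer_length": 200,
            "repeat_fraction": 0.10,
            **overrides,
        }
    )
    return generate_genome(cfg)
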