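import pytest

from foxe1_targets import CompositeMotifConfig, GeneratorConfig, load_reference_hits


@pytest.fixture(scope="session")
def motif_config() -> CompositeMotifConfig:
    return CompositeMotifConfig()


@pytest.fixture(scope="session")
def reference_hits():
    """Curated published composite instances (gene, status, spacer, strand, sequence)."""
    return load_reference_hits()


@pytest.fixture()
def gen_config() -> GeneratorConfig:
    return GeneratorConfig(seed=7)
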