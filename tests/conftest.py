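import pytest

from psifootprint import load_default_catalog
from psifootprint.synth import generate_genome, recovery_spec


@pytest.fixture(scope="session")
def catalog():
    return load_default_catalog()


@pytest.fixture(scope="session")
def small_genome(catalog):
    """One synthetic genome with 3 dup + 4 BGC + 3 HGT planted families."""
    spec = recovery_spec(seed=11)
    genome, regions, manifest = generate_genome(spec, catalog)
    return genome, regions, manifest
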