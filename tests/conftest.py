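import pytest

from allokit import pipeline, presets


@pytest.fixture(scope="session")
def tetra_ds():
    """Default synthetic allotetraploid (4 pairs x 500 kb, planted families)."""
    return presets.allotetraploid(seed=1)


@pytest.fixture(scope="session")
def phasing(tetra_ds):
    return pipeline.phase_subgenomes(tetra_ds.genome, tetra_ds.homeolog_map)


@pytest.fixture(scope="session")
def exchange_analysis(tetra_ds, phasing):
    return pipeline.find_exchanges(phasing, tetra_ds.homeolog_map)
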