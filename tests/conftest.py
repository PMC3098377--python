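import numpy as np
import pytest

from islandscape import IslandSpec, SimConfig, generate_genome


@pytest.fixture(scope="session")
def small_world():
    """A 200-kb world with one island of each association/methylation flavour."""
    config = SimConfig(
        genome_length=200_000,
        island_specs=[
            IslandSpec(length=1000, gc=0.65, oe=0.9, assoc="TSS"),
            IslandSpec(length=1000, gc=0.65, oe=0.9, assoc="TES"),
            IslandSpec(length=1000, gc=0.65, oe=0.9, assoc="orphan"),
            IslandSpec(length=1000, gc=0.65, oe=0.9, assoc="orphan", methylation="full"),
            IslandSpec(length=1400, gc=0.65, oe=0.9, assoc="orphan",
                       methylation="imprinted_50_50"),
        ],
        n_genes=6,
        frac_expressed=0.5,
        seed=11,
    )
    genome, islands, genes, methylome = generate_genome(config)
    return config, genome, islands, genes, methylome


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
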