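import numpy as np
import pytest

from intertrack import (
    SpeciesTable,
    default_config,
    default_reaction_table,
)
from intertrack.track import ParticleSpec


@pytest.fixture(scope="session")
def species():
    return SpeciesTable()


@pytest.fixture(scope="session")
def reactions(species):
    return default_reaction_table(species)


@pytest.fixture(scope="session")
def tiny_cfg():
    """A short, cheap configuration for end-to-end runs in unit tests."""
    cfg = default_config(particle=ParticleSpec("carbon", 240.0, 30.0, 0.05))
    return cfg.replace(t_end_offset=2.0e3)  # 2 ns of chemistry


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
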