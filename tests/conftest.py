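import numpy as np
import pytest

from crowdpd.builder import SpeciesSpec, SystemSpec, build_initial_state
from crowdpd.model import parse_species


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def small_mixed_state():
    """A small periodic box with IDPs, crowders and solvent at density 3."""
    spec = SystemSpec(
        box=(8.0, 8.0, 8.0),
        density=3.0,
        species=(
            SpeciesSpec(parse_species("5B6"), count=4),
            SpeciesSpec(parse_species("P12"), count=3),
        ),
        epsilon=0.6,
        seed=42,
        n_steps=100,
        sample_every=50,
    )
    return spec, build_initial_state(spec)


@pytest.fixture
def solvent_spec():
    return SystemSpec(
        box=(5.0, 5.0, 5.0), density=3.0, species=(), epsilon=0.0,
        seed=7, n_steps=100, sample_every=50,
    )
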