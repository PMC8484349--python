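import numpy as np
import pandas as pd
import pytest

from flavipes import (
    ClutchConfig,
    FertilityModel,
    FounderOutcome,
    GeneratorParams,
    HostEggRecord,
)


@pytest.fixture
def default_model():
    return FertilityModel()


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_founder(clutches, founder_id="f1", group="g", species="native",
                 substrate="usual_plant"):
    """Founder whose parasitized hosts carry the given (size, females) pairs."""
    hosts = [
        HostEggRecord(
            host_species=species,
            substrate=substrate,
            parasitized=True,
            clutch=ClutchConfig(s, f),
            offspring_emerged=(species == "native"),
        )
        for s, f in clutches
    ]
    return FounderOutcome(founder_id, group, hosts)


@pytest.fixture
def make_founder_factory():
    return make_founder


def random_founder(rng, max_hosts=6, max_clutch=7):
    """A random founder with 1..max_hosts parasitized native hosts."""
    n = int(rng.integers(1, max_hosts + 1))
    clutches = []
    for _ in range(n):
        size = int(rng.integers(1, max_clutch + 1))
        females = int(rng.integers(0, size + 1))
        clutches.append((size, females))
    return make_founder(clutches)


@pytest.fixture
def null_params():
    """Generator with no dish effect and equal parasitism everywhere."""
    p = GeneratorParams(dish_sd=0.0)
    p.p_parasitize = {k: 0.5 for k in p.p_parasitize}
    return p
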