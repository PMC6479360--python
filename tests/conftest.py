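import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ppiatlas import enrichment_stats as es
from ppiatlas import sasa_regions as sr
from ppiatlas import synthetic_data as sd

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def toy_complex():
    """120-residue-per-chain lattice-globule complex, seed 1."""
    return sd.make_toy_complex(sd.SyntheticComplexSpec(n_residues=120, seed=1))


@pytest.fixture(scope="session")
def toy_surface(toy_complex):
    profiles = sr.interface_partition(toy_complex.receptor, None)
    return frozenset(p.canonical_position for p in profiles if p.rasa_u >= 0.1)


def table1_tallies():
    """The published per-region residue totals and variant-bearing counts."""
    return {
        "disease": [es.RegionTally("buried", 6019, 1842),
                    es.RegionTally("surface", 3118, 552),
                    es.RegionTally("rim", 916, 151),
                    es.RegionTally("core", 1146, 337)],
        "neutral": [es.RegionTally("buried", 6019, 524),
                    es.RegionTally("surface", 3118, 767),
                    es.RegionTally("rim", 916, 178),
                    es.RegionTally("core", 1146, 83)],
    }


@pytest.fixture
def rng():
    return np.random.default_rng(0)
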