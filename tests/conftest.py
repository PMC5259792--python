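import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from halobind.synth import HelixSpec, build_ideal_helix, place_halogen_probe

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def ideal_helix():
    """20-residue poly-Ala ideal alpha-helix."""
    return build_ideal_helix(HelixSpec(20))


@pytest.fixture(scope="session")
def pro12_helix():
    """20-residue helix with a proline at position 12 (exposes carbonyl 8)."""
    return build_ideal_helix(HelixSpec(20, proline_positions=(12,)))


@pytest.fixture(scope="session")
def probe_complex(pro12_helix):
    """Pro-12 helix plus a chlorobenzene probe at (3.1 A, 170 deg) on carbonyl 8."""
    return place_halogen_probe(pro12_helix, 8, 3.1, 170.0)


def random_rotation(rng: np.random.Generator):
    from scipy.spatial.transform import Rotation

    return Rotation.random(rng=rng)
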