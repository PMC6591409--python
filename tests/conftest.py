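import numpy as np
import pytest

from bestgate.synthetic_data import PentamerSpec, RingSpec, make_pentamer_fixture


@pytest.fixture
def aperture_model():
    """C5 pentamer with a single Ile aperture ring (circumradius 3.394 A)."""
    spec = PentamerSpec(
        rings=(RingSpec(180, "ILE", circumradius=3.394),), seed=7
    )
    return make_pentamer_fixture(spec)


@pytest.fixture
def multi_ring_model():
    """Neck (Ile/Ile/Phe) plus aperture rings, the study's measurement set."""
    spec = PentamerSpec(
        rings=(
            RingSpec(62, "ILE", circumradius=3.9, z=30.0),
            RingSpec(66, "ILE", circumradius=4.9, z=24.0),
            RingSpec(70, "PHE", circumradius=3.5, z=18.0),
            RingSpec(180, "ILE", circumradius=3.394, z=0.0),
        ),
        seed=7,
    )
    return make_pentamer_fixture(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_ring_points(rng, n=5, spread=4.0, z_sd=0.5):
    """Non-degenerate random ring: jittered pentagon, shuffled order."""
    angles = np.sort(rng.uniform(0, 2 * np.pi, n))
    radii = rng.uniform(1.0, spread, n)
    pts = np.column_stack(
        [radii * np.cos(angles), radii * np.sin(angles),
         rng.normal(0, z_sd, n)]
    )
    rng.shuffle(pts)
    return pts
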