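import numpy as np
import pytest

import pitscan as ps


def make_disc(shape, center, radius, value=True):
    """Boolean image with a filled disc (centre-of-pixel inclusion)."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    mask = np.hypot(xx - center[0], yy - center[1]) <= radius
    out = np.zeros(shape, dtype=bool)
    out[mask] = value
    return out


def circular_index_distance(i, j, n=180):
    d = abs(int(i) - int(j)) % n
    return min(d, n - d)


@pytest.fixture(scope="session")
def suite_specs():
    """The deterministic phantom battery (seed fixed for the whole session)."""
    return dict(ps.make_suite(seed=1))


@pytest.fixture(scope="session")
def analyzed_suite(suite_specs):
    """Every battery case generated and run through the full chain once."""
    out = {}
    for name, spec in suite_specs.items():
        volume, truth = ps.generate(spec)
        result = ps.analyze_volume(volume)
        out[name] = (volume, truth, result)
    return out


@pytest.fixture(scope="session")
def uniform_phantom():
    spec = ps.PhantomSpec(length_um=900.0, uniform_loss_um=100.0)
    return ps.generate(spec)
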