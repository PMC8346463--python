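import numpy as np
import pytest

from damtrack import dams, localize, simulate


@pytest.fixture(scope="session")
def geometry():
    """LGS-like synthetic dam: 6 turbines then 7 spillbays, weir in B01."""
    return dams.standard_geometry(name="SYN", weir_bays=("B01",))


@pytest.fixture(scope="session")
def array(geometry):
    """Pier-mounted cabled array: (positions, phone -> pier map)."""
    return simulate.pier_array(geometry)


@pytest.fixture(scope="session")
def sound_speed_18():
    return localize.sound_speed(18.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def synthetic_tdoas(source, positions, c, tag_id="ABCD", t0=0.0, noise_sd=0.0, rng=None):
    """Noise-free (or jittered) forward-model TDOA set for a known source."""
    from damtrack.filters import Message
    from damtrack.localize import message_tdoas

    src = np.asarray(source, dtype=float)
    decodes = []
    for name, p in positions.items():
        d = float(np.linalg.norm(src - np.asarray(p, dtype=float)))
        t = t0 + d / c
        if noise_sd and rng is not None:
            t += noise_sd * rng.standard_normal()
        decodes.append((name, t))
    return message_tdoas(Message(tag_id=tag_id, decodes=decodes), positions, c)
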