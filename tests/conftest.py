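import numpy as np
import pytest

import toothvib as tv


@pytest.fixture(scope="session")
def molar():
    """Worked-example setup: 1.32 g molar, alpha=1.03, k=1, slope 0.002 g/s."""
    return tv.get_preset("molar")


@pytest.fixture(scope="session")
def molar_law(molar):
    A0 = tv.initial_amplitude(molar.tooth, molar.state)
    return tv.EnvelopeLaw(
        regime="with_reactive",
        A0=A0,
        alpha=molar.tooth.alpha,
        k=molar.tooth.k,
        m0=molar.tooth.m0,
    )


@pytest.fixture(scope="session")
def molar_trajectory(molar):
    """Full-equation integration of the worked example over 200 s."""
    cfg = tv.SimulationConfig(t_end=200.0, dt=0.02)
    return tv.simulate_setup(molar, cfg)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260927)
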