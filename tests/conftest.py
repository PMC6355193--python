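import numpy as np
import pytest

import gaitsim
from gaitsim import engine


@pytest.fixture(scope="session")
def default_network():
    return gaitsim.build_default_network()


@pytest.fixture(scope="session")
def compiled(default_network):
    return engine._Compiled(default_network)


@pytest.fixture(scope="session")
def cnf_stimulation():
    return gaitsim.Stimulation(gaitsim.DriveLaw("CnF-Glu", "left", m=1.35, b=3.95))


@pytest.fixture(scope="session")
def ppn_stimulation():
    return gaitsim.Stimulation(gaitsim.DriveLaw("PPN-Glu", "left", m=1.5, b=4.0))


@pytest.fixture(scope="session")
def cnf_sweep(default_network, cnf_stimulation):
    """Reduced-resolution CnF continuation sweep shared by the acceptance tests."""
    return engine.bifurcation_sweep(
        default_network, cnf_stimulation, n_steps=24, chunk_s=10.0, max_s=30.0, seed=1
    )


def gait_sequence(frame):
    """Collapse consecutive duplicates of the gait column, dropping non-gaits."""
    seq = []
    for gait in frame["gait"]:
        if gait in ("quiescent", "unclassified"):
            continue
        if not seq or seq[-1] != gait:
            seq.append(gait)
    return seq


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
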