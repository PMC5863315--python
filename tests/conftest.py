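import numpy as np
import pytest

from retgensync.topology import TopologySpec, assemble_network, build_lattice


@pytest.fixture(scope="session")
def lattice10():
    return build_lattice(10)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def fig1_network():
    """A network at the illustration configuration N=10, m=m'=m''=9."""
    spec = TopologySpec(N=10, m=9, m_tc=9, m_cc=9)
    return assemble_network(spec, np.random.default_rng(42))


def small_random_network(rng, N=3, m=2, m_tc=3, m_cc=2, tc_directed=True):
    spec = TopologySpec(N=N, m=m, m_tc=m_tc, m_cc=m_cc, tc_directed=tc_directed)
    return assemble_network(spec, rng)
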