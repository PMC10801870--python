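import numpy as np
import pytest
import scipy.sparse as sp

from hetsnn import (ConnectivitySpec, CouplingMatrix, DisorderSpec,
                    build_connectivity, default_truncation, preset)


@pytest.fixture(scope="session")
def rs():
    return preset("rs")


@pytest.fixture(scope="session")
def fs():
    return preset("fs")


@pytest.fixture(scope="session")
def rs_adapt():
    return preset("rs", kappa_override=100.0)


@pytest.fixture
def zero_coupling():
    def make(n):
        return CouplingMatrix(weights=sp.csr_matrix((n, n)),
                              in_degree=np.zeros(n, dtype=int))
    return make


@pytest.fixture(scope="session")
def rs_disorder(rs):
    low, high = default_truncation(rs)
    return DisorderSpec("lorentzian", rs.vtheta_bar, rs.delta_v, low, high, seed=7)


@pytest.fixture(scope="session")
def small_sparse_net(rs):
    """N=200 sparse RS network shared across tests."""
    return build_connectivity(
        ConnectivitySpec(200, "random_sparse", 0.2, seed=11), rs.J)
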