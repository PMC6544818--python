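import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import clusterdose as cd
from clusterdose.activation import ActivationSet
from clusterdose.cluster import GOLD_1NM, GOLD_25NM

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def standard_binning():
    return cd.build_standard_binning()


@pytest.fixture(scope="session")
def nobump_params():
    """Closed-form synthetic kernel: A/r^2 * exp(-r/600 nm), support 5 um."""
    return cd.SyntheticKernelParams(
        amplitude=1.0, attenuation_length=600.0, support_radius=5000.0
    )


@pytest.fixture(scope="session")
def nobump_kernel(nobump_params, standard_binning):
    return cd.make_synthetic_kernel(nobump_params, standard_binning)


@pytest.fixture(scope="session")
def reference_cluster_spec():
    """500 nm cluster, 10% fill, 26 nm agents (25 nm core + 1 nm coat)."""
    return cd.ClusterSpec(500.0, 0.1, GOLD_25NM, seed=20260921)


@pytest.fixture(scope="session")
def packed_cluster(reference_cluster_spec):
    return cd.pack_cluster(reference_cluster_spec)


@pytest.fixture
def central_source_cluster():
    """One agent at the cluster centre: the spherically symmetric case."""
    return cd.Cluster(np.zeros((1, 3)), 26.0, 500.0)


@pytest.fixture
def central_activation():
    return ActivationSet(np.array([0]), np.array([1]), 1.0, 1.0)


@pytest.fixture
def water_transport():
    """k = 1: no mixture correction, unit background dose."""
    return cd.TransportConfig(1.0, 1.0)
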